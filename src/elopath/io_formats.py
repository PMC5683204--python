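"""Readers and writers for the planning pipeline's external data.

All spatial data is handled in a single world frame (RAS+ millimetres).
Voxel indices are 0-based and a voxel's world position is the position of
its *center*; every voxel<->world conversion goes through the parcellation
affine at the I/O boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
#: sentinel painted into risk-map volumes outside entry voxels, so colour
#: maps can mask background
RISK_MAP_SENTINEL = -1.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """N x N weighted graph over atlas regions.

    ``flavour`` is ``"functional"`` (correlation-like, signed) or
    ``"structural"`` (streamline counts, nonnegative). The matrix is
    symmetric with a zero diagonal; self-connections carry no meaning in
    the node-strength computation.
    """

    labels: list[int]
    values: np.ndarray
    flavour: str
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        validate_connectivity(self.labels, self.values, self.flavour)

    @property
    def n(self) -> int:
        return len(self.labels)

    def row_strength(self) -> dict[int, float]:
        """Unsigned weighted degree (sum of |w|) per region label."""
        s = np.abs(self.values).sum(axis=1)
        return {lab: float(v) for lab, v in zip(self.labels, s)}


def validate_connectivity(labels: Sequence[int], values: np.ndarray,
                          flavour: str) -> None:
    if flavour not in ("functional", "structural"):
        raise ValidationError(f"unknown flavour {flavour!r}")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"connectivity matrix must be square, got {values.shape}")
    if values.shape[0] < 2:
        raise ValidationError("connectivity matrix needs N >= 2 regions")
    if len(labels) != values.shape[0]:
        raise FormatError("label count does not match matrix size")
    if not np.all(np.isfinite(values)):
        raise ValidationError("connectivity matrix contains non-finite entries")
    if not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0):
        raise ValidationError("connectivity matrix is not symmetric")
    if np.any(np.diag(values) != 0):
        raise ValidationError("connectivity diagonal must be zero")
    if flavour == "structural" and np.any(values < 0):
        raise ValidationError("structural connectivity entries must be >= 0")


def _clean_connectivity(values: np.ndarray, flavour: str) -> np.ndarray:
    """Symmetrize (warn) and zero the diagonal before validation."""
    if not np.all(np.isfinite(values)):
        raise ValidationError("connectivity matrix contains NaN/inf entries")
    if not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0):
        warnings.warn("asymmetric connectivity matrix; symmetrizing as (A+A.T)/2",
                      stacklevel=3)
        values = (values + values.T) / 2.0
    values = values.copy()
    np.fill_diagonal(values, 0.0)
    return values


def read_connectivity(path: str | Path, flavour: str) -> ConnectivityMatrix:
    """Read a delimited-text connectivity matrix with a label header.

    Comma or tab delimiters are auto-detected. The header row and index
    column hold integer atlas labels (optionally ``label:name``).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"connectivity table in {path} is not square: {df.shape}")
    labels, names = _parse_labels([str(c) for c in df.columns])
    row_labels, _ = _parse_labels([str(i) for i in df.index])
    if labels != row_labels:
        raise FormatError(f"row and column labels differ in {path}")
    values = df.to_numpy(dtype=float)
    if flavour == "structural" and np.any(values[np.isfinite(values)] < 0):
        raise ValidationError("negative entry in structural connectivity matrix")
    values = _clean_connectivity(values, flavour)
    return ConnectivityMatrix(labels=labels, values=values, flavour=flavour,
                              names=names)


def _parse_labels(raw: list[str]) -> tuple[list[int], list[str] | None]:
    labels, names = [], []
    for item in raw:
        head, _, name = item.partition(":")
        try:
            labels.append(int(head))
        except ValueError as exc:
            raise FormatError(f"non-integer atlas label {item!r}") from exc
        names.append(name)
    return labels, (names if any(names) else None)


def write_connectivity(cm: ConnectivityMatrix, path: str | Path,
                       sep: str = ",") -> None:
    cols = ([f"{l}:{n}" for l, n in zip(cm.labels, cm.names)]
            if cm.names else [str(l) for l in cm.labels])
    pd.DataFrame(cm.values, index=cols, columns=cols).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Integer label volume with its voxel-to-world affine.

    Label 0 is background. ``roi_volumes`` maps each label k to its volume
    L_k in mm^3 (voxel count times voxel volume).
    """

    label_volume: np.ndarray
    affine: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValidationError("label volume must hold integers")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")
        if not np.any(self.label_volume > 0):
            raise ValidationError("no labeled voxels in parcellation")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def min_voxel_edge(self) -> float:
        return float(self.voxel_sizes.min())

    @property
    def roi_volumes(self) -> dict[int, float]:
        if "roi_volumes" not in self._cache:
            labels, counts = np.unique(self.label_volume, return_counts=True)
            vv = self.voxel_volume
            self._cache["roi_volumes"] = {
                int(l): float(c) * vv for l, c in zip(labels, counts) if l > 0}
        return self._cache["roi_volumes"]

    @property
    def labels(self) -> list[int]:
        return sorted(self.roi_volumes)

    def labeled_voxels(self) -> tuple[np.ndarray, np.ndarray]:
        """(world-mm centers of all labeled voxels, their labels).

        Cached; this is the hot input to capsule tissue extraction.
        """
        if "labeled" not in self._cache:
            idx = np.argwhere(self.label_volume > 0)
            labs = self.label_volume[tuple(idx.T)].astype(np.int64)
            self._cache["labeled"] = (self.voxel_to_world(idx), labs)
        return self._cache["labeled"]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (round to get the containing voxel)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def labels_at(self, pts: np.ndarray) -> np.ndarray:
        """Label of the voxel containing each world point (0 outside grid)."""
        vox = np.rint(self.world_to_voxel(pts)).astype(int)
        shape = np.asarray(self.label_volume.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(vox), dtype=np.int64)
        if inside.any():
            v = vox[inside]
            out[inside] = self.label_volume[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounds of labeled voxels, padded to voxel extent."""
        coords, _ = self.labeled_voxels()
        half = self.voxel_sizes / 2.0
        return coords.min(axis=0) - half, coords.max(axis=0) + half


def read_parcellation(path: str | Path) -> Parcellation:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValidationError(f"parcellation {path} is not integer-valued")
    return Parcellation(label_volume=rounded.astype(np.int32),
                        affine=np.asarray(img.affine))


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(parc.label_volume.astype(np.int32), parc.affine),
             str(path))


# ---------------------------------------------------------------------------
# tractogram
# ---------------------------------------------------------------------------

@dataclass
class Tractogram:
    """Ordered list of streamlines (polylines) in world mm.

    The list index is the stable streamline identifier used throughout the
    pipeline; streamlines are never reordered or dropped after load.
    """

    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValidationError(f"streamline {i} is not an (M,3) polyline")
            if not np.all(np.isfinite(s)):
                raise ValidationError(f"streamline {i} has non-finite coordinates")
            cleaned.append(s)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def read_tractogram(path: str | Path) -> Tractogram:
    """Read a TRK or TCK file; streamlines come back in world (RAS+) mm.

    Single-point streamlines are dropped with a warning; an empty
    tractogram is allowed.
    """
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"cannot read tractogram {path}: {exc}") from exc
    kept: list[np.ndarray] = []
    dropped = 0
    for s in tf.streamlines:
        s = np.asarray(s, dtype=float)
        if len(s) < 2:
            dropped += 1
            continue
        kept.append(s)
    if dropped:
        warnings.warn(f"dropped {dropped} single-point streamline(s) from {path}")
    if not kept:
        warnings.warn(f"tractogram {path} is empty")
    return Tractogram(streamlines=kept)


def write_tractogram(tract: Tractogram, path: str | Path,
                     parc: Parcellation | None = None) -> None:
    """Write TRK/TCK (by extension). TRK headers need a reference grid;
    pass the parcellation or a unit grid is assumed."""
    path = str(path)
    t = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        if parc is not None:
            header = {"voxel_sizes": tuple(parc.voxel_sizes.astype(np.float32)),
                      "dimensions": tuple(parc.label_volume.shape),
                      "voxel_to_rasmm": parc.affine.astype(np.float32)}
        else:
            header = {}
        nib.streamlines.save(t, path, header=header)
    else:
        nib.streamlines.save(t, path)


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@dataclass
class TargetSet:
    """Named target points in world mm, validated against the volume bounds."""

    targets: list[tuple[str, np.ndarray]]

    def __iter__(self):
        return iter(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


def read_targets(path: str | Path, parc: Parcellation) -> TargetSet:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"target file {path} needs columns id,x,y,z")
    lo, hi = parc.world_bounds()
    targets = []
    for _, row in df.iterrows():
        p = np.array([row["x"], row["y"], row["z"]], dtype=float)
        if np.any(p < lo) or np.any(p > hi):
            raise ValidationError(
                f"target {row['id']} at {p} lies outside the labeled volume bounds")
        targets.append((str(row["id"]), p))
    return TargetSet(targets=targets)


# ---------------------------------------------------------------------------
# risk map output
# ---------------------------------------------------------------------------

def risk_map_frame(risk_map) -> pd.DataFrame:
    """Tabulate a RiskMap: entry coords, raw + normalized components, T_score."""
    rm = risk_map
    if len(rm.entries) == 0:
        raise ValidationError("risk map has no entries")
    df = pd.DataFrame({
        "entry_x": rm.entries[:, 0], "entry_y": rm.entries[:, 1],
        "entry_z": rm.entries[:, 2],
        "fcgm_path": rm.raw[:, 0], "scgm_path": rm.raw[:, 1],
        "fcwm_path": rm.raw[:, 2], "scwm_path": rm.raw[:, 3],
        "fcgm_norm": rm.norm[:, 0], "scgm_norm": rm.norm[:, 1],
        "fcwm_norm": rm.norm[:, 2], "scwm_norm": rm.norm[:, 3],
        "t_score": rm.t_score,
    })
    df["is_optimal"] = False
    df.loc[rm.optimal_index, "is_optimal"] = True
    return df


def write_risk_map(risk_map, parc: Parcellation, out_prefix: str | Path) -> dict:
    """Write ``<prefix>.csv`` (entry table) and ``<prefix>.nii.gz``.

    In the volume, the voxel nearest each entry point carries its T_score;
    every other voxel holds the sentinel -1 so colour maps can mask
    non-entry tissue.
    """
    out_prefix = Path(out_prefix)
    df = risk_map_frame(risk_map)
    csv_path = out_prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.10g")

    vol = np.full(parc.label_volume.shape, RISK_MAP_SENTINEL, dtype=np.float32)
    shape = np.asarray(vol.shape)
    vox = np.rint(parc.world_to_voxel(risk_map.entries)).astype(int)
    vox = np.clip(vox, 0, shape - 1)  # entries sit on a box outside the grid
    for (i, j, k), t in zip(vox, risk_map.t_score):
        vol[i, j, k] = max(vol[i, j, k], t)
    nii_path = out_prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(vol, parc.affine), str(nii_path))
    return {"csv": csv_path, "nifti": nii_path}


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "spacing": 10.0,   # entry-grid spacing on the search box, mm
    "radius": 5.0,     # tube radius, mm
    "margin": 10.0,    # box margin beyond the labeled volume, mm
    "base_face": "z-",  # excluded (skull-contact) face
    "scale": 1.0,      # display-only multiplier on T_score
    "step": None,      # resampling step, mm; None = half min voxel edge
    "seed": 0,
    "log_level": "INFO",
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge config: CLI overrides > YAML file > defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
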