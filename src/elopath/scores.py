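"""Eloquence scores for grey-matter regions and white-matter fibres.

The regional scores are unsigned weighted degrees (node strengths) of the
functional and structural connectivity graphs:

    FCGM_k = sum_j |FC(k, j)|                       (unitless)
    SCGM_k = sum_j |SC(k, j)| / L_k                 (fibres / mm^3)

where L_k is the region's volume, cancelling the size advantage of large
regions. A fibre inherits the mean regional score over the set of regions
it intersects anywhere along its course:

    FCWM_p = mean_{i in ROIs(p)} FCGM_i
    SCWM_p = mean_{i in ROIs(p)} SCGM_i

A fibre touching no labeled voxel scores 0 and is flagged unassigned (it
is kept so streamline indices stay stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ConnectivityMatrix, Parcellation, Tractogram, ValidationError
from .geometry import resample_polyline


@dataclass
class GMScoreTable:
    """Per-region functional (fcgm) and structural (scgm) scores."""

    fcgm: dict[int, float]
    scgm: dict[int, float]

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.fcgm) | set(self.scgm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels,
                             "fcgm": [self.fcgm.get(l, 0.0) for l in self.labels],
                             "scgm": [self.scgm.get(l, 0.0) for l in self.labels]})


@dataclass
class FiberScoreTable:
    """Per-streamline scores, indexed by streamline position in the tractogram."""

    rois: list[frozenset[int]]
    fcwm: np.ndarray
    scwm: np.ndarray

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def unassigned(self) -> np.ndarray:
        return np.array([len(r) == 0 for r in self.rois])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(len(self.rois)),
            "rois": [";".join(map(str, sorted(r))) for r in self.rois],
            "fcwm": self.fcwm, "scwm": self.scwm,
            "unassigned": self.unassigned})


def compute_fcgm(fc: ConnectivityMatrix) -> dict[int, float]:
    """Functional node strength per region (diagonal is zero by contract)."""
    if fc.flavour != "functional":
        raise ValidationError("compute_fcgm expects a functional matrix")
    return fc.row_strength()


def compute_scgm(sc: ConnectivityMatrix, parc: Parcellation) -> dict[int, float]:
    """Structural node strength per region, divided by region volume (mm^3)."""
    if sc.flavour != "structural":
        raise ValidationError("compute_scgm expects a structural matrix")
    volumes = parc.roi_volumes
    missing = [l for l in sc.labels if l not in volumes]
    if missing:
        raise ValidationError(
            f"labels missing from parcellation: {missing}")
    return {lab: s / volumes[lab] for lab, s in sc.row_strength().items()}


def compute_gm_scores(fc: ConnectivityMatrix, sc: ConnectivityMatrix,
                      parc: Parcellation) -> GMScoreTable:
    return GMScoreTable(fcgm=compute_fcgm(fc), scgm=compute_scgm(sc, parc))


def assign_fiber_rois(streamline: np.ndarray, parc: Parcellation,
                      step: float | None = None) -> frozenset[int]:
    """Set of region labels whose voxels the streamline passes through.

    The polyline is resampled to a fixed step (default half the minimum
    voxel edge) before the voxel lookup so no crossed voxel is skipped
    between distant vertices. Each region counts once regardless of dwell
    length. A streamline entirely in background or outside the grid yields
    the empty set.
    """
    if step is None:
        step = parc.min_voxel_edge / 2.0
    pts = resample_polyline(np.asarray(streamline, dtype=float), step)
    labs = parc.labels_at(pts)
    return frozenset(int(l) for l in np.unique(labs) if l > 0)


def compute_fiber_scores(tract: Tractogram, parc: Parcellation,
                         gm_scores: GMScoreTable,
                         step: float | None = None) -> FiberScoreTable:
    """Score every streamline as the mean regional score over intersected ROIs."""
    rois: list[frozenset[int]] = []
    fcwm = np.zeros(len(tract))
    scwm = np.zeros(len(tract))
    fcgm, scgm = gm_scores.fcgm, gm_scores.scgm
    for p, streamline in enumerate(tract):
        members = assign_fiber_rois(streamline, parc, step=step)
        rois.append(members)
        if members:
            try:
                fcwm[p] = float(np.mean([fcgm[i] for i in members]))
                scwm[p] = float(np.mean([scgm[i] for i in members]))
            except KeyError as exc:
                raise ValidationError(
                    f"streamline {p} intersects label {exc.args[0]} "
                    "absent from the GM score table") from exc
    return FiberScoreTable(rois=rois, fcwm=fcwm, scwm=scwm)
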