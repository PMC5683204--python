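"""Capsule model of a surgical access path and tissue extraction.

The path between an entry point outside the head and an intracranial
target is modelled as the volume swept by a sphere of the tube radius
moving along the entry-target segment: a capsule (cylinder with
hemispherical caps). Membership is the exact analytic test
``distance(point, segment) <= radius``; a flat-capped cylinder variant is
available behind the ``cap`` flag.

Damage of a trajectory aggregates the eloquence scores of everything the
capsule touches: grey-matter voxel volume weighted by regional scores
plus the summed scores of intersected white-matter fibres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Parcellation, Tractogram, ValidationError


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Insert evenly spaced samples so consecutive points are <= step apart.

    Original vertices are always retained; degenerate (zero-length)
    segments contribute no extra samples.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        ts = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + ts * (b - a))
    return np.vstack(out)


def point_segment_distance(points: np.ndarray, a: np.ndarray,
                           b: np.ndarray) -> np.ndarray:
    """Distance from each point to the closed segment [a, b] (vectorized)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    d = np.asarray(b, dtype=float) - a
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ d / denom, 0.0, 1.0)
    return np.linalg.norm(points - a - t[:, None] * d, axis=1)


@dataclass(frozen=True)
class TrajectoryTube:
    """Capsule-shaped access path from ``entry`` to ``target`` (world mm)."""

    entry: np.ndarray
    target: np.ndarray
    radius: float
    cap: str = "round"  # "round" = capsule, "flat" = finite cylinder

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if self.radius <= 0:
            raise ValidationError("tube radius must be positive")
        if self.cap not in ("round", "flat"):
            raise ValidationError(f"unknown cap style {self.cap!r}")
        if self.length == 0:
            raise ValidationError("entry and target coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.entry - self.target))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (M, 3) array of world points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.cap == "round":
            return point_segment_distance(points, self.entry, self.target) <= self.radius
        d = self.target - self.entry
        t = (points - self.entry) @ d / float(d @ d)
        radial = np.linalg.norm(points - self.entry - t[:, None] * d, axis=1)
        return (t >= 0.0) & (t <= 1.0) & (radial <= self.radius)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.minimum(self.entry, self.target) - self.radius
        hi = np.maximum(self.entry, self.target) + self.radius
        return lo, hi


def point_in_tube(p: np.ndarray, tube: TrajectoryTube) -> bool:
    return bool(tube.contains(np.asarray(p, dtype=float)[None, :])[0])


@dataclass
class TissueInventory:
    """What a tube intersects: GM voxels per region and WM fibre indices."""

    gm_voxels_per_roi: dict[int, int]
    voxel_volume: float
    fiber_indices: frozenset[int]

    @property
    def gm_volume_per_roi(self) -> dict[int, float]:
        return {k: v * self.voxel_volume for k, v in self.gm_voxels_per_roi.items()}

    @property
    def total_gm_volume(self) -> float:
        return sum(self.gm_voxels_per_roi.values()) * self.voxel_volume


class _ResampledTract:
    """Flat vertex array of a resampled tractogram, cached per (tract, step)."""

    def __init__(self, tract: Tractogram, step: float):
        parts = [resample_polyline(s, step) for s in tract]
        if parts:
            self.vertices = np.vstack(parts)
            self.owner = np.repeat(np.arange(len(parts)),
                                   [len(p) for p in parts])
        else:
            self.vertices = np.empty((0, 3))
            self.owner = np.empty(0, dtype=int)


_tract_cache: dict[tuple[int, float], _ResampledTract] = {}


def _resampled(tract: Tractogram, step: float) -> _ResampledTract:
    key = (id(tract), step)
    if key not in _tract_cache:
        _tract_cache.clear()  # keep at most one tractogram resident
        _tract_cache[key] = _ResampledTract(tract, step)
    return _tract_cache[key]


def extract_tissue(tube: TrajectoryTube, parc: Parcellation,
                   tract: Tractogram | None = None,
                   step: float | None = None) -> TissueInventory:
    """Inventory the labeled voxels and streamlines inside a tube.

    A voxel belongs to the tube iff its *center* does; a streamline
    belongs iff any of its resampled vertices does (step defaults to half
    the minimum voxel edge). Only candidates inside the tube's bounding
    box are tested; the result is identical to a full scan.
    """
    if step is None:
        step = parc.min_voxel_edge / 2.0
    coords, labs = parc.labeled_voxels()
    lo, hi = tube.bounding_box()
    near = np.all((coords >= lo) & (coords <= hi), axis=1)
    inside = np.zeros(len(coords), dtype=bool)
    if near.any():
        inside[near] = tube.contains(coords[near])
    hit_labels, counts = np.unique(labs[inside], return_counts=True)
    gm = {int(l): int(c) for l, c in zip(hit_labels, counts)}

    fibers: frozenset[int] = frozenset()
    if tract is not None and len(tract):
        rs = _resampled(tract, step)
        near_v = np.all((rs.vertices >= lo) & (rs.vertices <= hi), axis=1)
        if near_v.any():
            hit = tube.contains(rs.vertices[near_v])
            fibers = frozenset(np.unique(rs.owner[near_v][hit]).tolist())
    return TissueInventory(gm_voxels_per_roi=gm,
                           voxel_volume=parc.voxel_volume,
                           fiber_indices=fibers)


@dataclass(frozen=True)
class RawDamage:
    """Unnormalized damage components of one trajectory.

    GM components are score-weighted intersected volume (score * mm^3);
    WM components are sums of fibre scores over intersected streamlines.
    """

    fcgm_path: float
    scgm_path: float
    fcwm_path: float
    scwm_path: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fcgm_path, self.scgm_path,
                         self.fcwm_path, self.scwm_path])


def raw_damage(inv: TissueInventory, gm_scores, fib_scores) -> RawDamage:
    """Aggregate eloquence scores over a tube's tissue inventory."""
    fcgm = scgm = 0.0
    for label, vol in inv.gm_volume_per_roi.items():
        try:
            fcgm += vol * gm_scores.fcgm[label]
            scgm += vol * gm_scores.scgm[label]
        except KeyError:
            raise ValidationError(f"inventory references unknown label {label}")
    idx = sorted(inv.fiber_indices)
    if idx and (max(idx) >= len(fib_scores) or min(idx) < 0):
        raise ValidationError("inventory references streamline index out of range")
    fcwm = float(fib_scores.fcwm[idx].sum()) if idx else 0.0
    scwm = float(fib_scores.scwm[idx].sum()) if idx else 0.0
    return RawDamage(fcgm_path=fcgm, scgm_path=scgm,
                     fcwm_path=fcwm, scwm_path=scwm)
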