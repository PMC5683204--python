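"""Exhaustive entry-point search over a head-enclosing box.

Candidate entry points form a lattice on five faces of an axis-aligned
box around the labeled volume; the sixth (base) face rests against the
skull support and is excluded. Every entry is connected to the target by
a capsule tube, the four raw damage components are computed, each
component is min-max scaled across the entries of that search, and the
total score

    T_score = FCGM' + SCGM' + FCWM' + SCWM'   in [0, 4]

is painted back over the box as a risk map. Normalization is per target
and per search: rerunning on a subset of entries rescales the components.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import TrajectoryTube, extract_tissue, raw_damage
from .io_formats import Parcellation, Tractogram, ValidationError

logger = logging.getLogger(__name__)

_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned box enclosing the labeled volume plus a margin."""

    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    spacing: float = 10.0
    base_face: str = "z-"

    def __post_init__(self) -> None:
        if self.base_face not in _FACES:
            raise ValidationError(f"base_face must be one of {_FACES}")
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")
        if self.spacing > 2 * min(self.half_extents):
            raise ValidationError("spacing exceeds the smallest box edge")

    @classmethod
    def from_parcellation(cls, parc: Parcellation, margin: float = 10.0,
                          spacing: float = 10.0,
                          base_face: str = "z-") -> "SearchBox":
        lo, hi = parc.world_bounds()
        lo, hi = lo - margin, hi + margin
        return cls(center=tuple((lo + hi) / 2.0),
                   half_extents=tuple((hi - lo) / 2.0),
                   spacing=spacing, base_face=base_face)

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.half_extents)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.half_extents)

    def contains(self, p: np.ndarray) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))

    def _axis_coords(self, axis: int) -> np.ndarray:
        """1D lattice along one axis: endpoint-inclusive when the spacing
        divides the edge, otherwise centered on the face."""
        lo, hi = self.lo[axis], self.hi[axis]
        edge = hi - lo
        n = edge / self.spacing
        if abs(n - round(n)) < 1e-9:
            return lo + self.spacing * np.arange(int(round(n)) + 1)
        m = int(np.floor(n))
        start = lo + (edge - m * self.spacing) / 2.0
        return start + self.spacing * np.arange(m + 1)


def build_entry_grid(box: SearchBox) -> np.ndarray:
    """Deduplicated lattice points on the five non-base faces.

    Points shared between faces (box edges) appear once; base-face
    points survive only where a side face also contains them. Ordering is
    lexicographic by (x, y, z), hence deterministic.
    """
    coords = [box._axis_coords(a) for a in range(3)]
    pts = []
    for face in _FACES:
        if face == box.base_face:
            continue
        axis = "xyz".index(face[0])
        value = box.lo[axis] if face[1] == "-" else box.hi[axis]
        others = [a for a in range(3) if a != axis]
        u, v = np.meshgrid(coords[others[0]], coords[others[1]], indexing="ij")
        face_pts = np.empty((u.size, 3))
        face_pts[:, axis] = value
        face_pts[:, others[0]] = u.ravel()
        face_pts[:, others[1]] = v.ravel()
        pts.append(face_pts)
    allpts = np.vstack(pts)
    # exact dedup: lattice coordinates are generated identically per axis
    uniq = np.unique(allpts, axis=0)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    return uniq[order]


def minmax_normalize(values) -> np.ndarray:
    """Min-max feature scaling to [0, 1]; a constant vector maps to all 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot normalize an empty list")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite value in normalization input")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def total_score(norm_components, scale: float = 1.0) -> float:
    """Sum of the four normalized components, in [0, 4].

    ``scale`` is a display-only multiplier; it never affects ranking.
    """
    return float(np.sum(norm_components)) * scale


@dataclass
class RiskMap:
    """Result of one exhaustive search for a single target."""

    target_id: str
    target: np.ndarray
    entries: np.ndarray          # (M, 3) entry points
    raw: np.ndarray              # (M, 4) raw components
    norm: np.ndarray             # (M, 4) min-max scaled components
    t_score: np.ndarray          # (M,)
    component_ranges: list[tuple[float, float]]
    optimal_index: int

    @property
    def optimal_entry(self) -> np.ndarray:
        return self.entries[self.optimal_index]


def _pick_optimal(entries: np.ndarray, t_score: np.ndarray,
                  target: np.ndarray) -> int:
    """argmin T_score; ties broken by entry-target distance, then by
    lexicographic entry coordinates."""
    best = t_score.min()
    cand = np.flatnonzero(t_score == best)
    dist = np.linalg.norm(entries[cand] - target, axis=1)
    cand = cand[dist == dist.min()]
    sub = entries[cand]
    return int(cand[np.lexsort((sub[:, 2], sub[:, 1], sub[:, 0]))[0]])


def assemble_risk_map(target_id: str, target: np.ndarray, entries: np.ndarray,
                      raw: np.ndarray, scale: float = 1.0) -> RiskMap:
    """Normalize raw components across entries and rank them."""
    norm = np.column_stack([minmax_normalize(raw[:, c]) for c in range(4)])
    t = norm.sum(axis=1) * scale
    ranges = [(float(raw[:, c].min()), float(raw[:, c].max())) for c in range(4)]
    return RiskMap(target_id=target_id, target=np.asarray(target, dtype=float),
                   entries=entries, raw=raw, norm=norm, t_score=t,
                   component_ranges=ranges,
                   optimal_index=_pick_optimal(entries, t, target))


_search_cache: dict[tuple, RiskMap] = {}


def _scene_digest(parc: Parcellation, tract: Tractogram | None) -> str:
    h = hashlib.sha256()
    h.update(parc.label_volume.tobytes())
    h.update(parc.affine.tobytes())
    if tract is not None:
        for s in tract:
            h.update(s.tobytes())
    return h.hexdigest()


def exhaustive_search(target: np.ndarray, box: SearchBox, radius: float,
                      parc: Parcellation, tract: Tractogram,
                      gm_scores, fib_scores, target_id: str = "target",
                      step: float | None = None, scale: float = 1.0,
                      use_cache: bool = True,
                      progress_every: int = 200) -> RiskMap:
    """Evaluate every grid entry point against one target.

    Deterministic: identical inputs yield bit-identical risk maps.
    Results are memoized on (target, box, radius, step, scene digest) to
    support interactive refinement without recomputation.
    """
    target = np.asarray(target, dtype=float)
    if not box.contains(target):
        raise ValidationError(f"target {target} lies outside the search box")
    key = None
    if use_cache:
        key = (tuple(target), box, float(radius), step, scale,
               _scene_digest(parc, tract))
        if key in _search_cache:
            logger.info("risk map for target %s served from cache", target_id)
            return _search_cache[key]

    entries = build_entry_grid(box)
    raw = np.empty((len(entries), 4))
    for i, entry in enumerate(entries):
        tube = TrajectoryTube(entry=entry, target=target, radius=radius)
        inv = extract_tissue(tube, parc, tract, step=step)
        raw[i] = raw_damage(inv, gm_scores, fib_scores).as_array()
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("evaluated %d/%d entry points", i + 1, len(entries))
    rm = assemble_risk_map(target_id, target, entries, raw, scale=scale)
    if key is not None:
        _search_cache.clear()
        _search_cache[key] = rm
    return rm
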