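"""Trajectory bookkeeping: path length to cortex, entry-point distances.

These are the quantities a planning session reports when comparing a
proposed trajectory against a routinely chosen one: the intracranial
path length (target to the outer tissue boundary along the trajectory),
the straight-line distance between the two entry points on the search
box, and the angle between the two trajectories at the target.

The cortical surface is approximated by the outer boundary of the
labeled parcellation; no surface mesh is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Parcellation, ValidationError


def path_length(entry: np.ndarray, target: np.ndarray, parc: Parcellation,
                step: float | None = None) -> float:
    """Distance from the target to the tissue boundary along the trajectory.

    Marches from the entry toward the target with a step of half the
    minimum voxel edge (configurable) and returns the distance from the
    first labeled sample to the target. An entry already inside tissue
    degenerates to the full entry-target distance.
    """
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    if step is None:
        step = parc.min_voxel_edge / 2.0
    total = float(np.linalg.norm(target - entry))
    if total == 0:
        raise ValidationError("entry and target coincide")
    n = int(np.ceil(total / step))
    ts = np.linspace(0.0, 1.0, n + 1)
    pts = entry + ts[:, None] * (target - entry)
    labs = parc.labels_at(pts)
    hits = np.flatnonzero(labs > 0)
    if hits.size == 0:
        raise ValidationError("trajectory misses brain: ray never enters labeled tissue")
    boundary = pts[hits[0]]
    return float(np.linalg.norm(target - boundary))


def angular_distance(entry_a: np.ndarray, entry_b: np.ndarray,
                     target: np.ndarray) -> float:
    """Angle in degrees ([0, 180]) between the two trajectories at the target."""
    target = np.asarray(target, dtype=float)
    va = np.asarray(entry_a, dtype=float) - target
    vb = np.asarray(entry_b, dtype=float) - target
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValidationError("entry coincides with target: undefined direction")
    cos = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def euclidean_on_box(entry_a: np.ndarray, entry_b: np.ndarray) -> float:
    """Straight-line (chordal) distance between two entry points, mm."""
    return float(np.linalg.norm(np.asarray(entry_a, dtype=float)
                                - np.asarray(entry_b, dtype=float)))


@dataclass
class TrajectoryComparison:
    """Side-by-side report for two trajectories toward the same target."""

    path_length_a: float
    path_length_b: float
    damage_a: float
    damage_b: float
    euclidean_on_box: float
    angular_distance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "path_length_a_mm": self.path_length_a,
            "path_length_b_mm": self.path_length_b,
            "damage_a": self.damage_a,
            "damage_b": self.damage_b,
            "euclidean_on_box_mm": self.euclidean_on_box,
            "angular_distance_deg": self.angular_distance,
        }])


def compare_trajectories(entry_a: np.ndarray, entry_b: np.ndarray,
                         target: np.ndarray, parc: Parcellation,
                         damage_a: float, damage_b: float,
                         step: float | None = None) -> TrajectoryComparison:
    return TrajectoryComparison(
        path_length_a=path_length(entry_a, target, parc, step=step),
        path_length_b=path_length(entry_b, target, parc, step=step),
        damage_a=damage_a, damage_b=damage_b,
        euclidean_on_box=euclidean_on_box(entry_a, entry_b),
        angular_distance=angular_distance(entry_a, entry_b, target))
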