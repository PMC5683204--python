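"""Seeded phantom scenes: parcellation, streamlines and matching FC/SC.

The phantom emulates the four pipeline inputs without any acquisition: an
ellipsoidal "brain" partitioned into azimuthal sectors (the atlas
regions), jittered polyline bundles between region centroids (the
tractogram), a structural matrix counting exactly the generated
streamline endpoints, and a symmetric functional matrix of baseline
noise with optionally amplified hub rows/columns.

Every quantity derives from one ``numpy`` Generator seeded by the spec,
so a seed fully determines the scene. Ground truth (region volumes,
bundle membership, expected scores computed by plain loops) ships with
each scene for end-to-end verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ConnectivityMatrix, Parcellation, Tractogram, ValidationError


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic scene.

    Defaults mirror a desk-scale diffusion acquisition: a 64^3 grid of
    2 mm isotropic voxels, eight regions, three ten-streamline bundles
    with 2 mm endpoint jitter, and weak baseline functional coupling.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    n_rois: int = 8
    bundles: tuple[tuple[int, int, int, float], ...] = (
        (1, 5, 10, 2.0), (2, 6, 10, 2.0), (3, 7, 10, 2.0))
    hub_labels: tuple[int, ...] = ()
    hub_boost: float = 0.6
    fc_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValidationError("need at least two regions")
        for a, b, n, _ in self.bundles:
            if a == b:
                raise ValidationError(f"bundle endpoints must differ (got {a},{a})")
            for lab in (a, b):
                if not 1 <= lab <= self.n_rois:
                    raise ValidationError(f"bundle references invalid label {lab}")
            if n < 1:
                raise ValidationError("bundle needs at least one streamline")


@dataclass
class Phantom:
    """A complete synthetic scene plus its generation ground truth."""

    parcellation: Parcellation
    tractogram: Tractogram
    fc: ConnectivityMatrix
    sc: ConnectivityMatrix
    ground_truth: dict


def _sector_volume(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoid partitioned into n azimuthal sectors around the z axis.

    The grid is centered on the world origin so the scene is mirror
    symmetric under x -> -x; with an even sector count the label map is
    mirror symmetric too (sector 1 is centered on +x).
    """
    shape = np.asarray(spec.grid_shape)
    vs = spec.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * vs
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    coords = idx * vs + affine[:3, 3]
    semi = 0.42 * shape * vs
    inside = (coords ** 2 / semi ** 2).sum(axis=1) <= 1.0
    theta = np.arctan2(coords[:, 1], coords[:, 0])
    n = spec.n_rois
    sector = np.floor((theta + np.pi / n) / (2 * np.pi / n)).astype(int) % n
    vol = np.zeros(spec.grid_shape, dtype=np.int32)
    vol.reshape(-1)[inside] = sector[inside] + 1
    return vol, affine


def _roi_centroids(parc: Parcellation) -> dict[int, np.ndarray]:
    coords, labs = parc.labeled_voxels()
    return {int(l): coords[labs == l].mean(axis=0) for l in np.unique(labs)}


def _sample_endpoint(rng: np.random.Generator, centroid: np.ndarray,
                     label: int, parc: Parcellation, jitter: float) -> np.ndarray:
    """Centroid plus Gaussian jitter, rejected until inside the target ROI."""
    for _ in range(100):
        p = centroid + rng.normal(0.0, jitter, size=3)
        if int(parc.labels_at(p[None, :])[0]) == label:
            return p
    return centroid.copy()


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one scene; see module docstring for the construction."""
    rng = np.random.default_rng(spec.seed)
    vol, affine = _sector_volume(spec)
    parc = Parcellation(label_volume=vol, affine=affine)
    centroids = _roi_centroids(parc)

    streamlines: list[np.ndarray] = []
    bundle_indices: dict[str, list[int]] = {}
    n = spec.n_rois
    sc = np.zeros((n, n))
    for a, b, n_sl, jitter in spec.bundles:
        idxs = []
        for _ in range(n_sl):
            pa = _sample_endpoint(rng, centroids[a], a, parc, jitter)
            pb = _sample_endpoint(rng, centroids[b], b, parc, jitter)
            ts = np.linspace(0.0, 1.0, 15)[:, None]
            line = pa + ts * (pb - pa)
            # gentle lateral bow so bundles are not degenerate straight lines
            perp = np.cross(pb - pa, rng.normal(size=3))
            norm = np.linalg.norm(perp)
            if norm > 0:
                bow = rng.normal(0.0, jitter)
                line = line + np.sin(np.pi * ts) * bow * perp / norm
            idxs.append(len(streamlines))
            streamlines.append(line)
        bundle_indices[f"{a}-{b}"] = idxs
    tract = Tractogram(streamlines=streamlines)

    # SC counts the *actual* endpoint labels of the generated streamlines,
    # so matrix and tractogram are consistent by construction
    for s in tract:
        la = int(parc.labels_at(s[0][None, :])[0])
        lb = int(parc.labels_at(s[-1][None, :])[0])
        if la > 0 and lb > 0 and la != lb:
            sc[la - 1, lb - 1] += 1
            sc[lb - 1, la - 1] += 1

    fc = rng.normal(0.0, spec.fc_noise, size=(n, n))
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    for h in spec.hub_labels:
        i = h - 1
        boosted_row = np.sign(np.where(fc[i] == 0, 1.0, fc[i])) * np.minimum(
            np.abs(fc[i]) + spec.hub_boost, 1.0)
        fc[i, :] = boosted_row
        fc[:, i] = boosted_row
    np.fill_diagonal(fc, 0.0)
    np.fill_diagonal(sc, 0.0)

    labels = list(range(1, n + 1))
    fc_m = ConnectivityMatrix(labels=labels, values=fc, flavour="functional")
    sc_m = ConnectivityMatrix(labels=labels, values=sc, flavour="structural")

    gt = {
        "roi_volumes": dict(parc.roi_volumes),
        "bundle_streamline_indices": bundle_indices,
        "expected_fcgm": _loop_strength(labels, fc),
        "expected_scgm": {l: v / parc.roi_volumes[l]
                          for l, v in _loop_strength(labels, sc).items()},
        "centroids": {l: c.tolist() for l, c in centroids.items()},
    }
    return Phantom(parcellation=parc, tractogram=tract, fc=fc_m, sc=sc_m,
                   ground_truth=gt)


def _loop_strength(labels: list[int], mat: np.ndarray) -> dict[int, float]:
    """Plain-loop unsigned degree; deliberately naive bookkeeping oracle."""
    out = {}
    for i, lab in enumerate(labels):
        total = 0.0
        for j in range(len(labels)):
            total += abs(mat[i][j])
        out[lab] = total
    return out


# ---------------------------------------------------------------------------
# planted-hub scene
# ---------------------------------------------------------------------------

HUB_LABEL = 1        # sector centered on +x
MIRROR_LABEL = 5     # its x -> -x mirror sector (n_rois = 8)


def make_planted_hub_scene(seed: int, radius: float = 5.0) -> Phantom:
    """Scene with one dominant hub region and a mirrored trajectory pair.

    Region 1 (centered on +x) receives both an amplified functional row
    and the lion's share of streamline bundles, making its node strength
    at least three times any other region's. Two geometrically mirrored
    trajectories target the origin: one entering from +x through the hub,
    its twin from -x through the quiet mirror sector. Because grid,
    ellipsoid and sector map are all mirror symmetric, the two capsules
    intersect identical total grey-matter volume; only the scores differ.

    Ground truth records both trajectories' raw damage components,
    computed here by a direct all-voxel / all-vertex distance scan
    independent of the geometry module.
    """
    spec = PhantomSpec(
        n_rois=8,
        bundles=((HUB_LABEL, 3, 20, 2.0), (HUB_LABEL, 7, 20, 2.0),
                 (HUB_LABEL, 4, 20, 2.0), (HUB_LABEL, 6, 20, 2.0),
                 (MIRROR_LABEL, 4, 2, 2.0), (2, 6, 3, 2.0)),
        hub_labels=(HUB_LABEL,),
        hub_boost=0.7,
        fc_noise=0.05,
        seed=seed)
    phantom = make_phantom(spec)
    parc = phantom.parcellation

    lo, hi = parc.world_bounds()
    margin = 10.0
    entry_hub = np.array([hi[0] + margin, 0.0, 0.0])
    entry_mirror = np.array([-(hi[0] + margin), 0.0, 0.0])
    target = np.zeros(3)

    gt = phantom.ground_truth
    gt["hub_label"] = HUB_LABEL
    gt["mirror_label"] = MIRROR_LABEL
    gt["target"] = target.tolist()
    gt["entry_hub"] = entry_hub.tolist()
    gt["entry_mirror"] = entry_mirror.tolist()
    gt["radius"] = radius
    gt["raw_damage_hub"] = _direct_raw_damage(phantom, entry_hub, target, radius)
    gt["raw_damage_mirror"] = _direct_raw_damage(phantom, entry_mirror, target, radius)
    hub_vec = np.array(gt["raw_damage_hub"])
    mir_vec = np.array(gt["raw_damage_mirror"])
    if not (np.all(hub_vec >= mir_vec) and hub_vec.sum() > mir_vec.sum()):
        raise ValidationError(
            "planted-hub construction failed to order the trajectory pair")
    return phantom


def _direct_raw_damage(phantom: Phantom, entry: np.ndarray, target: np.ndarray,
                       radius: float) -> list[float]:
    """All-voxel, all-vertex capsule scan by the raw distance formula.

    Independent of the geometry module: used only to pin ground truth.
    """
    parc = phantom.parcellation
    d = target - entry
    dd = float(d @ d)

    def dist_to_segment(pts):
        t = np.clip((pts - entry) @ d / dd, 0.0, 1.0)
        return np.linalg.norm(pts - entry - t[:, None] * d, axis=1)

    coords, labs = parc.labeled_voxels()
    in_tube = dist_to_segment(coords) <= radius
    vv = parc.voxel_volume
    fcgm = phantom.ground_truth["expected_fcgm"]
    scgm = phantom.ground_truth["expected_scgm"]
    fcgm_path = scgm_path = 0.0
    for lab in np.unique(labs[in_tube]):
        volume = float(np.sum(labs[in_tube] == lab)) * vv
        fcgm_path += volume * fcgm[int(lab)]
        scgm_path += volume * scgm[int(lab)]

    step = parc.min_voxel_edge / 2.0
    fcwm_path = scwm_path = 0.0
    from .geometry import resample_polyline  # resampling rule is shared
    from .scores import assign_fiber_rois
    for s in phantom.tractogram:
        pts = resample_polyline(s, step)
        if np.any(dist_to_segment(pts) <= radius):
            members = assign_fiber_rois(s, parc)
            if members:
                fcwm_path += float(np.mean([fcgm[i] for i in members]))
                scwm_path += float(np.mean([scgm[i] for i in members]))
    return [fcgm_path, scgm_path, fcwm_path, scwm_path]
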