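# Methods

## Scores

Regional eloquence is the unsigned weighted degree (node strength) of the
region in each connectivity graph: `FCGM_k = Σ_j |FC(k,j)|` and
`SCGM_k = Σ_j |SC(k,j)| / L_k`, with L_k the region volume in mm³. Taking
absolute values treats anticorrelation as coupling; dividing the
structural sum by L_k removes the streamline-count advantage of large
regions. Connectivity matrices are symmetrized by averaging on load (with
a warning) and their diagonal is forced to zero, so the full-row sum and
the off-diagonal sum coincide; an FC diagonal of 1.0 is an artefact of
correlation matrices and carries no eloquence information.

A streamline's scores are the arithmetic mean of the regional scores over
the *set* of regions it intersects anywhere along its course — not just
its endpoints, and with each region counted once regardless of dwell
length, because the average is over regions rather than over samples.
Streamlines intersecting no labeled voxel score zero and are flagged
`unassigned` instead of being dropped, so streamline indices remain
stable identifiers across the pipeline. Endpoint-based assignment remains
the convention for *building* an SC matrix; it is not used for scoring.

## Path geometry

The access path is the volume swept by a sphere of the tube radius along
the entry–target segment: a capsule. The exact analytic membership test
(`distance(point, segment) ≤ r`) replaces the swept point-cloud
construction it models; the sampled sphere sweep survives only as a test
oracle, since its resolution is otherwise a free parameter. A flat-capped
cylinder is available behind `cap="flat"` for users who prefer ends flush
with the entry and target planes.

A voxel is inside the tube iff its *center* is (no partial-volume
weighting); a streamline is inside iff any of its resampled vertices is.
Polylines are resampled to a step of half the minimum voxel edge before
any voxel lookup or membership test, so no crossed voxel can be skipped
between sparse vertices; at that step an exact segment–capsule
intersection adds nothing. Extraction only examines candidates inside the
tube's axis-aligned bounding box; the tests assert this is bit-identical
to a full scan. Default radius is 5 mm, the usual calibre of a surgical
access tube; radius, spacing and step are configurable.

## Entry-point search

The search box is the axis-aligned world bounding box of the labeled
voxels (padded to the voxel extent) plus a margin (default 10 mm). Entry
candidates form a lattice of the grid spacing (default 10 mm) on five of
its six faces; the base face — by default the inferior, minimum-z face,
which rests against the skull support — is excluded, though edge points
it shares with the side faces remain. When the spacing does not divide an
edge, the face lattice is centered. Points are deduplicated and ordered
lexicographically, making grid and search fully deterministic.

Each component is min–max scaled *across the entries of one search*, so
`T_score = FCGM′ + SCGM′ + FCWM′ + SCWM′ ∈ [0, 4]`. Consequences worth
noting: normalization is per target and per search (re-searching a subset
of entries rescales components — asserted in tests); a component that is
constant across the search is mapped to all-zero and contributes nothing
to ranking; and componentwise raw dominance implies a T_score ordering.
An optional scale factor multiplies T_score for display only and can
never change the ranking. The optimum is the argmin of T_score with ties
broken by smaller entry–target distance, then lexicographic entry
coordinates, so reruns always name the same entry. Search results are
memoized in memory keyed by target, box, radius, step and content hashes
of the scene, which makes interactive refinement (re-querying trajectories
against a finished search) free; a disk cache was considered and rejected
as the CLI is single-invocation.

## Comparison metrics

Path length is measured from the target to the first labeled voxel
encountered marching from the entry toward the target (step: half the
minimum voxel edge) — the outer boundary of the parcellation stands in
for the cortical surface, since the pipeline has no mesh input. An entry
already inside tissue degenerates to the full entry–target distance.
Entry-point separation is the straight-line (chordal) 3D distance, not a
geodesic over the box faces. Angular separation is the clamped-arccos
angle between the two entry−target vectors, in [0°, 180°].

## Synthetic scenes

The phantom generator emulates the four inputs: an ellipsoid (semi-axes
0.42 of the grid extent) partitioned into azimuthal sectors around z as
"atlas regions"; jittered, gently bowed polyline bundles between region
centroids as the tractogram; an SC matrix that counts the *actual*
endpoint labels of the generated streamlines (consistent with the
tractogram by construction); and a symmetric FC matrix of clipped
Gaussian baseline noise with hub rows/columns amplified additively. One
`numpy` Generator seeded by the spec drives all sampling, so a seed fully
determines the scene byte-for-byte. Defaults — a 64³ grid of 2 mm
isotropic voxels, eight regions, ten-streamline bundles with 2 mm jitter,
baseline FC noise σ = 0.05 — echo a desk-scale diffusion acquisition and
keep a full five-face search around three seconds; smaller grids (24³,
32³) are used where a test only needs the bookkeeping, and the brute-force
oracle checks run at the full 64³.

The planted-hub scene pins the method's headline behaviour: sector 1
(centered on +x) gets an amplified FC row (+0.7 in absolute value) and
80 of the scene's streamlines spread over four partners, making its node
strengths at least 3× any other region's (measured ≈ 4.8–5.6× functional,
≈ 3.5× structural across seeds). Because grid, ellipsoid and sector map
are exactly mirror symmetric under x → −x (the grid is centered on the
origin and sector count is even), the +x and −x trajectories to the
origin intersect *identical* total grey-matter volume, so any damage
difference is purely connectional. The scene's ground truth records both
trajectories' raw damage computed by a direct all-voxel distance scan
that bypasses the geometry module.

What the phantom does not emulate: realistic BOLD covariance structure,
curved fasciculi and fanning/crossing fibre geometry, partial-volume
effects at grey/white boundaries, skull and scalp layers, and lesion mass
effect. Passing tests therefore demonstrate the correctness of the
scoring, extraction and search machinery and the hub-avoidance behaviour
it implies — not clinical validity on patient data.

## Numerical choices and edge cases

- Symmetry tolerance on load: 1e-8 absolute; asymmetry beyond it is
  averaged away with a warning. Structural entries must be nonnegative.
- Degenerate min–max (max = min) maps to all zeros; an empty entry list
  is an error.
- A tube with coincident entry and target, or nonpositive radius, is
  rejected; a tube wholly outside the volume returns an empty inventory.
- Voxel lookup rounds continuous voxel coordinates to the nearest index
  (voxel centers at integers); points outside the grid get label 0.
- A spacing larger than the smallest box edge is an error; spacing equal
  to an edge degenerates to face corners.
- Risk-map volumes use sentinel −1 outside entry voxels; entries whose
  nearest voxel falls outside the grid are clipped to the boundary, and
  collisions keep the larger T_score.

## Known limitations

Brain-shift and tissue deformation are not modelled, so scores for
deep-seated targets under large retraction are optimistic. Vessel
avoidance and no-go regions beyond the base face are out of scope. The
only centrality implemented is node strength; the T_score range [0, 4]
follows from the literal component sum, and any external rescaling of
published damage values is display-only here.
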