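# elopath

Connectivity-weighted *eloquence* scoring and exhaustive entry-point search
for neurosurgical access-path planning.

When a neurosurgeon plans a trajectory to an intracranial target, the
traditional heuristics (shortest path, avoid visible vessels and classic
eloquent cortex) ignore how important the traversed tissue is *within the
patient's own brain networks*. This package estimates that connectional
cost. It is aimed at researchers in surgical planning and connectomics who
have, for one subject:

- a functional connectivity (FC) matrix and a structural connectivity (SC,
  streamline-count) matrix over an atlas of N grey-matter regions,
- the labeled parcellation volume (NIfTI) used to build those matrices,
- a whole-brain tractogram (TRK/TCK) in world coordinates,
- one or more target points in mm.

## The model

Each region k gets two node-strength ("unsigned weighted degree") scores:

    FCGM_k = Σ_j |FC(k, j)|                  (functional, unitless)
    SCGM_k = Σ_j |SC(k, j)| / L_k            (structural, fibres/mm³)

where L_k is the region volume, cancelling the size advantage of large
regions. Each streamline p inherits the mean regional score over the set
ROIs(p) of regions it intersects anywhere along its course:

    FCWM_p = mean_{i ∈ ROIs(p)} FCGM_i ,   SCWM_p = mean_{i ∈ ROIs(p)} SCGM_i

A candidate trajectory (entry → target, radius r, default 5 mm) is the
volume swept by a sphere along the segment — a capsule. Its raw damage has
four components: score-weighted intersected grey-matter volume
(FCGM_path = Σ_k V_k·FCGM_k, likewise SCGM_path) plus the summed scores of
intersected fibres (FCWM_path, SCWM_path). Candidate entries form a 10 mm
grid on five faces of a box enclosing the head (the base face is excluded);
for one target every entry is evaluated, each component is min–max scaled
across the search, and

    T_score = FCGM′ + SCGM′ + FCWM′ + SCWM′   ∈ [0, 4]

is painted back over the box as a colour-mappable risk map whose argmin is
the proposed entry point.

## Worked example

```
elopath phantom --seed 3 --grid 64 --outdir scene/
elopath search --fc scene/fc.csv --sc scene/sc.csv \
    --parcellation scene/parcellation.nii.gz --tractogram scene/tractogram.trk \
    --target 0,0,0 --outdir run/
```

prints

```
risk map written to run/risk_map.csv and run/risk_map.nii.gz; optimal entry (64, -50, -20) with T_score 0.2902
```

`run/risk_map.csv` has one row per candidate entry (845 for this scene):
its coordinates, the four raw damage components, their normalized values,
`t_score` and an `is_optimal` flag. The optimal entry is the grid point
whose 5 mm capsule to the target carries the least total normalized
connectional damage — here a T_score of 0.2902 out of a possible 4, i.e. a
trajectory whose every component sits near the bottom of its distribution.
`run/risk_map.nii.gz` holds T_score at each entry's nearest voxel and −1
elsewhere, ready for green-to-red colour mapping over the head.

`elopath scores`, `elopath tube` and `elopath compare` expose the
intermediate stages: score tables per region/fibre, the damage report of a
single trajectory (with per-region breakdown), and a side-by-side
comparison of two trajectories (path lengths, damages, Euclidean distance
between entries, angular separation at the target).

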