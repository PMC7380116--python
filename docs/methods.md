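# Methods

## Coordinate conventions

All world coordinates are RAS millimetres. Two spaces are distinguished:
`patient` (scanner-native) and `template` (the group space in which priors
are pooled). Points carry their space tag; cross-space arithmetic is
refused and movement between spaces goes through an explicit 4×4 affine.
In clinical use the patient→template map comes from nonlinear MNI-152
normalization; this package consumes a supplied transform and its surrogate
is affine — estimating registrations is out of scope, and the affine
surrogate preserves everything the downstream statistics need (pooling,
flipping, centroid geometry) while remaining exactly invertible.

NIfTI voxel indices are 0-based; voxel→world goes through the image affine.
Binary-mask membership is nearest-voxel lookup without interpolation, which
is the natural reading of a binary segmentation.

## Risk model

A trajectory is sampled at 128 evenly spaced nodes from entry to target
inclusive. At each node the distance to the nearest vessel *surface* is the
centerline distance minus the local radius, floored at zero. Node risk is
clamped-linear: 0 beyond d_max = 10 mm, rising to 1 at the safety margin m
(default 3 mm). The cumulative score is the node mean; when the closest
node breaches the margin the score is replaced by 1 + (m − min d)/m. The
historical planning software never published its exact aggregation formula,
so this one was designed to satisfy every property its documentation
states: 128 nodes, scaling by the user-set minimum distance, strict
equivalence between "score > 1" and "a node within the margin", monotone
response to vessel retreat, and scale equivariance. Those properties — not
the specific falloff shape — are what the tests pin down.

The safety margin is electrode radius + mean implantation error + 3·SD.
The SD is population (ddof = 0) by default because the source equation
writes σ without qualification; sample SD is available via a flag.

## Constraint filtering and selection

Hard constraints are applied in a fixed order — intracerebral length
≥ 90 mm, drilling angle ≥ 30° from orthogonal, intersection of any node
with a critical-structure region, cumulative risk ≥ 1 — and each rejection
is attributed to the first failed constraint, giving an auditable ledger.
Survivors are sorted by cumulative risk ascending with ties broken by
higher gray-matter ratio then shorter length. Making risk the primary key
and gray matter the tie-break is an interpretive choice (the workflow being
emulated "optimizes for gray matter" and presents "lowest risk first");
re-ranking rather than re-positioning survivors is likewise a choice the
source leaves open. The tie-break chain makes the surviving order a total
order, so filtering is independent of candidate input order.

Intracerebral length runs from the first cortex intersection along
entry→target to the target, consistent with the entry-point definition.
Multi-electrode conflicts are resolved greedily in strategy order: each ROI
takes its lowest-risk survivor whose minimum segment-to-segment distance to
every already-selected electrode exceeds 10 mm, advancing down the risk
order as needed. Spacing is measured between intracerebral segments, not
infinite lines, because extracranial convergence of trajectories is
irrelevant. Greedy sequential selection mirrors the interactive clinical
workflow; joint optimization over electrodes is out of scope.

## Spatial priors

Per (ROI, role ∈ {entry, target}): trajectories are mapped to template
space, the entry point having first been re-derived in patient space as the
cortical-surface intersection of the planned path; left-sided points are
then reflected (x → −x) to the canonical right hemisphere. Flipping must
follow the template transform — reflection does not commute with
x-translation, and a test documents this operation order.

A prior is created only when the ROI was implanted at least `min_count = 5`
times and is not label-excluded (lesional, patient-specific targets).
Dispersion is summarised by WCSS = Σ‖x − x̄‖². The membership region is the
intersection of (a) a centroid ball of radius max point-to-centroid
distance + 2 mm and (b) the union of 5 mm balls around the training points.
The source material never states how a prior region is bounded; this
intersection keeps the region compact, lets it follow the cloud's shape,
and guarantees that every training point is a member of its own prior
(self-through rate 100%). Both radii are configurable. An optional per-role
WCSS ceiling (disabled by default) drops clouds too dispersed to be useful
— this is how an ROI can carry a target prior but no entry prior.

Validation reports integer percentages rounded half away from zero, which
matches how such tables are printed (e.g. 16/17 → 94%), alongside exact
fractions in the JSON twin.

## Adaptive learning

The K-NN classifier stores labeled template-space points (label =
(ROI, role)) with k = 5, uniform weights, Euclidean metric. Entry and
target points are classified against separate candidate sets by default
(role restriction), since entry and target priors are built independently;
a joint label space is available by leaving the role unset. Vote ties are
broken by the smaller mean neighbor distance, then lexicographic label
order; equal distances rank by insertion index. These tie-breaks are
arbitrary but deterministic — determinism is required for reproducible
state sequences, and the brute-force oracle in the tests applies the same
rule, so agreement is exact rather than statistical.

Ingestion partitions the new cohort into `n_folds = 5` seeded random folds
of equal size (±1). Each fold appends its canonical entry/target points to
the model — append-only; no initial point is ever removed or relabeled —
and every prior is rebuilt from the augmented cloud with the same
membership rule as initial construction, so "dynamic modification" has a
single source of truth. A prior can emerge for a label that newly reaches
the 5-point threshold. `decision_region_volume` grid-samples the bounding
box to quantify how a label's decision region changes across states.

## Synthetic phantom and cohorts

The phantom is deliberately spherical: an 80 mm watertight icosphere shell
for cortex, a 70–78 mm concentric band for gray matter (2 mm isotropic
voxels), 40 random tube segments (radii 0.5–2 mm) for vasculature, 6 paired
entry/target ball regions (targets at 25–50 mm depth) and a central
critical structure. Spheres keep analytic oracles available — radii,
normals, interior tests — and nothing in the method depends on anatomical
realism. What the phantom does *not* emulate: realistic vascular topology,
sulcal geometry, MRI intensities, inter-patient anatomical variability, or
registration error. Passing tests therefore demonstrate the correctness of
the algorithms under their stated geometric contracts, not clinical
performance on real anatomy.

Historical cohorts scatter entry/target points isotropically (Gaussian, σ
given in mm) around per-ROI anchor pairs, with entries projected back onto
the cortex; hemisphere is tagged by the sign of the entry x coordinate.
The dispersion estimator √(WCSS/3n) recovers the generating σ, which the
tests check at n = 200 within 15%.

The prospective-validation fixture reconstructs, by design, the published
per-region through/outside counts: training clusters use σ = 2.5 mm
(108 electrodes, 12 patients, 14 ROIs, sides alternating by patient with
left-side coordinates mirrored); "through" test points sit within 1 mm of a
training point, which places them inside every membership criterion for any
seed; "outside" points sit at twice the membership radius from the
centroid, unambiguously outside and robust to tolerance choices. The
posterior-insula entry cloud uses σ = 30 mm and the fixture's build
settings include an entry-WCSS ceiling of 1500 mm² — well above the
χ²-tail of the tight clouds and well below that of the dispersed one — so
that exactly 13 entry and 14 target priors form. The full prospective
cohort is 210 electrodes; the 47 beyond the 163 analyzable ones model
patient-specific (non-generalizable) implantations, excluded from the
through-prior table but ingested by the adaptive folds. Counts are
seed-invariant by construction; coordinates are not.

## Numerical choices and problem sizes

- Ray–mesh intersection is vectorised Möller–Trumbore over all faces with a
  10⁻⁹ minimum ray parameter; no spatial index, so results cannot depend on
  an acceleration structure. Interior tests use ray-crossing parity along a
  fixed generic direction.
- The entry angle uses the outward normal of the nearest face, accepted
  within a 0.5 mm snap tolerance (mesh discretization noise), and takes
  |cos| so the result lives in [0°, 90°] regardless of winding convention.
- Icosphere subdivision 3 (1280 faces) for phantoms: facet error ≈ 0.2 mm
  sagitta at radius 80 mm, far below every tolerance in the pipeline.
- Trajectory CSVs are written with 17 significant digits and read with
  pandas' round-trip float parser so coordinates survive I/O bit-exactly.
- Planning sweeps use 8 entry × 3 target samples per ROI and 3-ROI
  strategies, sized so a 50-scene compliance sweep completes in seconds;
  candidate counts are a config knob, and the exhaustive-argmin test runs a
  400-candidate grid.

## Known limitations

- The affine template surrogate cannot reproduce nonlinear normalization
  residuals; real pooled clouds would be wider.
- The exact historical risk-score normalization is unknown; only its
  published contract is guaranteed (see above).
- The membership-region geometry is this package's definition, chosen for
  testability; other compact region definitions would yield slightly
  different through-prior rates on real data.
- The criterion by which an entry cloud is "too dispersed" for a prior is a
  configurable WCSS ceiling, disabled by default, because no quantitative
  published threshold exists.
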