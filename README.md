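# seegplan

Computer-assisted trajectory planning for stereoelectroencephalography
(SEEG), with spatial priors learned from previous implantations and an
adaptive K-nearest-neighbor refinement of those priors.

SEEG implants 10–16 depth electrodes into the brain of a patient with
drug-refractory focal epilepsy to localize the epileptogenic zone. Each
electrode follows a straight trajectory from a cortical entry point to a
deep target, and the dominant surgical risk is hemorrhage from vessels near
the path. `seegplan` implements the full planning pipeline as a library and
CLI, exercisable end to end on a seeded synthetic head phantom:

- **Hard-constraint planning.** Candidate entry/target pairs are filtered by
  intracerebral length (< 90 mm), drilling angle from orthogonal to the
  surface (< 30°), avoidance of critical structures, and a vascular risk
  score, then returned risk-stratified (lowest risk first), optimized for
  gray-matter sampling, with > 10 mm between electrodes.
- **Risk score.** 128 nodes are placed along the trajectory; at each node
  the distance dᵢ to the nearest vessel surface yields a node risk
  clamp((d_max − dᵢ)/(d_max − m), 0, 1) with d_max = 10 mm and safety margin
  m. The cumulative score is the node mean, lifted above 1 whenever
  min dᵢ < m, so *score > 1 ⇔ the margin is breached*. The margin itself is

  &nbsp;&nbsp;&nbsp;&nbsp;m = electrode radius + Σ‖i − î‖/n + 3σ

  (mean and standard deviation of historical implantation error).
- **Spatial priors.** Historical trajectories are mapped into a group
  template space, left-hemisphere points are flipped to the canonical right
  side, and each region of interest (ROI) targeted ≥ 5 times yields an entry
  prior and a target prior: a point cloud with centroid, within-cluster sum
  of squares WCSS = Σ‖x − x̄‖², and a binary membership region. Prospective
  trajectories are validated by the fraction passing through both priors.
- **Adaptive learning.** A k = 5, uniform-weight, Euclidean K-NN classifier
  over the labeled template-space points ingests new implantations in
  seeded folds and rebuilds every prior from the augmented cloud, so the
  priors track evolving planning practice.

## Worked example

Generate the synthetic prospective-validation cohorts (108 training
electrodes over 12 patients; 163 analyzable test electrodes over 20
patients), build the priors, and validate:

```bash
$ seegplan fixture table2 --seed 1 --out fx
fixture cohort: 163 test trajectories, 129 through (79%)
$ seegplan priors validate --trajectories fx/test.csv --priors fx/priors.json --out val
129/163 trajectories through priors (79%)
$ head -4 val/report.csv
region,n,through,outside,through_pct
orbitofrontal,15,13,2,87
amygdala,17,16,1,94
anterior_hippocampus,11,8,3,73
```

79% of the prospective cohort passes through both the entry and the target
prior of its ROI; the per-region rows break that down (e.g. 13 of 15
orbitofrontal trajectories through, 87%). The posterior insula gets a
target prior but no entry prior — its entry cloud is too dispersed — so its
verdict rests on the target test alone.

Score a single trajectory against the seed-1 phantom's vasculature:

```bash
$ seegplan score trajectory --entry 0,0,120 --target 0,0,10 --phantom-seed 1
{
 "cumulative_risk": 0.09550931990722028,
 "min_vessel_distance_mm": 5.188486880266386,
 "margin_mm": 3.0,
 "length_mm": 110.0
}
```

The closest vessel surface is 5.19 mm away — outside the 3 mm margin, so
the cumulative risk stays well below 1.

Plan three electrodes from the library:

```python
import seegplan as sp
ph = sp.make_phantom(1)
res = sp.optimize_plan(sp.Strategy.of("roi_01", "roi_02", "roi_03"), ph, seed=2)
for roi, c in res.selected.items():
    print(f"{roi}: risk={c.cumulative_risk:.3f} gm={c.gm_ratio:.2f} "
          f"length={c.length:.1f} mm angle={c.angle:.1f} deg (rank {res.ranks[roi]})")
```

```
roi_01: risk=0.000 gm=0.17 length=55.8 mm angle=21.0 deg (rank 0)
roi_02: risk=0.003 gm=0.12 length=59.8 mm angle=13.8 deg (rank 0)
roi_03: risk=0.000 gm=0.22 length=42.6 mm angle=20.0 deg (rank 0)
```

All three selections are the head (rank 0) of their risk-sorted candidate
list: the regions are far apart, so the 10 mm spacing constraint never
forces a lower-ranked pick.

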