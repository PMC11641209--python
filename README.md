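# amphid

Quantitative analysis of the bilateral spatial layout of the *C. elegans*
amphid chemosensory neurons from segmented nuclear centroids.

The amphids are the worm's paired lateral chemosensory sensilla; each houses a
stereotyped set of sensory neuron classes (ASJ, AWC, ASE, ASH, AWA, ADF, AWB,
ASG, ASI, ADL, ASK) whose cell bodies normally sit in two roughly parallel
half-planes, one per side of the head.  Mutations affecting synaptic release
can disarrange this layout: the two halves tilt toward each other dorsally and
bilateral partner neurons drift apart.  This package turns a table of
segmented nuclear centroids (one row per nucleus: position in µm, nuclear
size, reporter intensity) into the quantities that describe that layout, and
provides the statistics to compare strains.

## What it computes

For each worm, with left/right point sets $X_L, X_R \subset \mathbb{R}^3$:

- **Per-side best-fit planes** by orthogonal least squares: the plane through
  the centroid whose unit normal $\hat{n}$ minimises
  $\sum_i \left( \hat{n}^\top (x_i - \bar{x}) \right)^2$, i.e. the smallest
  principal axis of the centred points (closed form via SVD).
- **Inter-plane angle** $\theta = \arccos\,\lvert \hat{n}_L^\top \hat{n}_R \rvert \in [0^\circ, 90^\circ]$,
  the acute dihedral angle between the two side planes, plus a flag for
  whether the wedge opens ventrally or dorsally.
- **Bilateral pair distances** $d_c = \lVert x_{c,L} - x_{c,R} \rVert$ for each
  class $c$ identified on both sides, pooled by the class's dorso–ventral
  rank $r \in \{1,\dots,6\}$ (ASJ = 1, AWC = 2, {ASE, ASH} = 3, {AWA, ADF} = 4,
  {AWB, ASG} = 5, {ASI, ADL, ASK} = 6, ventral to dorsal).

Across cohorts:

- **Rank regression**: OLS line through the per-rank mean distances
  $\bar{d}_r$ against $r$.
- **Slope-difference permutation test**: the statistic is the OLS slope of
  $\bar{d}_r^{\mathrm{ref}} - \bar{d}_r^{\mathrm{mut}}$ on $r$; its null is
  built by shuffling all distances within each rank between the cohorts
  (10,000 resamples by default), preserving per-rank group sizes.
- **One-way ANOVA** on the per-worm angles across strains.

Identification is automated: a rule cascade mirrors how experimenters label
the nuclei by eye (dorsal collinear triplet ASK/ADL/ASI first, then ASH as the
largest/brightest ventral nucleus, then ASJ/AWC/ASE by their direction from
ASH, finally the middle four by intensity and medial/lateral position), and
marks any nucleus it cannot call unambiguously as `UNIDENTIFIED`.  Worms with
fewer than 4 complete bilateral pairs are excluded.

Because no public centroid dataset exists, the package ships a synthetic
layout generator (`amphid.synthetic`) with known ground truth — generative
tilt, per-rank displacement, noise, dropout — so every stage is testable and
parameter recovery is measurable.

## Worked example

```python
from amphid import AnalysisConfig, LayoutParams, generate_cohort, run_compare

wt, _ = generate_cohort(LayoutParams(
    true_angle_deg=15.51, noise_sd=0.5, n_worms=70, seed=61, strain="WT"))
mut, _ = generate_cohort(LayoutParams(
    true_angle_deg=29.09, noise_sd=0.5, n_worms=59, seed=62, strain="unc-13",
    rank_displacement={2: 1.5, 3: 1.5, 4: 1.5}))

report = run_compare(wt, mut, AnalysisConfig(n_perm=10000, seed=63))
```

(Here the labels generated with the cohorts are ignored: `run_compare`
re-identifies every nucleus from geometry and signal cues.)  The report for
this run contains:

```
WT      angle 16.17 ± 2.84 deg   (n=70 kept)
unc-13  angle 39.49 ± 2.76 deg   (n=59 kept)
ANOVA   F = 2216.02, p = 3.0e-82
rank-regression slopes: WT -0.773, unc-13 -1.646 µm/rank
slope difference: observed +0.872 µm/rank, one-sided p = 1e-04 (10,000 permutations)
```

Reading it: the mutant cohort's halves meet at a much larger dihedral angle
(the extra lateral displacement of the inner ranks adds to the generative
29.09° tilt), its distance-vs-rank regression is roughly twice as steep as
the reference's, and the within-rank permutation test rejects the hypothesis
that the two cohorts' distances are exchangeable.  The observed statistic is
*positive* because the more-separated ranks (2–4) lie below the midpoint of
the rank axis — see `docs/methods.md` for the tail convention.

## Command line

```sh
amphid simulate --config sim.yaml --out cohort.csv --truth truth.csv --seed 1
amphid analyze  --in cohort.csv --config cfg.yaml --out report.json
amphid compare  --a wt.csv --b mut.csv --n-perm 10000 --seed 1 --out report.json
```

Input is a flat CSV with columns `worm_id, strain, condition, nucleus_id,
class, side, ap_um, dv_um, ml_um, size, intensity` (see `amphid.io`).  Exit
code 2 signals a validation error.

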