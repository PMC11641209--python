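# Methods

## The measurement model

A worm's amphid layout is summarised from the 3D centroids of its segmented
neuronal nuclei, expressed in a per-animal right-handed frame: axis 0
anterior→posterior (AP), axis 1 ventral→dorsal (DV), axis 2 left→right
(ML), midline at ML = 0, all in µm.  No registration across animals is
performed; every quantity below is invariant to the worm's pose in the
microscope frame (plane fitting is translation-invariant and
rotation-equivariant, distances are Euclidean), so only the ML-axis sign
conventions of the frame matter, and only for side naming.

**Plane fit.** Each side's identified nuclei are summarised by the
orthogonal-least-squares plane: with centred coordinates $C$, the normal is
the right singular vector of the smallest singular value of $C$, the plane
passes through the centroid, and the RMS residual is
$s_3/\sqrt{n}$ for smallest singular value $s_3$.  Normals are canonically
oriented (ML component ≥ 0, ties broken by DV then AP) so downstream code
never sees a sign ambiguity.  Fits require ≥ 3 points; configurations whose
second-smallest-to-largest singular-value ratio is below $10^{-10}$ are
rejected as collinear.  Minimising *squared* perpendicular distances is the
standard best-fit-plane reading; an L1 fit would lack a closed form and
reproducibility.

**Angle.** The acute dihedral angle
$\theta = \arccos\lvert\hat n_L^\top \hat n_R\rvert$ is reported in degrees,
rounded to 2 decimals in reports.  Because $\theta \ge 0$, the estimator is
positively biased at small true angles under positional noise (the tests
exercise this); at the angles of interest (≥ 15°) the residual bias at
0.5 µm noise is a fraction of a degree.  Whether the wedge opens ventrally
or dorsally is reported separately, by locating the planes' intersection
line relative to the joint centroid.

**Pair distances and ranks.** A class contributes one distance per worm iff
it is identified on both sides.  Distances are pooled by the class's
dorso-ventral rank (ASJ = 1, AWC = 2, {ASE, ASH} = 3, {AWA, ADF} = 4,
{AWB, ASG} = 5, {ASI, ADL, ASK} = 6); ranks 1-2 carry one class, 3-5 two,
6 three, so pooled rank means are weighted by class multiplicity.  The
default pools all pair distances of a rank across worms; a per-worm-mean
first variant (`pooling="per_worm"`) is available because the two differ
when worms contribute unequal numbers of pairs.

## Inference

**Cohort regression.** OLS of the per-rank mean distances on the rank values
present (unweighted across ranks).  With ≤ 6 points and 2 parameters this is
computed from the closed-form normal equations.

**Slope-difference test.** The statistic is the OLS slope, on rank, of the
per-rank differences (reference mean − comparison mean), computed over the
ranks both cohorts cover; it is antisymmetric under swapping the cohorts and
identical to the difference of the two cohorts' own slopes whenever their
rank coverage matches (OLS is linear in the response).  The null
distribution shuffles all distances within each rank and reassigns them to
the cohorts preserving per-rank group sizes; 10,000 resamples by default;
p-values use the add-one convention $(1 + \#\,\text{extreme})/(n_{\rm perm}+1)$
and so are never zero.  Resampling is without replacement (a permutation
test); a with-replacement bootstrap mode exists for sensitivity analysis
only — its null is visibly wider on the same data and it should not be used
for primary inference.

**Tail convention.** The alternative of scientific interest is a mutant
whose *inner* dorso-ventral ranks (2-4) are more separated than the
reference.  Those ranks lie below the midpoint (3.5) of the rank axis, so
this alternative pushes the reference-minus-mutant slope **positive**;
the default one-sided test is therefore upper-tailed
(`alternative="greater"`).  Lower-tailed (`"less"`, the mirror-image
convention $p = (1+\#\{\text{null} \le \text{obs}\})/(n_{\rm perm}+1)$) and
two-sided options are exposed.  Both 5% and 95% empirical percentiles of the
null are reported for plotting reference lines.

**Angles across strains.** One-way fixed-effects ANOVA
(`scipy.stats.f_oneway`) on per-worm angles, with group means, SDs and sizes
reported.  No mixed-effects modelling of worm-level clustering of distances
is attempted: distances are pooled within ranks, consistent with how the
permutation null is constructed.

## Automated identification

The rule cascade encodes the visual identification cues, each step consuming
the nuclei it matches:

1. *Dorsal triplet.* The three most dorsal nuclei are checked for near
   collinearity (max perpendicular deviation from their joint total-least-
   squares line < 2 µm by default); AP order gives ASK (anterior), ADL, ASI
   (posterior).  On failure the three are consumed unlabeled — proceeding
   would cascade misassignments into later steps.  Collinearity is this
   step's ambiguity control; a best/second-best score ratio is not
   meaningful for "dorsality", which has no natural origin.
2. *ASH.* The remaining nucleus on the ventral half (DV below the pool
   median) maximising size × intensity.  If the runner-up is within the
   ambiguity margin (ratio < 1.1), both are consumed unlabeled and the
   dependent steps 3-4 are abandoned.
3. *ASJ / AWC / ASE.* Remaining nuclei less than 1.5 µm dorsal of ASH are
   classified by the direction φ of their offset from ASH in the AP-DV
   plane (φ = 0 posterior, negative ventral): anterior (|φ| > 90°) → AWC;
   posterior with φ ≥ −25° → ASE; ventro-posterior (φ < −25°) → ASJ.
   Directions within 5° of a sector boundary, or sectors holding more than
   one candidate, stay unlabeled.
4. *Middle four.* The four remaining nuclei (dorsal of ASH, ventral of the
   triplet) are split at their AP median; the brighter of the posterior
   pair is ASG and of the anterior pair ADF (margin 1.1 each); of the last
   two, the one maximising size / |ML| (larger and more medial) is AWA, the
   other AWB.  If dropout leaves this group at any size other than four,
   it is left unlabeled rather than guessed.

All thresholds (collinearity tolerance, margin, sector geometry, DV band,
midline dead zone) are estimator parameters with the defaults above; none is
asserted to be the value experimenters use implicitly.  Side assignment
splits at the median ML coordinate with a 0.1 µm dead zone; a cloud entirely
on one side of the recorded midline is assigned wholesale to that side with
a warning.  Worms with fewer than 4 complete bilateral pairs after
identification are excluded from all downstream statistics (reported and
logged with reason `too_few_pairs`; unfittable sides give
`degenerate_geometry`).

## The synthetic generator

The generator emulates segmented centroid tables, not images; segmentation
is upstream of this package.  A worm is built from a fixed 11-class template
spanning ~11 µm AP × 14 µm DV per side, with relative size/intensity values
realising the identification cues.  Deformation has two independent modes,
because the underlying anatomy does not commit to one mechanism:

- **Rigid tilt** (`true_angle_deg`): each half rotates by half the angle
  about an AP axis through the dorsal hinge (the dorsal-most template point
  at the midline), opening the wedge ventrally.  The recovered inter-plane
  angle equals the generative angle exactly (to 1e-6°) at zero noise.
- **Per-rank displacement** (`rank_displacement`): extra lateral offset away
  from the midline for selected ranks on both sides — the "inner ranks
  spread, halves stay parallel" pattern.  This mode changes pair distances
  directly; because a DV-correlated displacement also tilts the fitted
  planes, it raises the measured angle as a side effect.

Gaussian positional noise (sd `noise_sd`, isotropic, i.i.d. per nucleus) and
independent per-nucleus dropout complete the model.  Sizes and intensities
are template values × lognormal jitter (sd 0.1 on the log scale), keeping
identification reliable but degradable.

Two numerical choices make the ground truth exactly recoverable.  The
per-class lateral offsets are decorrelated (least-squares) from the AP/DV
coordinates inside `make_template`, so the untilted half-layout's best-fit
plane is exactly sagittal — otherwise the class-specific offsets would bias
the fitted normals and zero-noise angle recovery would not be exact.  The
adjustment is affine in (AP, DV), so the exactly collinear dorsal triplet
stays exactly collinear.  Consequently the generated sides are *not*
coplanar: their residual is the spread of the per-class offsets, identical
on both sides, and carries the medial/lateral identity cues.

**What the generator does not emulate:** real segmentation errors (merged or
split nuclei, spurious detections), anisotropic axial noise from confocal
z-spacing, worm-to-worm template variation, body curvature, and
condition-dependent deformation (restraint squeeze).  Passing tests
demonstrate that the estimators recover the generative parameters of this
model, not that the identification rules are robust to every failure mode of
real imaging.

## Default study conditions

Cohort sizes and generative angles used in the recovery checks mirror the
published group means: 70 worms at 15.51°, 53 at 18.50°, 59 at 29.09°
(microfluidic), 18 at 16.84° and 11 at 42.71° (agar pad), all at 0.5 µm
noise — a conservative value for confocal stacks with sub-µm z-spacing —
with no dropout.  The mutant-pattern fixture displaces ranks 2-4 by 1.5 µm
per side (+3 µm pair distance), a package choice: no published effect size
exists for the displacement itself.  Simulation-based test sizes (type-I
error: 500 replicates × 2,000 permutations on 15-worm cohorts; power: 60
replicates at the published cohort sizes) were chosen so the whole suite
runs in well under a minute while the binomial bands stay informative.

## Known limitations

- Identification assumes at most one nucleus per class per side and ≤ 12
  candidate nuclei per side (extras beyond 12 are dropped by size before
  the cascade); heavily over-segmented data should be cleaned upstream.
- The median-ML side split assumes the head is roughly centred on the
  recorded midline; strongly rolled worms need re-orientation upstream.
- Under dropout, step 4 of the cascade declines to label a partial middle
  four; accuracy under combined dropout and noise is therefore conservative
  (unlabeled, not wrong).
- The permutation test pools distances within ranks and so treats pairs
  from the same worm as exchangeable with pairs from different worms;
  worm-level random effects are out of scope.
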