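# Methods

## Coordinate convention

All geometry is in physical millimetres. Array axes are ordered (x, y, z)
with +x = subject left, +y = posterior, +z = superior; a voxel at index
(i, j, k) has its centre at `origin + index * spacing`. "Left" labels
(vertebral dominance, basilar curve, WMH laterality) always refer to this
frame; `flip_lr` inverts the convention for RAS-ordered data. One fixed
frame makes every left/right label testable against planted ground truth.

## Reconstruction

**Segmentation.** TOF angiography renders flowing blood bright on a dark
background, so a double threshold suffices: voxels with intensity in
[lower, upper] are vessel. Defaults are 850 and 2500 gray levels; the
synthetic intensity model (foreground N(1800, 150), background N(300, 100)
clipped at 0) puts ≥99% of in-vessel voxels inside that window, and the
pipeline's branch labels are invariant to ±50 jitter of the lower
threshold (tested). Foreground connectivity is 26, background 6 — the
standard digital-topology pairing.

**Component selection.** The k largest 26-connected components are kept
(k = 1 for the vertebrobasilar tree). Equal-sized components are ordered
by lexicographically smaller centroid so selection is deterministic.

**Surface and smoothing.** Marching cubes at level 0.5 on the zero-padded
mask gives a closed surface in mm. Taubin smoothing alternates a shrinking
Laplacian step (λ) and an inflating step (μ < 0) with uniform umbrella
weights; with 0 < λ < −μ the filter sits in the pass-band regime that
suppresses voxel staircase without global shrinkage. Defaults λ = 0.5,
μ = −0.53, 10 iterations — a common pass-band choice; on a digitized
sphere these defaults change enclosed volume by ~0.1% where the pure
Laplacian (μ = 0) loses ~2.5% at the same iteration count (tested).
Smoothing affects the exported surface only; centerlines are computed from
the voxel mask, so mesh smoothing never perturbs morphometry.

## Centerline extraction and labeling

The mask is thinned to a one-voxel skeleton (Lee et al. 3D thinning as
implemented in scikit-image). Skeleton voxels with ≠2 neighbours form
junction/end clusters; 26-connected clusters are contracted to single
graph nodes at their centroid, and chains of degree-2 voxels become edges
carrying the voxel polyline and the Euclidean-distance-transform radius at
each point. Thinning artifacts are then removed:

* leaf chains shorter than the **prune length** (default 3 mm — below the
  VA diameter scale, so thinning spurs are eaten but true branches are
  not) hanging off a junction are deleted;
* small loops that thinning occasionally closes near the junction
  (self-loops, parallel chains, short cycles up to 4× the prune length)
  are opened by removing their longest edge. Longer cycles (a genuinely
  toroidal mask) are left and rejected downstream with a cycle error.

A valid tree has exactly one degree-3 node — the vertebrobasilar
confluence — and three endpoints. The branch whose far endpoint is most
superior is the basilar artery (its endpoint must lie above the
confluence, otherwise an error names the violation); of the remaining two,
the branch with greater mean x is the left vertebral artery. Branch
traversal is fixed caudal → cranial so torsion signs are reproducible.

**Resampling.** Each branch polyline is fit with a cubic smoothing spline
(residual budget `smoothing_mm`, default 0.4 mm — the scale of half-voxel
quantization jitter) and resampled at uniform 0.25 mm arc steps. The
smoothing default was chosen so the maximum |κ| on straight-tube fixtures
stays below 0.05 /mm, since derivative stability is the limiting error of
the curvature estimates; on analytic helices the resampled arc length is
within 1% of the closed form.

Endpoint behaviour of thinning is worth noting: skeletons retract by
roughly one tube radius at blunt tube ends, so the detected "basilar top"
of a phantom sits ~1 mm inside the planted tube end, and the junction
node sits slightly below the analytic confluence where the two VA tubes
merge. Mean centerline error stays below one voxel (tested), but
chord-referenced quantities measured through the full voxel pipeline carry
a ~0.2 mm bias relative to planted values.

## Morphometry

For a uniformly resampled branch r(s):

* κ(s) = |r′×r″| / |r′|³ and τ(s) = (r′×r″)·r‴ / |r′×r″|², derivatives by
  central finite differences (one-sided at the ends). Where κ < 1e-4 /mm
  the osculating plane is indeterminate and τ is reported as 0. Torsion is
  summarized as mean |τ| because its sign depends on traversal direction;
  curvature is summarized by both mean and median (the median is robust to
  junction-end transients and is the statistic used downstream).
* tortuosity = arc/chord − 1 (dimensionless, 0 iff straight).
* volume: every mask voxel is assigned to the nearest centerline point
  across all three branches, so the three branch volumes partition the
  mask volume exactly.
* cross-section: π r(s)² from the interpolated inscribed radius; mean
  diameter = 2 × median inscribed radius, robust to the junction bulge.

**Dominance rule.** The VA with the larger mean diameter is dominant when
|Δdiameter| ≥ 0.3 mm (with a 1e-9 epsilon so values stated at 0.1 mm
printed precision compare as written); below that the pair is "even". The
0.3 mm threshold excludes artifact-scale differences.

**Basilar bending.** The chord runs from the confluence to the basilar
top. The deviation extent is the maximum 3D distance of the BA centerline
from the chord; the signed lateral deviation is the x-component of the
displacement at that point (+ = left). Direction is "even" when the
lateral component stays inside the even-threshold band (default 1.0 mm —
no published threshold exists for the "even" class, so it is an exposed
parameter; 1.0 mm is twice the half-voxel noise floor of a typical 1 mm
acquisition). Both extent and lateral component are emitted; the lateral
component is the default logistic predictor because the laterality
hypothesis is about left–right asymmetry, not out-of-plane bowing.

## WMH scoring

Lesions arrive as annotated records (region VA/BA/PCA by supplying artery
territory, side of the virtual falx split, maximum diameter, confluence
flags) — the form a blinded FLAIR read produces; image-space lesion
segmentation and the anatomical templates that define the territories are
out of scope. Scoring follows the ARWMC ordinal scale per region-side:
0 none, 1 focal only, 2 any confluent lesion, 3 diffuse involvement.
Laterality: higher score wins; on a tie the side with more lesions ≥5 mm
wins (sub-5 mm focal lesions count for presence and scores but not for the
tie-break); a double tie is "even" — no further fallback is defined, so
"even" is final. A subject with any lesion is WMH, otherwise control. The
PCom gate keeps subjects with both posterior communicating arteries
hypoplastic/no-flow *and* at least one PCA-region lesion: only there does
basilar geometry plausibly drive posterior-cerebral perfusion asymmetry.
Bilateral-even subjects are kept as a third category in association tests
by default (coded 0); 2×2 Fisher tests drop them by construction.

## Statistics

* **Mann-Whitney U**: U = min of the two orientations; z from the
  tie-corrected normal approximation, by default without continuity
  correction (switchable — the corrected variant tracks the exact
  permutation p at very small n); r = |z|/√N.
* **Fisher exact**: two-sided p by probability ordering (sum of
  fixed-margin table probabilities no larger than the observed one, with a
  1+1e-9 relative guard against ties lost to rounding). The odds ratio is
  the conditional MLE: the noncentral hypergeometric odds parameter whose
  conditional expectation equals the observed cell, found by bracketed
  Brent root-finding on log ψ (relative tolerance 1e-10); an observed
  count at the edge of its support is flagged 0 or ∞, a degenerate margin
  gives NaN with p = 1. The sample cross-product OR is also emitted.
* **Spearman** on laterality codes right = −1, even = 0, left = +1, with
  average-rank ties and the t-approximation p.
* **Logistic regression** via Newton/IRLS (statsmodels) with an intercept;
  errors on no events, rank deficiency, and perfect separation (detected
  or inferred from diverged coefficients).
* **Battery**: group differences (age, BA length/tortuosity/area),
  risk-factor × group and laterality × dominance/curve Fisher tests, the
  dominance × curve Spearman, and the two PCA-region logistic models
  (severity ~ age + hypertension on the whole cohort; laterality ~ signed
  deviation on the PCom-gated subset). The Bonferroni family is the
  battery's own test list; raw and adjusted p are both reported and
  significance is called at α = 0.001 on the adjusted value.

## Synthetic data: what it emulates, and what it does not

**Phantoms.** Analytic centerlines (straight segments, planar circular
arcs, helices, composites) carry closed-form κ/τ profiles as oracles. The
Y phantom plants two VAs (default diameters 3.4/2.8 mm — a left-dominant
pair straddling the 0.3 mm rule), a BA of 3.2 mm diameter and 24 mm
length, and an optional planar lateral bow realized as a circular arc
whose sagitta is exactly the planted deviation extent. Tubes are
voxelized centre-in/centre-out (no partial-volume model — threshold
robustness is tested separately) with Gaussian intensities compatible with
the 850/2500 window. Not modelled: flow artifacts, bias fields, signal
dropout in slow flow, the rest of the circle of Willis. Passing phantom
tests therefore demonstrates geometric correctness of the measurement
chain, not robustness to MR physics.

**Cohorts.** Marginals default to the observed study: n = 290, dominance
139/84/66 (left/right/even — the published table rows sum to 289 against a
stated 290; the generator targets the printed counts and treats the
discrepancy as an erratum), WMH prevalence 204/290, group-specific age
(57.6 ± 16.7 vs 40.2 ± 13.0 years), sex and risk-factor rates, PCom status
72/56/67/95. The curve direction is drawn conditionally on dominance from
a table calibrated offline as a convex blend of the antitone coupling and
the independence coupling (blend weight 0.596), which reproduces the curve
marginals exactly and yields population Spearman ρ = −0.56. The basilar
deviation magnitude has no published distribution; curved subjects draw
|signed lateral| = 1.0 mm + Exp(1.5 mm) and "even" subjects U(0, 0.95) mm,
keeping labels consistent with the 1 mm band. Planted laterality effects
are log-odds tilts of lesion burden (VA region toward the non-dominant
side, strength 2.0; BA region opposite the curve, 2.8 — magnitudes chosen
to match the strongly protective published odds ratios of ~0.1 and ~0.06)
and a 0.316-per-mm logistic slope of PCA laterality on signed deviation.
Lesion lists are then synthesized to realize the drawn laterality exactly
under the scoring rules (including a 25% share decided by the ≥5 mm
tie-break rather than by score). `EffectConfig.null()` removes every
planted effect *including* the group differences in age, sex, risk factors
and morphometry, so that all battery tests are null under it — the null
configuration is exchangeable by construction.

## Numerical choices and degenerate inputs

Tolerances: spline residual 0.4 mm; resample step 0.25 mm; Frenet
uniformity guard at 5% spacing CV; κ floor 1e-4 /mm for torsion; Brent
tolerance 1e-10 on log ψ; logistic convergence 1e-8 / 100 iterations.
Tie-breaks: component selection by centroid order; identical VA mean x
falls back to edge order. Degenerate inputs raise typed errors: empty or
disconnected masks, cyclic skeletons, ≠1 junction (with the observed
count), basilar top not superior to the confluence, chords under 1 mm,
zero-variance Spearman inputs, separated logistic fits. Pipeline errors
are wrapped with the failing stage name and subject id.

## Problem sizes used in tests

Phantoms are voxelized at 0.5 mm spacing (volumes ≈ 56×20×112); cohort
tests use n = 290 for count calibration, n = 2000 for association
recovery and the 50-seed null battery, n = 10⁴ for marginal convergence,
and 100 replicates at n = 5000 for logistic coverage. These sizes give
each stochastic check a sampling error several times smaller than its
tolerance band.

## Known limitations

* Thinning retracts branch endpoints by about one tube radius, biasing
  chord-referenced extents by ~0.2 mm at 0.5 mm spacing; dominance and
  direction calls are unaffected on all fixtures.
* The tortuosity is reported as the dimensionless ratio arc/chord − 1; the
  source cohort's printed tortuosity median ("0.05%") has no stated
  formula and is not comparable unit-for-unit.
* Units of the published curvature/torsion/area medians are unstated, so
  those medians are not used as calibration targets; the generator's
  morphometry scalars only reproduce the *direction and effect size* of
  the group differences.
* Single-junction trees only: fetal-PCA variants or additional branches
  below the prune length are out of scope by design.
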