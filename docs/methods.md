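# Methods

## Problem

Whether an intracranial aneurysm (IA) has ruptured correlates with its
morphology (size, aspect ratio, irregularity) and with its hemodynamics
(wall shear stress, oscillatory shear, inflow-jet structure).  Classical
rupture-status classifiers use scalar summaries of both.  This package
implements an integrated pipeline that additionally encodes the *spatial*
structure of the hemodynamic field — the point cloud of the impingement
zone and inflow jet — as a 1,024-dimensional embedding from a
permutation-invariant point-cloud network, and quantifies how much that
embedding adds to five standard classifiers under repeated stratified
cross-validation.

Patient-specific CFD datasets of this kind are not publicly available, so
the pipeline runs on a synthetic cohort generator whose class-dependent
structure is explicit and controllable.  Every empirical claim the test
suite makes is therefore a claim about the pipeline's behaviour under
those generated conditions, not about clinical data.

## Synthetic cohort generator

A subject is a spherical-cap sac (radius 2-5 mm, neck-to-diameter ratio
0.5-0.95, parent vessel 3-5 mm) sampled quasi-uniformly by a Fibonacci
lattice, with an explicit closed neck ring and, for "irregular" sacs, 2-3
radial daughter-sac lobes that taper to zero at the neck.  The inlet
waveform is a two-harmonic pulse (cycle 0.8 s, step 0.01 s, mean 0.3 m/s,
systolic peak at 0.12 s) standing in for a Doppler-measured carotid
waveform.

The WSS vector at point *i*, time *t* is

```
w_i(t) = B_i [ m(t) u_i + beta q(t) s_i ] + eps
```

with `m(t)` the waveform normalised to unit mean, `q(t) = m(t) - 1` its
pulsatile deviation, `(u_i, s_i)` a tangent frame, `beta` an oscillation
amplitude, and `eps` i.i.d. Gaussian component noise (default sd 0.2 Pa).
Steady flow with no noise therefore gives OSI = 0 exactly.  The spatial
amplitude `B_i` is built from Gaussian patches around jet foci on the
dome and then **rank-matched**: the field only determines the ranking of
points, while the values themselves are a fresh draw from a per-subject
lognormal target.  Velocity (distance-to-jet-path kernel) and pressure
(axial gradient plus patch bump) are rank-matched the same way.

Rank-matching is what separates the signal modes:

* `spatial` — target distributions are identical across classes, so every
  area-weighted scalar summary (mean/max/min WSS, OSI, pressure,
  velocity, LSA, HOA) is moment-matched *by construction*; the classes
  differ only in arrangement: ruptured subjects get one concentrated
  high-WSS patch and a narrow jet (patch width 0.12 vs 0.35 of sac
  height, jet width 0.10 vs 0.30), unruptured subjects three diffuse
  patches and a broad jet.  This mirrors the clinical observation that
  ruptured IAs show small impingement regions and narrow inflow jets.
* `summary` — spatial texture is drawn identically for both classes, but
  target medians shift: ruptured subjects get lower sac WSS, higher
  oscillation, higher velocity and energy loss, and narrower necks.
* `both` / `none` — both effects / neither.

At cohort size 60 the `spatial` mode's group-A features still show
nonzero class correlations *in any particular cohort draw* — with 28
features and 16 minority subjects the largest chance point-biserial
correlation is around 0.3, and cross-validation legitimately picks it up
(in either direction).  Exchangeability holds in distribution (verified
at n = 300, where group-A AUC returns to ~0.5); it cannot hold
conditionally on a small draw.  The headline comparison is therefore a
*paired* contrast — group B against group A on identical folds — rather
than a claim that group A sits exactly at chance.

What the generator does **not** emulate: spatially correlated noise,
wall compliance, secondary-flow structures, inter-subject waveform
variability, or any calibrated relation between geometry and flow.
Passing tests show the pipeline recovers the structure the generator
plants; they say nothing about effect sizes in clinical cohorts.

## Descriptors

*Morphology (10):* neck width (max pairwise neck-ring distance), height
(perpendicular to the least-squares neck plane; a max-distance variant is
exposed), parent-vessel diameter, size ratio = height/vessel diameter,
aspect ratio = height/neck width, surface area (accumulated point
weights), volume (divergence theorem with position vectors taken from the
neck centroid, which closes the surface with the flat neck cap
implicitly), surface/volume, shape and location flags.  AR and SR follow
the dominant literature definitions; the closed-form hemisphere and
spherical-cap oracles agree within 2% at 4,000 points.

*Hemodynamics (18):* max / area-weighted mean / min of systolic WSS,
TAWSS, OSI, pressure and velocity; high-OSI area (OSI > 0.2); low-shear
area (TAWSS < 10% of parent-artery mean WSS); energy loss
`EL = (P + rho u^2/2) Q |_in - sum_out (P + rho u^2/2) Q` with
rho = 1060 kg/m^3.  Cycle integrals use the periodic trapezoidal rule
(wrapping t = T to t = 0), which is exact for the piecewise-constant
closed-form cases and within 1e-3 of a 100x-finer quadrature on smooth
series.  The LSA and HOA thresholds are configurable conventions — no
universal standard exists.  The systolic frame is the waveform argmax.

## Regions and the point-cloud network

Impingement zone: systolic WSS strictly above 80% of the sac maximum,
unioned with the jet's surface footprint (points within 10% of sac height
from the peak-velocity point).  Inflow jet: velocity strictly above 80%
of the sac maximum (mirroring the WSS rule; no streamline integration —
the surface velocity channel is the jet proxy).  On a degenerate uniform
field the strict rule would select nothing, so it falls back to `>=` at
the maximum.  N points (default 5,000; desk presets use 128-512) are
drawn uniformly from the union, with replacement when the region is
smaller than N, and assembled in the fixed channel order
(x, y, z, wss_sys, osi, pressure, velocity, tawss).

The extractor is a scaled-down PointNet-style network: an 8x8 input
T-net, shared MLP 8-64-64, a 64x64 feature T-net with orthogonality
penalty (weight 1e-3), shared MLP 64-128-1024, and channel-wise max
pooling, giving an exactly permutation- and duplication-invariant
1,024-d feature.  Inputs are standardised with *fixed physical scales*
(coordinates centred per cloud / 5 mm, WSS and TAWSS / 5 Pa, OSI / 0.25,
pressure centred / 30 Pa, velocity / 0.3 m/s); per-cloud centring uses
the row mean, which respects both symmetries.  There is no batch
normalisation or dropout, so inference is deterministic.  The network
and its reverse-mode autodiff are implemented directly in NumPy
(float32; Adam, lr 1e-3, batch 16, class-weighted cross-entropy).
Training is supervised on the rupture label through a detachable
512-256-2 head; the feature is the pre-head pooled vector.

**Leakage control.**  Hemodynamic cloud features used in evaluation are
extracted with weights trained on the training folds of the current
split only; test subjects never influence their own features.  A
`single_fit` mode (extractor trained once on everyone) exists for
comparison and is optimistically biased.

## Feature groups and preprocessing

Group A: the 28 base descriptors, z-scored.  Group B: the base
descriptors plus the cloud block processed as normalise -> RFE -> kernel
PCA.  RFE keeps 64 of 1,024 columns using a strongly regularised linear
margin model (squared-hinge SVM, C = 0.01, dropping 25% per round) —
under-regularised margin models rank noise coordinates unreliably when
features outnumber subjects.  Kernel PCA (RBF, median-heuristic
bandwidth) reduces to 16 components, which are then scaled to unit
training-row variance so they are commensurate with the z-scored base
features in distance-based classifiers.  All transforms are refit per
training fold.

## Evaluation

Five classifiers with fixed hyperparameters (random forest 300 trees,
balanced; kNN k=5 distance-weighted; XGBoost 200x3 with
scale_pos_weight = 109/39; RBF SVM C=1 balanced with Platt
probabilities; LightGBM 200 trees, balanced — the cost-sensitive
settings reflect the designed ~26% rupture prevalence).  Stratified
10-fold CV, reshuffled per repetition from derived seeds; per repetition
the pooled fold scores give accuracy, AUC (midrank statistic),
sensitivity and specificity with ruptured positive at threshold 0.5.
The AUC interval is the normal approximation over repetition-level AUCs.
Feature groups are compared per model by the two-sided Wilcoxon
signed-rank test on per-repetition differences (exact null for n <= 25
without zeros, else the tie-corrected normal approximation;
all-zero differences are reported as degenerate with p = 1).

The desk-scale preset runs 60 subjects (26% ruptured), 256-point
regions, a 5-epoch extractor, and **7 repetitions** of 10-fold CV.
Seven, not five: the exact two-sided signed-rank floor at n = 5 is
2/32 = 0.0625, so no 5-repetition paired comparison can reach p < 0.05;
n = 7 has floor 2/128.  The permutation-null calibration redraws the
label shuffle for every repetition: a single fixed shuffle leaves one
chance alignment in place and its repeated-CV mean does not concentrate
at 0.5 (observed per-model means 0.27-0.70 at n = 60), while fresh
shuffles concentrate (0.51-0.56).

## Numerical and degenerate-input conventions

Zero WSS over the whole cycle gives OSI 0 by convention; constant
feature columns z-score to zero with a warning; max-pool gradients break
ties toward the first maximiser; uniform threshold fields fall back to
`>=` at the maximum; cohorts below 20 subjects warn that stratified
10-fold CV is infeasible; k greater than the minority count is a hard
error.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; generator outputs, training, and report
files are bit-reproducible for a fixed seed and thread count.

## Known limitations

The synthetic fields are phenomenological, not solutions of the
Navier-Stokes equations; absolute metric values have no clinical
meaning.  The 18-parameter roster fixes one reasonable interpretation of
"max/avg/min of each named family plus HOA, LSA, EL".  The extractor is
trained for a handful of epochs at desk scale — its features are
informative but not converged representations.  Group-A performance at
n = 60 fluctuates with the cohort draw (see above), so single-seed
group-A numbers should not be over-interpreted.
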