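# Methods

This note documents the models, conventions and numerical choices behind
`opmcg`: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Coordinate and angle conventions

All geometry lives on the chest plane: x toward the subject's left, y
toward the head, units cm; the field is the normal (out-of-chest) component
B_z in pT. Angles are degrees counterclockwise from +x, wrapped into
(−180°, 180°].

The **magnetic field angle (MA)** is the orientation of the vector from
the negative-pole extremum to the positive-pole extremum of the field map.
The **current angle (CA)** is the orientation of the strongest vector of
the pseudo-current map. For an ideal tangential current dipole these are
not equal: the pole axis is orthogonal to the current, so MA = CA + 90°
exactly, and both rotate together through repolarization. The tests
therefore check CA against the dipole moment and MA against moment + 90°.
The generator's "normal" T-wave moment is oriented at −145°, placing the
normal T-peak MA near −55°, inside the clinically normal −86°…−45° band;
ischemic drift is counterclockwise out of that band.

Pole-sign conventions differ between MCG devices and from the 1981 Rome
Biomag standard; this package fixes the convention above and makes no claim
of cross-device comparability.

## Forward model (synthetic recordings)

A single equivalent current dipole with tangential moment (m_x, m_y) at
depth d below the chest plane, in a homogeneous conducting half-space. For
horizontally layered conductors volume currents contribute nothing to B_z,
leaving

    B_z(r) = K (m_x Δy − m_y Δx) / |r − r₀|³,

linear in the moment and rotation-equivariant. K = 4000 pT·cm³ per moment
unit, chosen so the synthetic R-peak reaches ~10–18 pT at the default
geometry (6×6 grid, 4 cm spacing, sensor plane 5 cm above the sources,
source depth 6 cm) — typical magnitudes for close-to-chest OPM recordings.
This is deliberately non-physiologic: no torso boundary, respiration,
baseline wander from breathing, or rhythm disturbance. It exists to produce
dipolar two-pole maps whose TT-segment dynamics the downstream geometry can
be tested against, not to simulate a heart.

The beat is a sum of Gaussian deflections (P at −180 ms, Q/R/S around 0,
T peaking at +300 ms with σ = 45 ms, R-to-T amplitude ratio 2.5 at zero
ischemia). Ischemia (a level in [0, 1]) acts only through the TT segment:
counterclockwise angle drift of 10°–70°, source deepening by up to 2.5 cm
(which inflates pole areas), in-plane pole wander up to ~1.4 cm, T-amplitude
loss up to 35%, and optionally a second displaced dipole creating a positive
sub-pole. These five handles map one-to-one onto the five canonical Δ
predictors (ΔMAmax/ΔCAmax, ΔNPAmax, ΔCPPPPmax, ΔRoART), so the generator's
"truth" is known feature-by-feature.

Recordings are 36 × 18,000 samples (200 Hz × 90 s, ~100 beats at
66.7 bpm), with ±3% uniform RR jitter — enough to make R-detection
non-trivial without simulating arrhythmia. Noise defaults: white sensor
noise 1 pT SD per channel, 2 pT common 50 Hz powerline with per-channel
phase, 3 pT slow drift (0.15/0.33 Hz sinusoids). How much ischemia persists
post-intervention in symptomatic patients is not observable, so the paired
generator exposes persistence factors (defaults 0.75 for eventual angina
reporters, 0.15 otherwise); setting them equal produces a null cohort.

All randomness flows from one integer seed through `numpy.SeedSequence`
spawning (cohort → subject → scan), so every artifact is bit-reproducible.

## Signal conditioning

Zero-phase (forward–backward) filtering keeps fiducial latencies unbiased:
a 4th-order Butterworth 1–40 Hz band-pass plus an IIR 50 Hz notch (Q = 30),
each applied with `filtfilt` so the effective attenuation doubles
(measured: > 40 dB at 50 Hz, < 1 dB ripple at 10 Hz, > 20 dB at 0.2 Hz).
R-peaks are maxima of the cross-channel RMS trace above half the robust
(99.8th-percentile) trace maximum with a 250 ms refractory window —
thresholding is relative, so detection is amplitude-scale invariant.
Averaging uses the −300…+500 ms window (wide enough to hold T_b and T_p at
resting rates); beats whose R-sample RMS amplitude z-score exceeds 3 are
rejected, and a scan with fewer than 10 accepted beats fails quality.
Richer artifact removal (gradiometer referencing, empirical-mode
decomposition, ICA) is a pluggable hook: those algorithms have no published
parameters for this device, and the downstream contract — one clean
averaged beat — is testable without them.

## Mapping and features

Field maps are bicubic splines through the 36 sensor values on a lattice of
4 points/cm (81×81 over a 20 cm extent); sensor values are reproduced
exactly at the nodes. The pseudo-current map is the Hosaka–Cohen transform
c = (∂B_z/∂y, −∂B_z/∂x) by central differences — the standard MCG
convention for visualizing underlying current direction. Pole area is the
area of the connected lattice region around an extremum where the same-sign
value exceeds `area_fraction` × extremum; 0.5 (half-maximum) is the
default because it is scale-free and standard for extent measures. The
number of disjoint same-sign regions at that threshold is the sub-pole
count (≥ 2 flags multipolarity). Whether the vendor software measures pole
area on the field or the current map is unknown; the field map was chosen
and the alternative is one function call away for sensitivity work.

Fiducials are located on the RMS trace of the averaged beat: R_p at the
global maximum, T_p at the maximum of a 150–450 ms post-R window, T_b at
the last pre-T_p instant where the RMS falls below baseline + 10% of the
T-wave height (baseline = mean RMS over the window's first 80 ms). The TT
segment is sampled at the 11 instants T_b, T_b+τ, …, T_p with
τ = (T_p − T_b)/10.

The 65-parameter manifest is generated from a fixed grammar (the vendor's
full list is not public): 7 scalar TT series (MA, CA, NPA, PPA, D, MM, CM)
× {max, min, sum, range, max consecutive change} = 35; the same 7 over the
"bp" epoch (window start to the estimated P-offset, R_p − 120 ms, a choice
forced by the absence of any published P-offset rule) × {max, min, range} =
21; consecutive pole-point displacement series for both poles × {max, min,
sum, range} = 8; plus RoART = field amplitude at R_p ÷ field amplitude at
T_p. Field amplitude defaults to the maximum absolute value of the
interpolated map (`"ptp"` switches to max − min; the choice rescales RoART
by a bounded factor). Angle aggregates use signed angles; "maximum angle"
could also be read as maximum absolute angle, so that is a switch too.
Series aggregation is NaN-tolerant (an undefined angle at one instant is
skipped; an all-undefined series aggregates to 0), keeping the vector
finite for every valid beat. Ordering is frozen and regression-tested.

## Statistical pipeline

Screening drops features with raw-Δ variance < 0.10 (standardizing first
would make the threshold vacuous) and then resolves |Pearson r| > 0.9 pairs
greedily, strongest pair first, dropping the member with the larger mean
absolute correlation (deterministic name-order tie-break). Screening is
idempotent.

Stability selection runs B stratified bootstrap resamples (class counts
preserved exactly). On each resample features are standardized and a lasso
logistic regression is tuned by stratified 10-fold cross-validated binomial
deviance over a 15-point log-spaced λ path in [10⁻³, 10]; the model is
refitted at the winning λ and nonzero coefficients recorded. Two details
matter and were verified by simulation:

* **CV folds are built on the original subjects**, and every resampled copy
  of a subject inherits its subject's fold. Row-level folds put duplicates
  of one subject on both sides of the split; that leakage rewards
  overfitting, drives λ systematically small, and under a global null made
  the procedure retain ~8 "stable" features per run. With subject-level
  folds the null retains none.
* **Deviance, not AUC, tunes the bootstrap-stage λ.** Out-of-fold AUC is
  rank-based and almost flat in λ once the strong predictors are in, so
  argmax-AUC drifts to near-unpenalized fits and dense models; deviance has
  a clear interior minimum.

Features selected in ≥ 70% of resamples (≥ 0.7·B for general B; 700 of
1,000 at full scale) are retained. The final lasso model tunes λ over 100
log-spaced points in [10⁻⁴, 10] by repeated (10-repeat × 10-fold)
cross-validated AUC — λ_min, no one-standard-error rule — and refits on the
full standardized data. Class imbalance is handled by stratification only.

Validation: out-of-fold probabilities from refitting the chosen λ per fold
(fold-wise standardization) give the cross-validated AUC; its variance and
95% CI come from the DeLong placement-value formulation; pointwise 2.5/97.5
percentile bootstrap bands dress the ROC curve (whether published bands
were pointwise or simultaneous is unstated; pointwise chosen). Calibration
is the logistic-recalibration pair — intercept from a logistic fit with the
predicted log-odds as offset (calibration-in-the-large), slope from a
logistic fit on the log-odds — always on the continuous scale; decile bins
exist only for plotting. Decision curves use
NB(p_t) = TP/n − FP/n·p_t/(1−p_t) with treat-all/treat-none references
(p_t = 1 is excluded). The nomogram scales each coefficient×range term so
the widest spans 100 points; totals are affine in the linear predictor.
Permutation importance scores the *fitted* model on column-permuted data,
so a zero-coefficient feature has a drop of exactly zero. Sensitivity
analyses: elastic-net with α tuned over {0, 0.25, 0.5, 0.75, 1} jointly
with λ by the same repeated-CV criterion, and a 4-knot restricted cubic
spline (quantiles 0.05/0.35/0.65/0.95) likelihood-ratio test of
nonlinearity per predictor (2 df).

## Solver

The penalized logistic fits are solved by a warm-started
iteratively-reweighted-least-squares coordinate descent (the glmnet
algorithm): at each outer step the logistic loss is replaced by its local
quadratic with weights w = p(1−p) (clipped at p ∈ [10⁻⁵, 1−10⁻⁵]) and the
penalized weighted least-squares problem is solved by cyclic soft-threshold
updates with active-set iteration between full sweeps. The sigmoid is
evaluated once per reweighting rather than once per coordinate — the
difference between an affordable and an unaffordable 1,000-iteration
bootstrap. Fold fits in the bootstrap run at tolerance 2×10⁻⁴ with a
60-sweep cap (λ selection is insensitive to this); all final refits use
tolerance 10⁻⁸, at which the solver matches a general-purpose convex
optimizer (L-BFGS-B on the split-variable formulation) to better than
10⁻⁵ in every coefficient, for lasso, ridge and intermediate mixing.

## Feature-table generator

The Δ-feature tables are multivariate standard normal under a Gaussian
copula whose correlation is compound-symmetric (ρ = 0.4 by default) within
blocks; the default blocks are the aggregate families of each base quantity
*minus* the five canonical predictors, which enter independently — so with
the default effect map the other 60 features are genuinely null rather than
weakly informative through family correlation. The outcome is Bernoulli
with log-odds b₀ + Σ βⱼzⱼ; b₀ is solved by Gauss–Hermite quadrature so the
marginal event rate equals the requested prevalence (0.369 by default,
n = 363). Default standardized effects: 0.8 (ΔRoART), 0.7 (ΔNPAmax),
0.5 (ΔMAmax), 0.4 (ΔCPPPPmax), 0.3 (ΔCAmax). A quadrature calibrator
rescales any effect map so the Bayes-optimal AUC of the true linear
predictor hits a target (verified by Monte Carlo at n = 10⁴ within ±0.02).

## What passing tests do and do not show

The generator reproduces the *statistical shape* of the study — sample
size, prevalence, 65 correlated features, a handful of true predictors, a
dipolar field with TT dynamics — not real cardiac electrophysiology.
Recovery results therefore speak to the correctness and calibration of the
pipeline, not to clinical performance. One scaled recovery study is left
deliberately failing: at n = 363 with 60 null features, predictors with
standardized effects of 0.3–0.4 have marginal z ≈ 2.8 while the luckiest
null reaches z ≈ 2.6 by chance, so no penalty rule can hold all five true
predictors above a 70% bootstrap-selection frequency in ≥ 90% of cohorts
while keeping the median false-positive count ≤ 2; the honest pipeline
achieves the false-positive bound (median 0) and recovers the three-to-four
strongest predictors essentially always, losing the weakest ones.

## Known limitations

* The forward model is a single (optionally double) point dipole; real
  repolarization fields are distributed sources.
* The bp-epoch parameters rest on a crude P-offset estimate (R_p − 120 ms).
* Angle aggregates ignore circular statistics (a series straddling ±180°
  can produce a misleading range); the generator keeps normal and ischemic
  trajectories away from the wrap.
* EMD/ICA artifact removal is a hook, not an implementation.
* No external validation, no MACCE modelling, no inverse source
  localization.
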