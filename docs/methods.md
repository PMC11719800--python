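# Methods

## Dose model

An ideal SFRT field is represented as a 1-D lateral dose profile sampled on
a regular grid spanning the field width. `floor(field/ctc)` beam centers
are placed on a symmetric grid of pitch *ctc* about the field center; dose
is the peak inside each beam (half-width w/2 around a center) and
peak/PVDR elsewhere. This reproduces the reference collimators: 25 beams
for 50 µm / 400 µm CTC and 5 beams for 500 µm / 2000 µm CTC in a 10 mm
field. The default grid step is `min(beam_width/10, 25 µm)` — at least ten
samples per beam (5 µm for the microbeam geometry, 25 µm for the minibeam
geometry); steps coarser than beam_width/5 are rejected.

EUD under the linear-quadratic model uses uniform lateral weighting: the
mean survival S̄ is averaged over all grid samples in log space
(`logsumexp`), so peak doses of hundreds of Gy cannot underflow
(exp(−0.0115·470²) ≈ 10⁻¹¹⁰³ would underflow naive arithmetic). The unique
uniform dose with survival S̄ solves βD² + αD + ln S̄ = 0; we evaluate the
rationalized root

    EUD = 2(−ln S̄) / (α + sqrt(α² − 4β(−ln S̄)))

which is free of subtractive cancellation and reduces exactly to
−ln S̄ / α when β = 0, making the β → 0 limit continuous by construction.
Peak-dose solving for a target EUD brackets the root on [target, 10⁴ Gy]
and uses Brent's method to 10⁻⁹ Gy (EUD is monotone in the peak dose, so
the bracket is valid whenever a solution exists).

Note that the EUD of the *ideal* 470/23.5 Gy microbeam profile under the
A549 parameters (α = 0.4460 Gy⁻¹, β = 0.0115 Gy⁻²) is 23.6 Gy, not the
nominal 20 Gy prescription such studies quote: measured film profiles have
penumbra and rounded valleys that ideal top-hat profiles lack. Peak doses
are therefore treated as inputs, and the module accepts arbitrary measured
profiles from CSV for EUD evaluation.

## Regrowth model

Normalized volume kinetics follow
f(t) = A1·e^(−α1 t) + A2·e^(α2 t), with A1 + A2 = 1 and all parameters
positive: a killed fraction resorbing at rate α1 and a surviving fraction
regrowing at rate α2. Volumes come from caliper measurements via the
ellipsoid formula (π/6)·L·B² (breadth is the smaller axis by convention;
swapped inputs are corrected with a warning).

Fitting minimizes Σ[f(tᵢ) − Vᵢ/V0]² on the normalized scale. The
constraints are enforced exactly: A2 is eliminated as 1 − A1 with
A1 ∈ [0, 1 − 10⁻⁶], and rates bounded to [10⁻⁴, 1] day⁻¹. The objective is
multimodal, so a deterministic multi-start grid
(A1 ∈ {0.1, 0.3, 0.5, 0.7, 0.9} × α1 ∈ {0.03, 0.1, 0.3} × α2 ∈ {0.01,
0.03, 0.06} day⁻¹, 45 starts) is run through bounded trust-region least
squares and the lowest objective kept; the procedure contains no random
element, so identical inputs give bit-identical fits. Pre-irradiation
measurements are excluded, and no pseudo-point is added at t = 0 — the
model already forces f(0) = 1, and a pseudo-point would double-weight the
origin. At least four post-irradiation points (free parameters + 1) are
required.

Derived quantities:

- **Nadir** t_min = ln(A1α1/(A2α2))/(α1 + α2) when A1α1 > A2α2, else 0
  (monotone curve).
- **Regrowth start**: the first *measurement* day strictly after t_min —
  events are observable only on measurement days, so "the day after the
  minimum" maps to the next scheduled day, not t_min + 1. No remaining
  measurement day ⇒ censored.
- **Tripling time**: default is linear interpolation of the recorded
  (day, V/V0) series anchored at (0, 1) — growth time is defined from
  measurements; the model-based variant (Brent bisection on f(t) = 3,
  tolerance well below 10⁻⁶ days) exists for noise-free validation and for
  pure-exponential closed-form checks (ln 3 / α2).

Both fit scopes are provided: per-mouse (the default, feeding per-animal
growth times and PFS events) and per-group pooled (all of an arm's
normalized points concatenated into one fit). Simulation shows the two
scopes differ materially in estimator quality: per-mouse fits of single
90-day series under 15% multiplicative noise carry a finite-sample α2 bias
of about +3%, inherent to unweighted nonlinear least squares with
heteroscedastic multiplicative noise, while pooled 9-animal cohort fits
reduce it below 0.5%. Parameter-recovery tests therefore quantify both:
exactness on noise-free data per mouse, and bias/median-error bounds on
pooled cohort replicates.

## Endpoint statistics

Growth delay of a treated arm centers each animal's growth time on the
*mean* control growth time (arms are independent; no pairing exists). The
arm summary is the mean and SD of per-mouse delays and the half-width of
the t-based 95% CI, t₀.₉₇₅,ₙ₋₁·sd/√n — a single-number CI column is read
as a half-width. Because "treated vs control" can mean two different
tests, both are reported: a pooled-variance two-sample t-test on growth
times and a one-sample t-test of the delays against zero. The t-test is
the classic Student (pooled) flavor; Welch is deliberately not the
default. Degenerate inputs are mapped to limits: zero variance with equal
means → p = 1; with unequal means → p = 0.

PFS is the time from irradiation to the fitted regrowth-start day, capped
at the 90-day follow-up (events after the cap, or censored fits, become
censoring at min(last follow-up, cap)). The Kaplan–Meier product-limit
estimate and the unstratified Mantel–Cox log-rank test are delegated to
lifelines; the median is the smallest time with S(t) ≤ 0.5 (undefined if
never reached). A stratified variant accumulates observed-minus-expected
events and hypergeometric variances within each stratum and combines them
(χ², 1 df); with a single stratum it reduces to the plain test, which the
suite verifies against lifelines, and the asymptotic p is checked against
a 10,000-draw label-permutation null on 20-subject toy sets (agreement
within ±0.02; at n ≈ 12 the χ² approximation already deviates by up to
0.04, so smaller sets are not a fair benchmark of the asymptotic test).
No stratification factor is invented by default, and the three pairwise
log-rank p-values are reported uncorrected (a Holm option exists,
off by default).

## qPCR quantification

Technical replicates are collapsed to a mean Ct per sample × gene before
anything else; biological replicates are the unit of analysis. ΔCt is the
target Ct minus the arithmetic mean of the reference-gene Cts (equivalent
to normalizing by the geometric mean of reference quantities); ΔΔCt
centers on the control group's mean ΔCt per gene; the per-replicate fold
is 2^−ΔΔCt, summarized per group as mean ± SD on the fold scale. With
noisy replicates the control group's arithmetic mean fold exceeds 1
slightly (Jensen's inequality on 2^−x); its geometric mean is exactly 1 by
construction. Samples missing any reference gene, and genes without
control samples, are skipped with warnings. Amplification-efficiency
correction and melting-curve QC are out of scope.

## Synthetic cohort generator

The generator emulates the study design the analysis expects: four arms
(sham control, conventional broadbeam, minibeam-like, microbeam-like) of
9 animals; enrollment volumes V0 uniform in 60–100 mm³; measurements three
times a week (day offsets {0, 2, 4} mod 7 from irradiation, so the first
measurement is day 2); euthanasia the first measurement day the *observed*
volume reaches 3·V0 — using the noisy value mirrors real caliper-triggered
endpoints and reproduces their selection effect (noisy first passage makes
raw growth times read systematically early; the effect largely cancels in
treated-minus-control delays, which is what the recovery tests measure);
censoring at a 90-day cap.

Reference kinetics: the control arm is pure-exponential with
α2 = 0.0332913 day⁻¹ (model tripling at 33.0 days); treated arms share
A1 = 0.6, α1 = 0.15 day⁻¹ and regrow at α2 = 0.045683, 0.037873 and
0.029674 day⁻¹, placing their model tripling times 11.1, 20.2 and 34.9
days after the control's.

Caliper noise is multiplicative lognormal with unit mean and coefficient
of variation 0.15 (σ² = ln(1 + cv²), µ = −σ²/2): volumes stay positive
and the error scales with size, as L·B² error propagation does. The cv is
a configurable default, not a measured quantity. Per-animal random
substreams are keyed by (seed, CRC32(arm label), animal index), so cohorts
are bit-reproducible and stable under arm reordering.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: tumor-take failures, inter-animal heterogeneity
in kinetic parameters (all animals of an arm share one true curve),
measurement-day jitter, operator drift, toxicity-driven dropout, and any
immune-mediated dynamics.

## Problem sizes and numerical choices

Stochastic checks use 200 simulated cohorts for delay recovery and 200
pooled-cohort replicates for α2 recovery — sizes at which Monte-Carlo
error is comfortably below the asserted bounds. Root finding uses Brent's
method (xtol 10⁻⁹); optimizer tolerances are 10⁻¹²; ties in the log-rank
statistic use the grouped hypergeometric variance; the raw tripling-time
interpolant takes the *first* upward crossing of 3·V0. Measurement CSVs
are re-read with pandas' round-trip float parser so re-analysis of an
emitted CSV is bit-identical to the original run.

## Known limitations

- Single-curve-per-arm simulation understates between-animal variance in
  delay SDs relative to a real cohort.
- EUD assumes uniform lateral weighting and ideal top-hat (or
  user-supplied) profiles; no penumbra modelling, no 2-D/3-D dose grids,
  no fractionation corrections.
- No hierarchical (mixed-effects) fitting across animals; per-mouse fits
  at high noise carry the finite-sample rate bias quantified above.
- No Cox regression or hazard ratios; comparisons are rank-based only.
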