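# Methods

## The problem

Multi-b-value diffusion-weighted MRI (DWI) of the prostate decays
biexponentially: capillary microcirculation contributes a fast,
perfusion-related component on top of ordinary molecular diffusion.  The
intravoxel incoherent motion (IVIM) model separates the two:

    S(b) / S0 = f · exp(−b (D* + D)) + (1 − f) · exp(−b D)

with `b` the diffusion weighting (s/mm²), `f` the perfusion fraction,
`D` the molecular diffusion coefficient, `D*` the pseudo-diffusion
coefficient of the perfusing compartment (typically an order of magnitude
above `D` and notoriously hard to estimate), and `S0` the signal at
b = 0.  The mono-exponential apparent diffusion coefficient (ADC)
conflates the two compartments.

A diagnostic study built on this model needs three more ingredients, all
implemented here: (i) transferring a pathologist's lesion outline from a
whole-mount histology slide onto the low-resolution DWI grid via
landmark registration against T2-weighted MRI; (ii) a contralateral
normal-tissue reference ROI mirrored across the prostate midline within
the same anatomical zone; and (iii) the cohort statistics layer (paired
lesion-vs-normal tests, age correlations, ROC accuracy with cutoffs,
age-adjusted odds ratios).

No public dataset accompanies this problem, so the package is organized
around a first-class synthetic-data module: every downstream stage is
exercised against phantoms with known ground truth.

## Acquisition and phantom defaults

* b-values: 0, 50, 100, 200, 400, 600, 1000, 1200, 1800, 2000 s/mm²
  (a standard 10-b prostate protocol; the `AcquisitionScheme` type
  enforces b = 0 first, strict increase, and at least two points on each
  side of the segmented-fit threshold).
* DWI grid 64×64 at 3.05 mm pixels; T2/histology grid 256×256 at
  0.7625 mm.  Power-of-two grids preserve the roughly 4× resolution gap
  of a clinical prostate protocol while keeping downsampling tests exact.
* Phantom geometry: prostate ellipse containing a transitional-zone (TZ)
  ellipse; the peripheral zone (PZ) is the remainder; an optional lesion
  ellipse must sit entirely inside exactly one zone.
* Region parameter defaults are prostate-typical central tendencies:
  TZ f = 38.8 %, D = 0.80, D* = 4.41; PZ f = 37.4 %, D = 0.82,
  D* = 5.80; lesion f = 42.7 %, D = 0.51, D* = 3.73 (D, D* in
  10⁻³ mm²/s).  S0 = 100 arbitrary units.

## Noise model

Magnitude MRI noise is Rician: each value S is replaced by
√((S + ε₁)² + ε₂²) with ε₁, ε₂ ~ N(0, σ²) and σ = S0_ref / SNR.  The
acquisition SNR of a clinical study is rarely reported, so SNR is a free
simulation parameter; the default is 50 at b = 0, which puts the
high-b tail (S ≈ 0.2 S0) around SNR 10 — the regime in which D* becomes
unstable and shrinkage pays off.  All generators are bit-identical under
a fixed seed.

## Registration

Landmark (control-point) registration supports two planar families:
affine (6 coefficients, ≥ 3 point pairs) and full degree-2 bivariate
polynomial (12 coefficients, ≥ 6 pairs).  The degree-2 polynomial is the
smallest non-linear landmark family; with only 5 points (the practical
minimum of manual placement) it is under-determined, so family
auto-selection uses polynomial-2 at ≥ 6 points and affine otherwise.
The fit is linear least squares on the monomial design matrix; a
rank-deficient configuration (collinear points for affine, points on a
degenerate conic for polynomial-2) raises a named singular-configuration
error rather than returning a garbage transform.

Numerical choices:

* images are resampled by inverse mapping with bilinear interpolation
  (out-of-domain fill 0); label masks use nearest-neighbor semantics
  (a target pixel is set when its inverse-mapped center falls inside the
  source mask);
* the polynomial inverse has no closed form; it is approximated by
  fitting a polynomial-2 transform to a dense 40×40 grid of
  forward-mapped samples, which is accurate to well below a pixel for
  the smooth, mildly non-linear transforms this workflow sees, and the
  Jacobian is checked for sign changes (a fold triggers a warning, not a
  failure);
* mask downsampling from the T2 grid to the DWI grid is a majority rule
  in physical coordinates: a coarse pixel is set when ≥ 50 % of its
  footprint is covered by the fine mask, with pixel centers at
  (index + 0.5) · pixel_size and a shared origin.  Majority coverage
  minimizes area bias relative to any-overlap or center-sampling rules;
* the contralateral ROI is the lesion mask reflected across the
  prostate midline and clipped to the lesion's own zone (PZ lesions get
  a PZ reference, TZ lesions a TZ reference); a lesion straddling the
  midline has no defined contralateral ROI and raises an error;
* registration quality is reported as held-out target registration
  error (TRE), because residuals on the fitted points are optimistically
  biased.

## IVIM fitting

### ADC

Ordinary least squares of ln S on b over b ≤ 1000 s/mm² (positive
signals only).  Points at b = 1200–2000 show non-Gaussian (kurtosis)
behaviour in vivo that a mono-exponential cannot absorb, so they are
excluded from ADC by default.

### Segmented fit

1. mono-exponential OLS on the b ≥ 400 s/mm² tail gives D and an
   extrapolated intercept A;
2. f = 1 − A / S(0) (negative values are clipped to 0 and flagged);
3. bounded trust-region least squares over (f, D* − D, S0) with D fixed;
4. a final bounded least squares over all four parameters, initialized
   from step 3.

Step 4 matters: with D* ≈ 3–6 × 10⁻³ mm²/s the perfusion term still
carries ~18 % of its weight at b = 400, which biases the fixed-D
two-step estimate of D upward by ~16 % at lesion-typical parameters.
The final polish removes that bias exactly in the noise-free limit and
keeps the two-step solution as a robust initializer.  D* is
parameterized as D plus a positive offset so D* > D holds structurally
(no compartment label switching), and all estimates respect the bounds
f ∈ [0, 1], D ∈ [10⁻⁵, 5×10⁻³], D* − D ∈ (0, 0.5] mm²/s.
Non-convergence is flagged in the result, never raised.

### Bayesian shrinkage prior (BSP) fit

Per-voxel transformed parameters θ_v = (log D, log(D* − D), logit f,
log S0) are modelled as draws from a shared multivariate Gaussian
N(μ, Σ) whose mean and covariance carry weak hyperpriors (flat on μ,
inverse-Wishart(6, 10⁻² I) on Σ); the likelihood is Gaussian on the
signal residuals with a shared noise variance under an
InvGamma(10⁻³, 10⁻³) prior.  μ, Σ and σ² have conjugate Gibbs updates;
θ is updated by component-wise Metropolis random walks vectorized across
voxels, with proposal scales adapted every 50 burn-in iterations toward
30 % acceptance.  Defaults: one chain of 5000 iterations with 1000
burn-in, initialized from the segmented fit; the point estimate is the
posterior mean of the back-transformed parameters.  The log/logit
transform makes the Gaussian prior respect the physical constraints
automatically.

The in-house formulation such a study would have used is not published
in equation form; what this reconstruction is designed to guarantee —
and what the tests assert — is the shrinkage property itself: on
homogeneous ROIs at SNR ≤ 30 the across-voxel variance of the BSP
estimates is below that of independent segmented fits for f, D and D*,
with the largest gains on D*.  A Gaussian likelihood is used despite the
Rician simulation noise; at the SNRs of interest (≥ 20 at b = 0) the
Rician bias is below the parameter variability, and a Rician likelihood
is out of scope.  An acceptance rate outside [0.1, 0.6] after adaptation
produces a warning in the diagnostics; fewer than 10 voxels is an error
(shrinkage needs a population to learn from).

### ROI summaries

Median and quartiles per parameter with the linear-interpolation
(type-7) quantile convention, pinned so Q1/Q3 tables reproduce exactly.
Reporting units follow clinical convention: f in percent, D / D* / ADC
in 10⁻³ mm²/s.

## Cohort simulation

Per-subject zone parameters are linear in age plus Gaussian
between-subject noise:  baselines at the reference age 35 equal the zone
defaults above; slopes default to +0.3 % per year for f (angiogenesis
accompanying benign hyperplasia), −0.05 × 10⁻³ mm²/s per year for D*
and 0 for D; between-subject SDs 8 % (f), 0.12 (D) and 1.2 (D*)
× 10⁻³ mm²/s.  With these values the configured age trends dominate the
spread (|slope| × age range > 2 × SD), so the pooled Spearman signs are
recoverable at n = 38.  Draws violating the parameter invariants
(f ∈ (0,1), D > 0, D* > D) are redrawn up to a cap of 100; exhausting
the cap raises an error naming the inconsistent spec.

Patients (default 16, ages 50–84) each carry one lesion, placed in the
PZ with probability 0.7; controls (default 22, ages 24–49) carry none.
The lesion modifies the subject's own zone values: D drops by
0.29 × 10⁻³ mm²/s (paired SD 0.15), while the lesion effects on f and
D* default to zero — lesion ADC contrast then emerges from the D effect
rather than being set directly.  Gleason groups are assigned 10 : 6
(score 7 vs 8–9) and enhancement labels 11 : 4 : 1 (yes/no/unknown),
scaled to the configured patient count.

What the generator deliberately does not emulate: partial-volume mixing
at zone boundaries, spatially correlated noise, intra-lesion
heterogeneity, B0-distortion of the DWI frame, and through-plane
(3-D) misalignment between histology and MRI.  Passing tests therefore
demonstrate correctness of the estimators and the statistics under the
stated model, not robustness to those real-data effects.

## Statistics layer

* Mann–Whitney U: exact null distribution by full enumeration of group
  assignments for combined n ≤ 12 (midranks for ties; two-sided p =
  min(1, 2·min(P(U ≤ u), P(U ≥ u)))), normal approximation with tie and
  continuity corrections otherwise.
* Paired lesion-vs-normal: paired t (two-sided) with a Wilcoxon
  signed-rank companion.  Degenerate conventions are pinned because
  small-n tables hit them: identical pairs → p = 1 (flagged);
  zero-variance nonzero-mean differences → p = 0 (flagged).
* Spearman rank correlation with average ranks for ties; p via the t
  approximation; constant input is flagged, not an error.
* ROC: AUC by the rank (Mann–Whitney) formulation with ties counted ½;
  95 % CI from the DeLong variance; cutoff maximizing Youden's J,
  reported as the midpoint between adjacent distinct observed values;
  orientation auto-selected so AUC ≥ 0.5 (lower-is-positive for D and
  ADC, since lesions restrict diffusion).
* Age-adjusted odds ratios: logistic regression (outcome ~ dichotomized
  parameter + age) by Newton–Raphson MLE with Wald CIs.  Complete or
  quasi-complete separation — which a perfectly discriminating
  parameter at n = 16 + 16 produces — is detected and reported as
  not-available rather than as an astronomically large OR.
* No multiple-testing correction: tables report raw per-comparison
  p-values.

## Problem sizes and runtime choices

The replicate significance-pattern experiment
(`ivimfusion.experiments`) runs the cohort at ROI-decay-curve level:
each ROI is represented by its mean curve at the ROI-effective SNR
(voxel SNR × √N_voxels, N = 40 by default), which preserves the
statistical structure at a fraction of the cost of image-level fitting;
100 replicates complete in about two minutes.  The full image-level
pipeline (simulate → register → fit ROI voxels → statistics, 38
subjects, 64×64 DWI) is run once per suite/acceptance invocation and
completes in about a minute with the segmented fitter.  Monte-Carlo
recovery checks use 500 replicate voxels at SNR 50; shrinkage
comparisons use 100 voxels at SNR 20 with 2000-iteration chains.

## Known limitations

* Registration is strictly 2-D single-slice; through-plane deformation
  between the histology block and the imaging plane is not modelled.
* The BSP reconstruction asserts the shrinkage property, not numerical
  equivalence to any particular in-house implementation.
* The Gaussian likelihood understates noise skew below SNR ≈ 10.
* The segmented fit's D* remains the least stable estimate (median
  error an order of magnitude above D's at matched SNR); this is a
  property of the model's conditioning, not of the optimizer.
* Real-data mode expects NIfTI/PNG/CSV inputs that already share a
  physical frame; frame alignment metadata must be supplied, not
  inferred.
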