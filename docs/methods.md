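# Methods

## Signal model

A voxel containing water and fat is modeled with a single effective
transverse relaxation time T2\* shared by both species:

    S(TE) = S0 · | (1 − FF) + FF · Σ_p a_p · e^{2πi f_p TE} | · e^{−TE/T2*}

with fat fraction FF ∈ [0, 1] and a multipeak fat spectrum of frequency
offsets f_p (Hz relative to water) and non-negative relative amplitudes
a_p summing to one.  The shared-T2\* assumption matches the estimation
target of clinical iron/fat software: one T2\* and one FF per ROI.  The
default spectrum is the widely used six-peak set, specified in the
packaged config as chemical shifts from water
{+0.60, −0.39, −1.94, −2.60, −3.40, −3.80} ppm with amplitudes
{0.048, 0.039, 0.004, 0.128, 0.693, 0.087} (normalized at load time),
converted to Hz at the configured field strength (default 1.5 T).  The
spectrum lives in the config file rather than in code because published
spectra differ slightly and sites calibrate their own.

Magnitude noise is Rician: each noisy sample is |(s + n_re) + i·n_im|
with independent Gaussian(0, σ) components.  At zero underlying signal
this produces a Rayleigh floor with mean σ·√(π/2) — the plateau that
motivates the truncation fit.  No Gaussian approximation is offered.

**Echo grids** (configurable; the values are acquisition design choices,
not measurements): pancreas and liver use 12 echoes from 1.0 ms with
1.6 ms spacing; heart uses 10 echoes from 2.0 ms with 2.2 ms spacing.
The 1.6 ms spacing samples the dominant fat–water beat (period ≈ 4.6 ms
at 1.5 T) finely enough to separate FF from decay, and the 1.0 ms first
echo keeps heavily iron-loaded tissue (T2\* of 1–2 ms) measurable.

## Relaxometry

All variants minimize the sum of squared differences between the
noiseless magnitude model and the measured magnitudes with bounded
trust-region least squares (scipy `least_squares`, method `trf`,
ftol = xtol = gtol = 1e−12).  Bounds: S0 ≥ 0, T2\* ∈ [0.1, 1000] ms
(configurable), FF ∈ [0, 1], offset ∈ [0, max signal].  Initial values
come from a log-linear regression of ln(signal) on TE restricted to
echoes above 2% of the peak signal; if the solver reports
non-convergence, up to three restarts perturb the start by 20%
multiplicative Gaussian jitter drawn from a fixed, documented seed, and
the best solution is kept.  Non-convergence after restarts flags the
result rather than raising.  A T2\* estimate within 1e−6 (relative to
the bound span) of either bound sets `at_bound`; a constant signal is
the canonical case, pinning T2\* at the upper bound.  Standard errors
come from the Gauss–Newton covariance rss/(n−p)·(JᵀJ)⁻¹ at the solution.

The **fat–water** fit multi-starts over FF ∈ {0.05, 0.25, 0.45, 0.65}
and keeps the lowest residual; this is the only mechanism used to
resolve the fat/water dominance ambiguity (no FF ≤ 0.5 constraint, since
fat-replaced tissue above 50% occurs).  The **truncated** fit first
estimates the noise floor from the offset of a mono+offset fit on the
full train (σ̂ = offset/√(π/2), inverting the Rayleigh mean), then
repeatedly drops the last echo while the current offset-free fit
predicts a noiseless signal below 2σ̂ there, refitting after each drop.
Truncation never goes below 4 echoes; hitting that floor sets a warning
flag.  Ties (predicted signal exactly at the threshold) resolve toward
keeping more echoes because the loop only drops on a strict inequality.
Fitting uses the noiseless magnitude model plus an optional additive
constant; a full Rician likelihood is deliberately not used, preserving
the least-squares semantics of the clinical software class this mirrors.

**Known accuracy limits.**  Magnitude least squares is bias-limited by
the Rician floor when the decay reaches the noise level inside the echo
train (short T2\* at moderate SNR), and variance-limited when the train
ends long before the decay does (T2\* well above the last TE).  At
SNR = S0/σ = 30 these limits are intrinsic: experiments with an exact
Rician maximum-likelihood estimator given the true σ showed errors of
the same order as the least-squares fit, so the residual error at that
SNR reflects the information in the data, not the optimizer.  The
acceptance script reports the measured medians
(`ff_abs_error_median_snr30`, `t2s_rel_error_median_snr30`).  Similarly,
the truncated fit roughly halves the median T2\* error at T2\* = 1.5 ms
with a 5% noise floor (see `truncation_median_error_ratio`), but its
*pairwise* win rate against the untruncated fit saturates near 85%
because the two estimators' errors are strongly correlated on the same
noise draw.

## Organ-level mapping

Global pancreatic T2\* and FF are plain arithmetic means of the
head/body/tail ROI values (FF reported in percent); whether to average
T2\* or R2\* across regions is a convention, and the arithmetic mean of
T2\* is used.  A missing, non-converged, or boundary-pinned regional fit
aborts the aggregation — nothing is imputed.  The cardiac map takes 16
segmental T2\* values in AHA order (6 basal, 6 mid, 4 apical; the
package never infers anatomy), reports their mean and the count of
segments at or below the 20 ms conservative normal limit.  Liver T2\*
converts to liver iron concentration through the linear calibration
LIC = 0.0254·R2\* + 0.202 mg/g dry weight (R2\* in Hz), config-exposed
because published calibrations differ in the third decimal.  A
susceptibility-artifact correction hook exists but is a documented
no-op: the published correction needs scanner-specific coefficients
that are not redistributable.

## Diagnostic rules

Boundary conventions follow the clinical definitions verbatim:
pancreatic iron overload at T2\* strictly below 26 ms; fatty replacement
at FF strictly above the normative limit (default 6.6%, always
injectable); hepatic iron at LIC ≥ 3 mg/g dw; myocardial iron at
T2\* ≤ 20 ms (normal strictly above); pulmonary hypertension at a
tricuspid jet strictly above 3.2 m/s.  Glucose classes partition the
(FPG, 2h) plane with precedence DM > IGT > IFG > NGT: DM at known
diabetes, FPG ≥ 126, or 2h ≥ 200 mg/dL; IGT at 140 ≤ 2h < 200; IFG at
100 ≤ FPG < 126; NGT otherwise.  The precedence resolves the overlap of
the IFG and IGT definitions (a patient can satisfy both) and is
configurable.  A missing 2-h value yields DM when FPG ≥ 126 (the class
is already determined) and UNKNOWN otherwise.  Metabolic syndrome uses
three-valued majority logic over the five criteria: true at ≥ 3 true,
false when the unknowns can no longer reach 3, unknown in between —
refining an unknown input never flips a determined verdict.  Missing
data propagate as unknown throughout; nothing is imputed.

## Cohort statistics

* **ROC / Youden.**  The AUC is the tie-corrected Mann–Whitney statistic
  (midranks), identical to the pairwise count with ties scored ½.  The
  cutoff scan enumerates midpoints between adjacent sorted unique scores
  plus one candidate beyond each extreme; ties in sensitivity +
  specificity resolve toward higher specificity (a screening-oriented
  choice), then toward the more extreme cutoff.  The 95% CI and the
  p-value against AUC = 0.5 use the Hanley–McNeil asymptotic SE.
* **DeLong.**  Implemented from the covariance of placement values
  (midrank formulation); identical paired scores give a zero variance
  and p = 1 by convention.  The test suite validates it against a
  subject-resampling paired bootstrap.
* **Normative limit.**  exp(mean + 2·SD) of log(FF + ε) minus ε, sample
  SD with n−1.  ε (default 0.1 percentage points) guards exact zeros,
  which occur in healthy regional fat fractions; it is reported with the
  result so the limit is reproducible.
* **Stepwise regression.**  Univariate screen at p < 0.05 on
  standardized variables, then forward selection (entry p < 0.05) with
  backward removal (p ≥ 0.10) — the classic defaults of the statistics
  packages this procedure descends from — then a collinearity screen
  dropping later-entering variables while any VIF > 5 or tolerance
  < 0.20.  Listwise deletion of missing rows; a warning below
  n = 10 × candidates.  Exact p-value ties break by candidate order.
  Note that with a strong true predictor the compound screen-then-enter
  procedure retains pure-noise candidates at well below the nominal 5%:
  their chance univariate significance is mostly borrowed from the true
  predictor's share of the outcome variance and disappears once it
  enters the model.  The nominal rate applies on a pure-noise outcome,
  where the screen and the entry test coincide.
* **Multiple testing.**  Bonferroni adjustment only for the pairwise
  post hoc comparisons after Kruskal–Wallis; no global correction.

## Synthetic cohort generator

The generator encodes the causal structure the analysis assumes, with
every effect size in config:

1. a latent transfusional iron burden L ~ log-normal(0, 0.8);
2. pancreatic R2\* = 28 + 39·L Hz (regional values jittered ±8% around
   the patient level, global T2\* the exact mean of the regional T2\*s);
3. fat fraction through a saturating logistic link,
   FF = 80%·σ(−1.3 + 0.9·ln L + 0.02·(age−40) + 0.05·(BMI−22.3)
   + 0.8·HCV-exposure + N(0, 0.9)), with regional values drawn on the
   logit scale so each stays below the ceiling and the global is their
   exact mean;
4. glucose class from an ordinal latent 0.12·FF% + 0.03·(age−40) +
   logistic noise with cutpoints (4.80, 5.65, 6.41) calibrated by
   simulation to class prevalences of roughly 69/8/6/16%
   (NGT/IFG/IGT/DM); the observable FPG/1h/2h values are then drawn
   consistently with the class, and ~81% of diabetics are "known"
   diabetics who skip the OGTT (post-load glucose and insulin missing);
5. myocardial iron probability σ(−3.4 + 1.2·ln L), with iron hearts
   drawn below 20 ms and normal hearts above, then ±6% segmental jitter;
   liver R2\* = 25 + 62·L·e^{N(0,0.45)} converted to LIC;
6. replacement fibrosis (assessed in 46% of patients, tri-state) and
   cardiac complications via logistic links on FF and fibrosis, with
   subtypes (HF / arrhythmia / PH) and a jet velocity consistent with
   the PH flag.

Location and scale defaults target the marginals of a well-treated adult
thalassemia cohort (median age ≈ 40 y, BMI ≈ 22 kg/m², pancreas
T2\* ≈ 15 ms, FF ≈ 25%, LIC ≈ 2.4 mg/g dw, heart T2\* ≈ 40 ms, healthy
controls FF median 1.85% with a ≈ 6.6% upper limit).  The glucose
coupling strength was set so the FF separation between adjacent glucose
classes survives sampling noise at cohort scale — the class ordering is
a designed-in property, not an accident of one seed.

Under the default **gated** regime, abnormal glucose classes,
significant myocardial iron and cardiac complications occur only above
the fatty-replacement limit; the iron- and normal-heart T2\* latents are
kept clear of the 20 ms boundary so the gate is exact.  This makes the
100%-NPV findings generative assumptions: with the gate on they hold on
every seed as a wiring check of the pipeline, with the gate off they
break for large n — the package makes no claim that real cohorts behave
this way.  The gate applies to the noiseless observables in the cohort
table; cohorts refitted from synthesized noisy echo trains can violate
the exact NPV through measurement error.  A configuration whose FF
ceiling does not exceed the gate limit is rejected as infeasible.

All draws come from one seeded generator in a fixed, documented order,
so cohorts are byte-identical across runs and releases.  What the
generator does **not** emulate: longitudinal dynamics, treatment
effects, site/vendor heterogeneity, ROI-delineation variability, and
any image-domain effect (partial volume, susceptibility artifacts).
Passing end-to-end tests therefore demonstrates that the estimation and
rule machinery is correct under the assumed causal structure, not that
the structure is true of real patients.

## Problem sizes

The acceptance script runs each check at a size chosen to give stable
estimates on a single CPU in about a minute: the full 20-point
forward–inverse grid, 50 noise replicates per grid point at SNR 30,
200 truncation replicates, 300 ROC oracle instances, a 4000-resample
bootstrap, 10⁵ normative-limit draws, 100 stepwise seeds, the full
75,551-point glucose grid, and a 2000-patient gated cohort.  The test
suite uses the larger replicate counts quoted in the individual test
docstrings.
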