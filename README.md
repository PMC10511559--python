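# ferrofat

Quantitative T2*/fat-fraction MRI relaxometry and clinical cohort
statistics for transfusional iron overload (thalassemia major and
related conditions).

In chronically transfused patients, tissue iron shortens the effective
transverse relaxation time T2*, and in the pancreas the death of
parenchymal cells is followed by fatty replacement.  Both quantities can
be read off the same multiecho gradient-echo acquisition: iron from the
exponential decay rate, fat from the oscillation that the fat resonances
superimpose on the decay.  `ferrofat` implements the full desk-side
chain that such studies run:

* **Signal model** — the multipeak fat–water magnitude model
  S(TE) = S0 · |(1−FF) + FF·Σₚ aₚ e^{2πi fₚ TE}| · e^{−TE/T2\*},
  with a single T2\* shared by water and fat, plus Rician magnitude
  noise.
* **Relaxometry** — bounded nonlinear least squares for the
  monoexponential, noise-floor-truncated, and joint (S0, T2\*, FF)
  fat–water fits, exposed as a `DecayModel` / `DecayFitResults` pair
  (statsmodels-style: `fit()`, `summary()`, `predict()`, `plot()`).
* **Organ mapping** — pancreatic head/body/tail aggregation, the
  AHA 16-segment cardiac T2\* map (pathological at ≤ 20 ms), and the
  linear R2\* → liver iron concentration calibration.
* **Clinical rules** — NGT/IFG/IGT/DM glucose classes from fasting and
  2-h OGTT glucose, HOMA-IR, pancreatic iron (T2\* < 26 ms) and fatty
  replacement (FF above the normative limit, default 6.6%), hepatic iron
  (LIC ≥ 3 mg/g dw), metabolic syndrome (≥ 3 of 5 criteria with
  three-valued missing-data logic), cardiac complications (HF,
  arrhythmia, pulmonary hypertension at jet > 3.2 m/s), and ventricular
  SVI/EF arithmetic.
* **Cohort statistics** — nonparametric comparisons with Bonferroni post
  hocs, Spearman and chi-square, ROC analysis with the Youden-optimal
  cutoff (maximum sensitivity + specificity), the DeLong test for
  correlated AUCs, predictive values, the log-normal normative upper
  limit (mean + 2 SD on the log scale), and univariate + forward-stepwise
  multivariate regression with VIF/tolerance collinearity screening.
* **Synthetic cohorts** — a seeded generator with the assumed causal
  structure (latent iron → pancreatic R2\* and FF; FF + age →
  dysglycemia; FF + fibrosis → cardiac events), gated so that a normal
  FF has 100% negative predictive value by construction, plus echo-train
  synthesis so the whole pipeline can be exercised end to end with no
  external data.

## Worked example

```python
from ferrofat import (DecayModel, TissueState, evaluate_signal, add_magnitude_noise,
                      default_fat_spectrum, default_protocol, generate_cohort,
                      CohortConfig, roc_with_youden, spearman, predictive_values)

spectrum = default_fat_spectrum()              # 6-peak spectrum at 1.5 T
protocol = default_protocol("pancreas")        # 12 echoes, 1.0 + 1.6k ms
truth = TissueState(s0=300.0, t2star_ms=12.0, ff=0.35)
train = add_magnitude_noise(evaluate_signal(truth, protocol, spectrum),
                            noise_sd=5.0, seed=7)

res = DecayModel.from_echo_train(train, spectrum=spectrum).fit("fat_water")
print(res.summary())
```

```
Multiecho decay fit (fat_water)
============================================
parameter         estimate       std err
--------------------------------------------
s0                 296.706          4.59
t2star_ms          12.0053         0.301
ff                0.344599       0.00928
--------------------------------------------
echoes used: 12   RSS: 116.1
converged: True   at bound: False
```

The fit recovers the generating parameters (T2\* = 12 ms, FF = 35%)
within one standard error at SNR 60.  The same objects drive a whole
cohort analysis:

```python
df = generate_cohort(CohortConfig(seed=17)).patients   # 308 synthetic patients
rho = spearman(df.pancreas_global_ff_pct, df.pancreas_global_t2s_ms)
roc = roc_with_youden(df.pancreas_global_t2s_ms,
                      df.pancreas_global_ff_pct > 6.6, direction="less")
npv = predictive_values(df.pancreas_global_ff_pct > 6.6,
                        df.glucose_class.isin(["IFG", "IGT", "DM"]))
```

```
n = 308 patients; median global pancreas FF = 26.15%, T2* = 14.87 ms
Spearman rho(FF, T2*) = -0.562 (p = 4.94e-27)
T2* < 17.20 ms predicts fatty replacement: AUC = 0.88, sens = 67.9%, spec = 100.0%
NPV of a normal FF for abnormal glucose metabolism: 100%
```

The negative FF–T2\* correlation reflects the shared latent iron burden;
the perfect NPV is a built-in property of the default gated generator
(see `docs/methods.md`).

## Command line

```bash
ferrofat simulate-cohort --seed 17 --out cohort.csv --healthy-out healthy.csv
ferrofat classify        --input cohort.csv --out flags.csv
ferrofat analyze-cohort  --input cohort.csv --healthy healthy.csv --out report.json
ferrofat fit-decay       --input roi.csv --model fatwater --out fit.json
ferrofat normative-limit --input healthy.csv
```

Exit codes: 0 ok, 1 validation failure, 2 internal error.  All
thresholds, the fat spectrum, echo grids and generator parameters live
in a TOML config (`--config`); every report records the config hash.

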