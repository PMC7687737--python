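# readmitsim

Hospital readmission risk models are usually built from discharge-level
data in which one patient contributes many discharges, and the patients
who are discharged most often are also the ones readmitted most often —
*informative cluster size*. How you sample (one discharge per patient vs
all of them) and how you estimate (ordinary logistic regression vs
clustering-aware methods) changes both the readmission rate you observe
and every measure of model performance you report.

`readmitsim` is a simulation laboratory for exactly this problem. It
provides:

* a **synthetic cohort generator** in which a patient-level frailty
  u_i ~ N(0, σ²) drives *both* the number of discharges,
  n_i = 1 + Poisson(λ·exp(γ·u_i)), and the 30-day readmission outcome,
  Y_ij ~ Bernoulli(expit(α + βᵀX_ij + u_i)), so cluster size is
  informative whenever γ > 0;
* **cohort-construction rules**: merging of readmissions within 8 hours of
  a discharge (in-hospital transfers) and 30-day all-cause outcome
  labeling from timestamps;
* **sampling frames** (first discharge per patient vs all discharges) and
  patient-level 60/40 train/validation splits;
* three **estimators** of logit P(Y=1|X) = α + βX, written from first
  principles with cluster-robust sandwich inference:
  ordinary logistic regression (IRLS), GEE with an exchangeable working
  correlation, and cluster-weighted GEE (CWGEE, cluster weights 1/n_i),
  which remains valid when cluster size is informative;
* the two-stage **variable selection** protocol (univariate screen at
  P < 0.1, best-subset by AIC/QIC, backward pruning at P < 0.05);
* five **performance measures**: C statistic (AUC), outcome–prediction
  correlation, coefficient of discrimination D, Brier score, and scaled
  Brier score 1 − Brier/Brier_max with Brier_max = mean(p)(1 − mean(p));
* a **resampling study** over cohort sizes with per-method slope tests
  (ANCOVA-style) and discharge-count correlation analyses, plus figures.

## Worked example

```python
from readmitsim import (
    GeneratorConfig, generate_cohort, first_discharges, split_by_patient,
    fit_method, evaluate, cluster_summary,
)

cohort = generate_cohort(GeneratorConfig(n_patients=4000), seed=1)
first = first_discharges(cohort)
print(f"readmission rate, first discharges: {first['outcome'].mean():.3f}")
print(f"readmission rate, all discharges:   {cohort['outcome'].mean():.3f}")

train, valid = split_by_patient(cohort, 0.6, seed=1)
for method in ("LR-first", "LR-all", "GEE", "CWGEE"):
    frame = first_discharges if method == "LR-first" else (lambda t: t)
    fit, screen, sel = fit_method(frame(train), method)
    rep = evaluate(fit, frame(valid))
    print(f"{method:9s} AUC={rep.auc:.3f} D={rep.coef_discrimination:.3f} "
          f"Brier={rep.brier:.3f} scaled={rep.scaled_brier:.3f} "
          f"rho={fit.working_correlation:.3f}")
print("r(log n_i, readmissions) =", round(cluster_summary(cohort).log_size_readmission_r, 3))
```

Output:

```
readmission rate, first discharges: 0.090
readmission rate, all discharges:   0.194
LR-first  AUC=0.836 D=0.216 Brier=0.064 scaled=0.171 rho=0.000
LR-all    AUC=0.842 D=0.271 Brier=0.117 scaled=0.275 rho=0.000
GEE       AUC=0.836 D=0.192 Brier=0.126 scaled=0.222 rho=0.329
CWGEE     AUC=0.825 D=0.145 Brier=0.140 scaled=0.132 rho=0.426
r(log n_i, readmissions) = 0.567
```

Reading it: sampling only first discharges halves the observed
readmission rate (0.090 vs 0.194) and produces the *smallest* Brier score
(0.064) — not because the model is better, but because Brier scores
shrink mechanically at lower incidence. The scaled Brier score, which
normalizes by the incidence-determined maximum, removes that artifact:
LR-first is no longer the best. GEE and CWGEE estimate a within-patient
correlation (ρ ≈ 0.3–0.4) and give more conservative performance than
logistic regression on all discharges. Cluster size is strongly coupled
to readmission (r = 0.57 between log discharge count and readmission
count).

The same pipeline is scriptable from a shell:

```bash
readmitsim simulate --patients 5000 --seed 1 --out cohort.csv
readmitsim study --table cohort.csv --sizes 2000,3000,4000 --seed 1 --out results/
readmitsim report --records results/study_records.csv --table cohort.csv --out figures/
```

`study` writes tidy per-(size, method, metric) records, a slope table
(change per 1000 patients with an ANCOVA comparison of slopes across
methods), and a run manifest; `report` renders one line chart per metric
and a readmission-percent-by-discharge-count bar chart.

## Layout

```
src/readmitsim/
  synthetic_cohort.py    generator + cluster summaries
  cohort_labeling.py     8h merge, 30-day labeling
  sampling.py            first/all discharges, patient-level split
  estimators.py          LR (IRLS), GEE, CWGEE, sandwich inference
  variable_selection.py  univariate screen, best subset, pruning
  performance.py         the five measures
  study.py               resampling grid, slopes, correlations, figures
  table_io.py            CSV dialect, schema validation, config sidecars
  cli.py                 simulate / label / study / report
docs/methods.md          model and design notes
```
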