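# Methods

## The data-generating model

Each patient i carries a latent frailty u_i ~ N(0, σ²) shared by all of
their discharges. The frailty enters the cohort twice:

* **cluster size** — the number of discharges is
  n_i = 1 + Poisson(λ · exp(γ · u_i)); γ > 0 makes sicker patients return
  more often, so cluster size is *informative*;
* **outcome** — each discharge's 30-day readmission indicator is
  Y_ij ~ Bernoulli(expit(α + βᵀX_ij + u_i)).

This shared-parameter construction is the minimal mechanism that couples
a patient's discharge count to their readmission risk, which is the
phenomenon the whole package studies. The frailty also induces the
within-patient outcome correlation that GEE's exchangeable working
structure models.

Covariates mix patient-constant indicators (Bernoulli(1/2), recoded ±1 so
they are standardized) and discharge-varying continuous measurements
(standard normal). Varying covariates additionally *load on the frailty*:
covariate j is (z + l_j·u_i)/√(1 + l_j²σ²) with
l_j = `frailty_loading` · sign(β_j). Clinically, sick patients drift in
the risk-increasing direction of each measurement (prior utilization,
labs, comorbidity flags); statistically, this loading is what allows a
covariate-only model's predicted risk to correlate with discharge count.
With `frailty_loading = 0` covariates are pure noise with respect to
frailty and predicted risk is uncorrelated with cluster size even when
γ > 0 — useful for isolating the cluster-size channel in tests.

### Default parameters

| parameter | default | meaning / why |
|---|---|---|
| `frailty_sd` (σ) | 1.1 | latent heterogeneity; sets within-cluster correlation ρ ≈ 0.1–0.4 depending on weighting |
| `cluster_rate` (λ) | 0.65 | mean excess discharges at u = 0 |
| `informativeness` (γ) | 1.1 | frailty → cluster-size coupling |
| `baseline_logit` (α) | −3.4 | anchors incidence |
| `covariate_effects` (β) | (0.8, −0.5, 0.3, 0.15, 0, 0.6, −0.4, 0.2, −0.1, 0) | strong, weak and null effects so variable selection has real work |
| `frailty_loading` | 0.3 | covariate–frailty coupling (above) |

These defaults were chosen once to emulate the structure of a large
urban-hospital diabetes cohort: ≈10% of first discharges and ≈20% of all
discharges are followed by a 30-day readmission (the informative-size
gap), a mean of ≈2.4 discharges per patient with roughly half of the
patients contributing a single discharge, and correlations between
discharge count and (observed, predicted) readmission in the 0.3–0.8
range. They are study conditions, not tuning knobs.

### Timeline mode

With `timestamps=True` the generator emits admission/discharge times such
that the labeling rules reconstruct the simulated outcomes exactly:
lengths of stay are uniform on 1–10 days; the gap after a readmitted
discharge is uniform on ≈(8 h, 30 d) and after a non-readmitted one on
≈(31 d, 365 d). A margin of ~0.1 day is kept at the 8-hour and 30-day
boundaries so that rounding timestamps to whole seconds cannot move a gap
across a window. Because a patient's final discharge has no subsequent
admission, its outcome is set to 0 in timeline mode; the labeling
post-condition makes the same choice, so the round trip is exact. Real
gap distributions are not modeled — only the threshold behavior matters
to the pipeline.

Boundary conventions are inclusive on both windows: a gap of exactly
8 hours merges; a readmission at exactly 30 days counts.

### Reproducibility

One root seed is split hierarchically (one child stream per patient), so
enlarging the cohort leaves existing patients' draws byte-identical, and
the same (config, seed) pair always produces the same table.

## Estimators

All three estimators target logit P(Y=1|X) = α + βᵀX.

* **Logistic regression** maximizes the Bernoulli likelihood by IRLS
  (tolerance 1e-8 on the max coefficient update, 100 iterations).
  Both the inverse-information covariance and a cluster-robust sandwich
  (clusters = patients) are reported. Perfect separation is flagged on
  the result, never returned silently.
* **GEE** solves Σᵢ wᵢ Dᵢᵀ Vᵢ⁻¹ (Yᵢ − μᵢ) = 0 with the exchangeable
  working correlation R = (1−ρ)I + ρJ, Fisher-scoring steps initialized
  at the logistic solution, and ρ re-estimated each outer iteration from
  Pearson residuals. The closed form
  R⁻¹v = [v − c_n(Σv)1]/(1−ρ), c_n = ρ/(1+(n−1)ρ), lets every quantity be
  computed by grouped vector operations (no per-cluster inversions), so
  fits scale linearly in rows.
* **CWGEE** is the same machinery with cluster weights wᵢ = 1/nᵢ applied
  to each cluster's whole contribution — estimating function, bread and
  meat alike. Weighting clusters equally per patient re-targets the
  estimation at the per-patient marginal, which is consistent under
  informative cluster size.

The ρ moment estimator uses the degrees-of-freedom-corrected convention:
scale = Σr²/(N − p) and pairwise denominator (#pairs − p). This is the
convention of widely used GEE software, which makes the solver directly
comparable against an independent implementation in the oracle tests
(they agree to ≈1e-11 on small data). ρ estimates outside [0, 0.99] are
clamped with a warning by default; the bounds are a parameter because
negative exchangeable correlation (bounded below by −1/(n−1)) is
legitimate and the clamp must be released when comparing against
references that do not clamp.

A subtlety worth knowing: with an exchangeable structure the effective
weight of a cluster's mean residual is n/(1+(n−1)ρ), which saturates at
1/ρ for large clusters. Unweighted exchangeable GEE therefore *already*
discounts large clusters and sits between the per-discharge marginal
(independence weighting) and the per-patient marginal (CWGEE). In
cohorts where covariates partially proxy the frailty, the calibration
difference between GEE and CWGEE can be small and noisy; the clean
contrast is CWGEE versus the discharge-weighted logistic fit.

## Variable selection

Per estimator family: (1) univariate screen keeping candidates with Wald
p < 0.1 (cluster-robust SEs throughout — the defensible default under
clustering — switchable to naive); a candidate whose fit fails or does
not converge is excluded with an explicit reason. (2) Best-subset
selection by AIC for logistic regression and QIC
(−2Q + 2·trace(Ω̂_I V̂_R)) for GEE/CWGEE, enumerating all subsets up to 15
screened covariates and falling back to forward search beyond that.
(3) Backward pruning refits after dropping the least significant
covariate until everything retained has p < 0.05; ties break on |z| and
then name, so selection is deterministic and row-order invariant.
Rank-deficient subsets score +∞, which resolves exactly-collinear
candidate pairs to a single survivor.

## Performance measures

AUC (Mann–Whitney, ties at 1/2), Pearson correlation between outcome and
prediction, coefficient of discrimination D = |mean p̂(events) − mean
p̂(non-events)|, Brier score, and scaled Brier 1 − Brier/Brier_max.
mean(p) inside Brier_max = mean(p)(1−mean(p)) is taken to be the
*observed incidence* of the evaluation sample (for a calibrated model the
mean prediction is close to the incidence); `convention="mean_prediction"`
switches to the mean predicted probability. Any metric that is undefined
on a sample (single outcome class, zero-variance predictions) is NaN —
never silently 0. Each model is evaluated in its own sampling frame:
first-discharge models on validation first discharges, all-discharge
models on all validation discharges.

## The resampling study

For each size on the grid (default 2000–17000 by 1000; tests use a
reduced grid) a subset of patients is drawn without replacement,
split 60/40 at the patient level — no patient ever straddles the split —
and each method runs the full screen/select/fit/evaluate pipeline.
Subsets are drawn independently per size and one replicate per size is
the default, matching a single-trajectory experimental design;
`replicates > 1` is available for property checks. Metric-vs-size slopes
are reported per 1000 patients from per-method OLS, together with two
ANCOVA-style summaries per metric: an interaction F-test of slope
equality across methods and the common-slope test from the
parallel-lines model (both are emitted because either parameterization
is defensible). Failed cells record NaN metrics plus a reason and never
abort the grid.

### What the synthetic study does and does not show

The qualitative findings are robust in simulation: the first-discharge
frame understates the readmission rate by ≈2×; the first-discharge model
posts the smallest raw Brier score while its scaled Brier advantage
disappears; discharge counts correlate positively with readmission
counts and with model-predicted risk (ordering LR-all > GEE ≳ CWGEE);
AUC, D, correlation and scaled Brier improve with cohort size for the
clustering-aware methods.

One caveat is instructive: a validation draw's *raw* Brier score is
dominated by that draw's incidence term p(1−p), and across resampled
subsets the incidence noise exceeds the model-improvement signal at
desk-scale seed counts, so the sign of the raw-Brier-vs-size slope for
GEE/CWGEE is unstable even when the incidence-adjusted slope is negative.
That dependence of the Brier score on incidence is precisely the reason
the scaled Brier score is part of the measure set — and the scaled-Brier
slope is stably positive.

The generator emulates structure, not clinical content: its covariates
are generic standardized variables, not the dozens of real administrative
and clinical variables of an EHR cohort; the frailty is one-dimensional;
admission-gap distributions are schematic. Passing tests therefore
demonstrate properties of the estimators and of the sampling/evaluation
design under informative cluster size — they do not certify performance
numbers on any real hospital population.

## Numerical choices

* Convergence: max |Δβ| < 1e-8, ≤100 outer iterations (GEE initialized at
  the logistic solution); the estimating-function max-norm at the
  returned estimate is stored on every fit.
* μ(1−μ) is floored at 1e-12 inside GEE iterations so diverging candidate
  fits during subset enumeration cannot produce NaN residuals.
* Clusters with constant outcomes contribute normally; nothing is
  dropped.
* Train-count rounding in the patient split is round-half-up.
* CSV I/O uses one dialect with round-trip float parsing, so equal tables
  serialize to identical bytes.

## Problem sizes used by the test suite

Unit tests run on cohorts of a few hundred to a few thousand patients;
the study-level qualitative suite uses five seeds of a 9000-patient
default cohort over the size grid {2000, 4000, 6000, 8000}, and the
estimator-vs-reference comparison uses 200 datasets of ≤12 clusters.
These sizes were chosen so the whole suite runs comfortably on one CPU
while keeping Monte-Carlo error well below the contrasts being asserted.
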