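# lsmatch

Large-scale **cardinality matching** and **propensity score matching**
for two-arm observational cohort studies, with covariate-balance
diagnostics and negative-control-based calibration of residual
confounding.

The package is aimed at epidemiologists and biostatisticians running
new-user, active-comparator designs on claims-style data: tens of
thousands of subjects, thousands of sparse binary covariates, survival
outcomes. It provides the full analytic chain — high-dimensional
propensity modelling, two matching engines, standardized-mean-difference
diagnostics, intention-to-treat Cox estimation, and empirical-null
calibration — plus a synthetic cohort generator that emulates these
study conditions for validation and methods work.

## Methods at a glance

**Propensity model.** Candidate covariates are screened by observed
frequency (> 0.1% by default), then an L1-penalized (LASSO) logistic
regression of treatment on all candidates is fitted with 10-fold
cross-validated choice of penalty. Covariates with nonzero coefficients
are the *matching covariates*.

**Greedy PSM.** 1:1 nearest-neighbour matching on the logit propensity
score within a caliper of 0.10 or 0.20 of the pooled SD of logit
scores, without replacement.

**Cardinality matching (CM).** An integer program selects the *largest*
1:1 sample satisfying explicit balance constraints: with selection
indicators `a_i`, `b_j` and matched size `n = Σaᵢ`,

```
maximize  n        subject to   Σaᵢ = Σbⱼ   and, per covariate k,
|Σᵢ aᵢ v_ik − Σⱼ bⱼ v_jk| ≤ c · s_pk · n
```

where `s_pk` is the pre-match pooled SD and `c` the balance criterion —
`c = 0` is *fine balance* (exactly equal marginal distributions), or
0.01 / 0.05 / 0.10 in SMD units. The selection formulation keeps the
program at O(n) variables; it is solved with the HiGHS
branch-and-bound solver.

**Balance.** `SMD = (x̄_target − x̄_comparator) / s_p` with the
pre-match pooled SD as denominator throughout; `|SMD| < 0.10` is read
as balanced. Per-draw reports pool across subsample draws.

**Residual confounding.** Negative-control outcomes (true hazard ratio
1) are estimated with unconditional Cox models; observed log HRs follow
`θ̂ᵢ ~ N(θᵢ + βᵢ, τᵢ²)` with `βᵢ ~ N(μ, σ²)`. The **expected
systematic error** `ESE = E|β|` summarizes residual bias, with 95%
credible intervals from Metropolis–Hastings sampling, and observed
safety-outcome estimates are calibrated against the fitted null
(shifted by `μ`, variance inflated by `σ²`).

## Worked example

Run a compact evaluation grid: a confounded synthetic cohort of 4,000
subjects (75/25 arm split, 40 sparse binary covariates of which 10
confound, 20 negative controls, a safety outcome with true HR 3), a
full-population cell plus five 10% subsample draws, and three matchers.

```python
from lsmatch.pipeline import run_evaluation, summarize

config = {
    "seed": 42,
    "simulation": {
        "n_subjects": 4000, "n_binary_covariates": 40, "n_confounders": 10,
        "n_negative_controls": 20, "prevalence_range": [0.02, 0.3],
    },
    "propensity": {"min_frequency": 0.01, "cv_folds": 10},
    "sample_groups": [
        {"name": "full", "fraction": 1.0, "n_draws": 1},
        {"name": "10pct", "fraction": 0.10, "n_draws": 5},
    ],
    "methods": [
        {"name": "psm-0.10", "kind": "psm", "caliper_fraction": 0.10},
        {"name": "cm-fine", "kind": "cm", "balance_criterion": 0.0},
        {"name": "cm-0.10", "kind": "cm", "balance_criterion": 0.10},
    ],
}
run_evaluation(config, output_dir="results/demo")
print(summarize("results/demo"))
```

Output (abridged):

```
cell                      avg size  max|SMD|m  imb prop     ESE       ESE 95% CrI
full/pre-match              4000.0      0.300     0.500   0.285   (0.112, 0.409)
  safety HR uncal 3.62 (2.20, 5.96); cal 2.76 (1.47, 5.18), p=0.00152
full/psm-0.10               1932.0      0.072     0.000   0.248   (0.013, 0.433)
full/cm-fine                1990.0      0.000     0.000   0.311   (0.023, 0.547)
full/cm-0.10                1990.0      0.099     0.000   0.229   (0.022, 0.375)
  safety HR uncal 3.24 (1.87, 5.60); cal 2.80 (1.35, 5.81), p=0.00567
10pct/pre-match              399.0      0.556     0.907   0.386   (0.059, 0.682)
10pct/psm-0.10               186.8      0.330     0.500   0.326   (0.012, 0.596)
10pct/cm-fine                197.2      0.000     0.000   0.359   (0.011, 0.635)
10pct/cm-0.10                198.0      0.100     0.000   0.338   (0.010, 0.618)
```

Reading it: before matching half the matching covariates are imbalanced
(max |SMD| 0.30) and the safety HR is biased upward (3.62 vs the true
3.0). Cardinality matching retains more subjects than greedy PSM
(1,990 vs 1,932; 198 vs 187 in the 10% draws), never exceeds its
balance criterion (max |SMD| 0.099 at `c = 0.10`; exactly 0.000 under
fine balance), and in the small-sample cells greedy PSM leaves
substantial matching-covariate imbalance (max |SMD| 0.33, half the
covariates ≥ 0.10) while CM does not. Calibration shifts the
safety-outcome estimates toward the truth and widens their intervals to
absorb the residual systematic error measured on the negative controls.

The same grid is available from the shell:

```bash
lsmatch simulate --config sim.yaml --seed 42 --out cohort/
lsmatch match --cohort cohort/ --method cm --balance-criterion 0.05 --out pairs.csv
lsmatch evaluate --config analysis.yaml --out results/
lsmatch summarize results/
```

## Layout

| module | contents |
|---|---|
| `lsmatch.cohort` | `Cohort` container, CSV round-trip |
| `lsmatch.simulate` | synthetic cohort generator, stratified subsample draws |
| `lsmatch.propensity` | frequency screening, LASSO fit, scores, matching-covariate extraction |
| `lsmatch.psm` | caliper computation, greedy logit-score matching |
| `lsmatch.cardinality` | balance-constrained ILP, solver interface, rank pairing |
| `lsmatch.balance` | SMDs, balance tables, imbalance counts, pooling |
| `lsmatch.survival` | ITT time-at-risk, unconditional Cox fits |
| `lsmatch.calibration` | empirical null MLE, ESE, MCMC intervals, calibrated estimates |
| `lsmatch.pipeline` | evaluation grid orchestration, result bundles |
| `lsmatch.cli` | `lsmatch` command-line entry point |

See `docs/methods.md` for the full model description, the generator's
assumptions, and known limitations.
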