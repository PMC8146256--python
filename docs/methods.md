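# Methods

## Setting

`lsmatch` implements the analytic core of a large-scale two-arm
observational comparison in the new-user, active-comparator design:
subjects initiate one of two treatments (a *target* and a *comparator*
arm), carry thousands of sparse binary covariates of the kind produced
by claims databases (condition/drug/procedure indicators) plus a few
continuous covariates (age), and are followed for survival outcomes.
Confounding is addressed by 1:1 matching; residual confounding is
quantified with negative-control outcomes and an empirical-null
systematic-error model.

## Matching

**Propensity model.** Candidate covariates are those with observed
frequency strictly above a threshold (default 0.1%), computed over both
arms combined. The propensity model is an L1-penalized logistic
regression of arm on all candidates; the penalty is chosen to minimize
mean held-out deviance over seeded stratified 10-fold cross-validation
(the plain CV minimum, not the 1-SE rule, to maximize covariate
capture). Continuous covariates are standardized before penalization
and the scaling is folded back into the stored coefficients; binary
covariates enter as 0/1. *Matching covariates* are the candidates with
exactly nonzero coefficients — coordinate descent produces exact zeros,
so no epsilon threshold is applied.

**Propensity score matching (PSM).** Greedy 1:1 nearest-neighbour
matching on the logit score within a caliper of 0.10 or 0.20 of the
pooled SD of logit scores, `sqrt((s2_t + s2_c)/2)` with n−1 variances on
the pre-match scores. Units of the smaller arm are processed in a
seeded random permutation (greedy matching leaves the order unspecified;
randomizing avoids systematic order bias while staying reproducible);
each takes the nearest unmatched opposite-arm unit within the caliper,
ties broken by smallest subject id, matching without replacement.
Nearest-available lookups use two path-compressed disjoint-set forests
over the score-sorted opposite arm, so matching is near-linear.

**Cardinality matching (CM).** Binary selection indicators `a_i`
(target) and `b_j` (comparator) maximize the matched count
`n = Σ a_i` subject to `Σ a_i = Σ b_j` and, for each matching covariate
`k` with pre-match pooled SD `s_pk > 0`,

    |Σ_i a_i v_ik − Σ_j b_j v_jk| ≤ c · s_pk · n,

where `c` is the balance criterion (0 = fine balance, or
0.01/0.05/0.10). Each absolute constraint is two linear inequalities;
`n` on the right-hand side is itself `Σ a_i`, so the program stays
linear with O(n) variables — the property that makes the approach
viable at large scale, as opposed to O(n²) pairwise-assignment
formulations. Because the downstream effect model is unconditional,
only the selected sets matter; selected subjects are rank-paired by
propensity score purely for reporting. The program is solved with the
HiGHS branch-and-bound solver (via `scipy.optimize.milp`), gap
tolerance 0 by default (proved optimality) with configurable relaxation
and time limit. Infeasibility — no nonempty sample satisfies the
constraints, or the time limit expires without an incumbent — is
reported via `feasible=False`, never silently relaxed; the CLI suggests
loosening the criterion.

With binary covariates and equal matched group sizes, fine balance
(`c = 0`) forces equal integer covariate sums, so post-match SMDs are
*exactly* zero in floating point. Continuous covariates enter the
constraints on their raw scale and are balanced to the solver's
feasibility tolerance rather than bit-exactly.

## Balance diagnostics

`SMD = (x̄_target − x̄_comparator) / s_p`, where `s_p` is always the
**pre-match** pooled SD (unweighted two-group form, n−1 variances) —
post-match SMDs therefore measure improvement against the original
scale. `|SMD| < 0.10` strictly is read as balanced; 0.10 itself counts
as imbalanced. Covariates with zero pre-match pooled SD are flagged
undefined and excluded from summaries rather than counted as balanced
(subsample draws can lose rare covariates entirely). Per-draw reports
are pooled by concatenating SMDs across draws; summaries report the
pooled mean absolute SMD, SD, maximum, pooled imbalance
count/proportion, and the per-draw imbalance count and proportion
averaged across draws (both are emitted because "average frequency of
imbalance" can be read either way).

## Outcomes

**Time-at-risk** is intention-to-treat: day 1 post-index to the
earliest of the study end, end of continuous exposure extended by a
30-day persistence gap, and end of observation; subjects with under 1
day at risk are excluded. **Effect estimation** is an unconditional Cox
proportional-hazards model with treatment as the only covariate
(matched pairs are treated as an analytic cohort, so estimates are
invariant to the pairing), Efron tie handling (day-granular synthetic
times produce many ties), Newton precision 1e-9. Outcomes with zero
events in either arm are flagged non-estimable and dropped, with counts
logged. Across subsample draws, per-outcome estimates are obtained from
one fit on the stacked post-match observations of all draws; the
stacked fit is unstratified by draw (a draw-stratified alternative
would change risk sets but not the null-centering logic).

## Systematic error and calibration

Negative-control outcomes have true hazard ratio 1, so each observed
log HR decomposes as `θ̂_i ~ N(θ_i + β_i, τ_i²)` with `θ_i = 0` and
`β_i ~ N(μ, σ²)`. The marginal likelihood `N(θ̂_i; μ, σ² + τ_i²)` is
maximized over `(μ, σ ≥ 0)` by L-BFGS-B; a boundary fit at `σ = 0` is
flagged. The **expected systematic error** is the folded-normal mean

    ESE = E|β| = σ·sqrt(2/π)·exp(−μ²/(2σ²)) + μ·(1 − 2Φ(−μ/σ)),

with `ESE = |μ|` at `σ = 0`. Uncertainty comes from random-walk
Metropolis–Hastings over `(μ, log σ)` with flat priors; `log σ` gets a
flat prior on the wide compact support `[−10, 5]` because a fully
unbounded flat prior is improper here (the likelihood tends to a
positive constant as `σ → 0`). Proposal SDs adapt toward ~30%
acceptance during burn-in and are then frozen; a final acceptance rate
outside [0.1, 0.6] raises a warning. ESE is computed per posterior
sample and the 2.5/97.5 percentiles form the 95% credible interval.

**Calibration** of an observed estimate uses the null-based
shift-and-inflate rule: calibrated log HR `θ̂ − μ` with SE
`sqrt(σ² + τ²)`, symmetric normal CI, and a two-sided p-value for `θ̂`
under `N(μ, σ² + τ²)`. Methods that also use positive controls to
calibrate the CI width exist, but with negative controls as the only
input this rule is the consistent choice; with a degenerate null
(μ = 0, σ = 0) it reduces exactly to the uncalibrated statistics.

## Synthetic cohort generator

The generator produces the study conditions the evaluation assumes, not
a particular real dataset:

- **Arm split**: target probability follows a logistic model in the
  confounder columns and standardized age; the intercept is calibrated
  by root-finding so the marginal comparator fraction equals the
  configured value (default 0.25, emulating a 75/25 split). With all
  treatment coefficients zero, assignment is marginal Bernoulli.
- **Covariates**: sparse binary indicators with log-uniform prevalences
  over a configurable range (default 0.001–0.3), emulating the
  many-rare-codes profile of claims data that the frequency-threshold
  heuristic is designed for. A designated leading subset are
  confounders affecting both assignment and outcome hazards; default
  effects are alternating-sign ramps (log-odds up to 0.8, log-hazard up
  to 0.5) so confounding has a consistent direction per covariate.
- **Outcomes**: exponential event times under proportional hazards
  (baseline 1e-4/day), day-granular. Negative-control hazards (default
  105 outcomes) depend on confounders and age but never on arm, so
  their true HR is exactly 1 by construction; the safety outcome's
  hazard is multiplied by a true HR (default 3.0, an
  ACEI-angioedema-like effect) in the target arm.
- **Censoring**: exposure-era and observation durations are exponential
  (means 180 and 500 days) with era end capped at observation end;
  index dates are uniform over a 1-year window with study end at day
  1000.
- **Subsampling**: stratified draws without replacement keep
  `floor(fraction × arm size)` per arm — reproducing, at 10%/1%/0.5% of
  a 129,078/43,039 cohort, per-draw counts of 12,907/4,303, 1,290/430
  and 645/215. Draws use independent substreams spawned from one seed.

What the generator does *not* emulate: correlated covariate structure
(codes co-occur in real claims), non-proportional hazards, informative
censoring, calendar-time trends, and vocabulary hierarchies. Passing
tests therefore demonstrate the correctness and the qualitative
behaviour of the machinery (retention orderings, balance guarantees,
null-centering, calibration coverage) — not the quantitative operating
characteristics on any real database.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: cohorts of
2,000–20,000 subjects with tens of covariates, chosen so each guarantee
is exercised with adequate power while a full run of the suite stays in
the minutes range. Exhaustive-enumeration oracles for the ILP use ≤6
units per arm. The MILP gap tolerance defaults to 0; integral solutions
are read off at a 0.5 threshold. MCMC defaults are 10,000 iterations
after 2,000 burn-in. All randomness in the pipeline derives from one
master seed through named substreams (CRC32-hashed labels), so reruns
are byte-identical.

## Known limitations

- Greedy PSM is order-dependent by construction; the seeded random
  processing order makes this reproducible but not order-free (optimal
  full matching is out of scope).
- The CM solve time grows with arm sizes and constraint count;
  instances beyond ~10⁵ variables need a nonzero gap tolerance or time
  limit, and a time-out without incumbent is reported as infeasible.
- The empirical-null model assumes normally distributed systematic
  error across negative controls with outcome-independent (μ, σ);
  effect-size-dependent bias models are out of scope.
- With very few estimable negative controls (small subsamples), the
  MLE often lands on the σ = 0 boundary and the ESE point estimate
  collapses to |μ|; the credible interval is the more honest summary
  there.
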