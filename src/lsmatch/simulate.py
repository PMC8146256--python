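"""Seeded synthetic new-user cohort generator.

Emulates a two-arm active-comparator claims cohort: a ~75/25 arm split,
high-dimensional sparse binary covariates with log-uniform prevalences
(many rare codes), confounded treatment assignment through a logistic
model in a subset of covariates plus age, exponential survival outcomes
under proportional hazards, and stratified subsample draws.

Negative-control outcomes have hazards that depend on the confounders
but never on the treatment arm, so their true hazard ratio is exactly 1;
a designated safety outcome has its hazard multiplied by a configurable
true hazard ratio in the target arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import COMPARATOR, TARGET, Cohort

SAFETY_OUTCOME = "safety"


def _default_coefficients(k: int, scale: float) -> np.ndarray:
    """Alternating-sign effects with magnitudes spread over [scale/4, scale]."""
    if k == 0:
        return np.zeros(0)
    mags = np.linspace(scale / 4, scale, k)
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return mags * signs


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions of a new-user antihypertensive
    cohort: 25% of subjects in the comparator arm, 105 negative-control
    outcomes with true hazard ratio 1, day-granular follow-up, and
    covariate prevalences spanning three orders of magnitude.
    """

    n_subjects: int = 20_000
    comparator_fraction: float = 0.25
    n_binary_covariates: int = 200
    prevalence_range: tuple[float, float] = (0.001, 0.3)
    n_confounders: int = 20
    #: log-odds effects of the confounders on target-arm assignment;
    #: scalar broadcasts, None gives an alternating-sign default ramp
    treatment_coefficients: object = None
    #: log-hazard effects of the confounders on every outcome
    hazard_coefficients: object = None
    treatment_age_coefficient: float = 0.3
    hazard_age_coefficient: float = 0.2
    n_negative_controls: int = 105
    safety_outcome_true_hr: float = 3.0
    baseline_hazard: float = 1e-4
    exposure_mean_days: float = 180.0
    observation_mean_days: float = 500.0
    study_end_day: int = 1000
    index_day_range: tuple[int, int] = (0, 365)
    age_mean: float = 45.0
    age_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.comparator_fraction < 1:
            raise ValueError("comparator_fraction must be in (0, 1)")
        for name in ("n_subjects", "n_binary_covariates", "study_end_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_negative_controls < 0 or self.n_confounders < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_confounders > self.n_binary_covariates:
            raise ValueError("n_confounders must not exceed n_binary_covariates")
        lo, hi = self.prevalence_range
        if hi <= 0 or lo <= 0 or lo > hi or hi >= 1:
            raise ValueError("prevalence_range must satisfy 0 < min <= max < 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.safety_outcome_true_hr <= 0:
            raise ValueError("safety_outcome_true_hr must be positive")
        # fail fast on mis-sized coefficient vectors
        self.resolved_treatment_coefficients()
        self.resolved_hazard_coefficients()

    def resolved_treatment_coefficients(self) -> np.ndarray:
        return self._resolve(self.treatment_coefficients, 0.8)

    def resolved_hazard_coefficients(self) -> np.ndarray:
        return self._resolve(self.hazard_coefficients, 0.5)

    def _resolve(self, raw, default_scale: float) -> np.ndarray:
        k = self.n_confounders
        if raw is None:
            return _default_coefficients(k, default_scale)
        arr = np.atleast_1d(np.asarray(raw, dtype=float))
        if arr.size == 1:
            return np.full(k, arr.item())
        if arr.size != k:
            raise ValueError(
                f"expected {k} coefficients, got {arr.size}"
            )
        return arr

    @property
    def negative_control_ids(self) -> list[str]:
        return [f"nc_{i:03d}" for i in range(self.n_negative_controls)]


def _sparse_bernoulli(
    rng: np.random.Generator, n: int, prevalences: np.ndarray
) -> sp.csr_matrix:
    """Column-wise sparse Bernoulli draws (efficient for rare covariates)."""
    rows, cols = [], []
    for j, p in enumerate(prevalences):
        k = rng.binomial(n, p)
        if k == 0:
            continue
        rows.append(rng.choice(n, size=k, replace=False))
        cols.append(np.full(k, j, dtype=np.int64))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.zeros(0, dtype=np.int64)
    return sp.csr_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, len(prevalences))
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a confounded two-arm cohort with survival outcomes.

    Treatment assignment follows a logistic model in the confounder
    columns and standardized age, with the intercept calibrated so the
    marginal comparator fraction matches ``config.comparator_fraction``.
    Outcome event times are exponential under proportional hazards;
    events after the end of observation are discarded (they could never
    enter any time-at-risk window).
    """
    ss = np.random.SeedSequence(config.seed)
    (
        ss_prev,
        ss_x,
        ss_age,
        ss_arm,
        ss_days,
        ss_events,
    ) = ss.spawn(6)

    n = config.n_subjects
    lo, hi = config.prevalence_range
    rng_prev = np.random.default_rng(ss_prev)
    # log-uniform prevalences: many rare codes, few common ones
    prevalences = np.exp(
        rng_prev.uniform(np.log(lo), np.log(hi), size=config.n_binary_covariates)
    )
    X = _sparse_bernoulli(np.random.default_rng(ss_x), n, prevalences)

    rng_age = np.random.default_rng(ss_age)
    age = np.clip(
        rng_age.normal(config.age_mean, config.age_sd, size=n), 18, 64
    ).round(1)
    age_std = (age - age.mean()) / (age.std() or 1.0)

    gamma = config.resolved_treatment_coefficients()
    conf = np.asarray(
        X[:, : config.n_confounders].todense(), dtype=float
    )
    lp = conf @ gamma + config.treatment_age_coefficient * age_std

    p_target = 1.0 - config.comparator_fraction

    def _excess(b: float) -> float:
        return float(expit(b + lp).mean() - p_target)

    intercept = brentq(_excess, -30.0, 30.0)
    rng_arm = np.random.default_rng(ss_arm)
    is_target = rng_arm.random(n) < expit(intercept + lp)
    arm = np.where(is_target, TARGET, COMPARATOR)

    rng_days = np.random.default_rng(ss_days)
    d0, d1 = config.index_day_range
    index_day = rng_days.integers(d0, max(d0 + 1, d1), size=n)
    obs_dur = np.ceil(
        rng_days.exponential(config.observation_mean_days, size=n)
    ).astype(np.int64) + 1
    exp_dur = np.minimum(
        np.ceil(rng_days.exponential(config.exposure_mean_days, size=n)).astype(
            np.int64
        )
        + 1,
        obs_dur,
    )
    observation_end = index_day + obs_dur
    exposure_end = index_day + exp_dur

    subjects = pd.DataFrame(
        {
            "arm": arm,
            "index_day": index_day,
            "exposure_end_day": exposure_end,
            "observation_end_day": observation_end,
            "age": age,
        },
        index=pd.RangeIndex(n, name="subject_id"),
    )

    eta = config.resolved_hazard_coefficients()
    log_rate_base = (
        np.log(config.baseline_hazard)
        + conf @ eta
        + config.hazard_age_coefficient * age_std
    )
    outcome_ids = config.negative_control_ids + [SAFETY_OUTCOME]
    ev_subj, ev_out, ev_day = [], [], []
    child_streams = ss_events.spawn(len(outcome_ids))
    for oid, child in zip(outcome_ids, child_streams):
        rng_o = np.random.default_rng(child)
        log_rate = log_rate_base.copy()
        if oid == SAFETY_OUTCOME:
            log_rate = log_rate + np.where(
                is_target, np.log(config.safety_outcome_true_hr), 0.0
            )
        t = rng_o.exponential(np.exp(-log_rate))
        event_day = index_day + np.maximum(1, np.ceil(t).astype(np.int64))
        keep = event_day <= observation_end
        ev_subj.append(np.flatnonzero(keep))
        ev_out.append(np.full(keep.sum(), oid, dtype=object))
        ev_day.append(event_day[keep])
    events = pd.DataFrame(
        {
            "subject_id": np.concatenate(ev_subj),
            "outcome_id": np.concatenate(ev_out),
            "event_day": np.concatenate(ev_day),
        }
    )

    binary_ids = np.array(
        [f"x_{j:04d}" for j in range(config.n_binary_covariates)], dtype=object
    )
    return Cohort(subjects=subjects, X=X, binary_ids=binary_ids, events=events)


def draw_subsamples(
    cohort: Cohort, fraction: float, n_draws: int, seed: int
) -> list[Cohort]:
    """Stratified subsample draws without replacement.

    Each draw keeps ``floor(fraction * arm size)`` subjects per arm,
    sampled without replacement within the draw; draws are mutually
    independent (sampling is with replacement across draws).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    per_arm = {}
    for arm in (TARGET, COMPARATOR):
        ids = cohort.arm_ids(arm)
        k = int(np.floor(fraction * len(ids)))
        if k == 0:
            raise ValueError(
                f"fraction {fraction} empties the {arm} arm ({len(ids)} subjects)"
            )
        per_arm[arm] = (ids, k)
    draws = []
    for child in np.random.SeedSequence(seed).spawn(n_draws):
        rng = np.random.default_rng(child)
        chosen = np.concatenate(
            [rng.choice(ids, size=k, replace=False) for ids, k in per_arm.values()]
        )
        draws.append(cohort.subset(np.sort(chosen)))
    return draws
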