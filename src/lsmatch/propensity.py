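"""Large-scale propensity modelling.

Candidate covariates are screened by a frequency heuristic (observed
prevalence above a threshold), then an L1-penalized logistic regression
of arm on all candidates is fitted with cross-validated choice of the
penalty. Covariates retaining nonzero coefficients are the "matching
covariates" used downstream both for score-based matching and as the
balance-constraint set in cardinality matching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from sklearn.linear_model import LogisticRegressionCV, LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import TARGET, Cohort


@dataclass
class PropensityModel:
    """Sparse logistic propensity model on the original covariate scale.

    ``coefficients`` maps covariate id to its log-odds coefficient per
    raw covariate unit (continuous covariates are standardized before
    penalization; the stored coefficients fold the scaling back in, so
    prediction is a plain linear predictor over raw values).
    """

    intercept: float
    coefficients: dict[str, float]
    regularization_strength: float  # lambda = 1 / C of the selected fit
    candidate_covariate_ids: list[str]
    cv_folds: int = 10
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.coefficients) - set(self.candidate_covariate_ids)
        if extra:
            raise ValueError(f"coefficients outside candidate set: {sorted(extra)[:5]}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "regularization_strength": self.regularization_strength,
                    "candidate_covariate_ids": list(self.candidate_covariate_ids),
                    "cv_folds": self.cv_folds,
                    "seed": self.seed,
                    "meta": self.meta,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "PropensityModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def select_candidate_covariates(cohort: Cohort, min_frequency: float) -> set[str]:
    """Covariates with observed frequency strictly above ``min_frequency``.

    Frequency is computed over the whole cohort, both arms combined.
    """
    if not 0 <= min_frequency < 1:
        raise ValueError("min_frequency must be in [0, 1)")
    freq = cohort.frequencies()  # raises on empty cohort
    return set(freq.index[freq > min_frequency])


def _design(
    cohort: Cohort, candidates: list[str]
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Feature matrix plus per-column (center, scale) used before fitting."""
    bin_set = set(cohort.binary_ids)
    centers = np.zeros(len(candidates))
    scales = np.ones(len(candidates))
    cols = []
    for j, cid in enumerate(candidates):
        v = cohort.values([cid])[:, 0]
        if cid not in bin_set:  # continuous: standardize
            centers[j] = v.mean()
            scales[j] = v.std() or 1.0
            v = (v - centers[j]) / scales[j]
        cols.append(sp.csr_matrix(v.reshape(-1, 1)))
    return sp.hstack(cols, format="csr"), centers, scales


def fit_propensity_model(
    cohort: Cohort,
    candidates,
    cv_folds: int = 10,
    seed: int = 0,
    n_penalties: int = 20,
) -> PropensityModel:
    """L1 logistic regression of arm on candidates, CV-tuned penalty.

    The penalty is chosen to minimize mean held-out deviance over
    ``cv_folds`` seeded stratified folds. Under perfect separation the
    strongest penalty on the path is returned with a warning.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    y = (cohort.arms == TARGET).to_numpy().astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 subjects per arm")

    F, centers, scales = _design(cohort, candidates)
    Cs = np.logspace(-4, 2, n_penalties)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        refit=True,
        max_iter=2000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(F, y)
    chosen_C = float(clf.C_[0])
    coef = clf.coef_.ravel().copy()
    intercept = float(clf.intercept_[0])

    # perfect separation: fitted scores split the arms exactly
    scores = expit(intercept + F @ coef)
    if scores[y == 1].min() > scores[y == 0].max():
        warnings.warn(
            "perfect separation detected; returning the strongest penalty "
            "on the regularization path",
            stacklevel=2,
        )
        strongest = LogisticRegression(
            C=Cs[0], penalty="l1", solver="liblinear", max_iter=2000,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strongest.fit(F, y)
        chosen_C = float(Cs[0])
        coef = strongest.coef_.ravel().copy()
        intercept = float(strongest.intercept_[0])

    # fold standardization back into original-scale coefficients
    coef_orig = coef / scales
    intercept -= float(np.sum(coef * centers / scales))
    coefficients = {
        cid: float(c) for cid, c in zip(candidates, coef_orig) if c != 0.0
    }
    return PropensityModel(
        intercept=float(intercept),
        coefficients=coefficients,
        regularization_strength=1.0 / chosen_C,
        candidate_covariate_ids=candidates,
        cv_folds=cv_folds,
        seed=seed,
        meta={"n_subjects": cohort.n, "n_candidates": len(candidates)},
    )


def predict_scores(model: PropensityModel, cohort: Cohort) -> pd.Series:
    """Propensity of target-arm membership per subject, in (0, 1)."""
    lin = np.full(cohort.n, model.intercept)
    if model.coefficients:
        cids = list(model.coefficients)
        V = cohort.values(cids)
        lin = lin + V @ np.array([model.coefficients[c] for c in cids])
    return pd.Series(expit(lin), index=cohort.subjects.index, name="score")


def extract_matching_covariates(model: PropensityModel) -> set[str]:
    """Candidate covariates with exactly nonzero coefficients."""
    return {cid for cid, c in model.coefficients.items() if c != 0.0}
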