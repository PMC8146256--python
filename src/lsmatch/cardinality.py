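"""Cardinality matching: the largest balanced 1:1 sample by integer programming.

Selection formulation: binary indicators ``a_i`` (target arm) and
``b_j`` (comparator arm) choose equal-sized subsets maximizing the
matched count ``n = sum(a)`` subject to, for every matching covariate
``k``, a standardized-mean-difference constraint

    | sum_i a_i v_ik - sum_j b_j v_jk |  <=  criterion * s_pk * n,

with ``s_pk`` the pre-match pooled SD of the covariate. ``criterion = 0``
is fine balance (exactly equal matched sums). Because the downstream
effect model is unconditional, only the selected sets matter; pairing is
a deterministic rank-by-propensity-score convenience. This keeps the
program at O(n) variables rather than O(n^2) pairwise assignments.
"""

from __future__ import annotations

import contextlib
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import COMPARATOR, TARGET, Cohort
from .psm import MatchResult


@dataclass
class CMConfig:
    balance_criterion: float = 0.10
    matching_covariate_ids: list = field(default_factory=list)
    solver_time_limit: float = 300.0
    solver_gap_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.balance_criterion < 0:
            raise ValueError("balance_criterion must be >= 0")


@dataclass
class CMProblem:
    """Built ILP data: per-arm covariate values and per-covariate tolerances."""

    target_ids: np.ndarray
    comparator_ids: np.ndarray
    V_target: np.ndarray  # (n_target, K) constrained covariate values
    V_comparator: np.ndarray
    deltas: np.ndarray  # (K,) = criterion * pooled SD
    covariate_ids: list[str]  # constrained covariates (pooled SD > 0)
    pooled_sds: np.ndarray

    @property
    def n_variables(self) -> int:
        return len(self.target_ids) + len(self.comparator_ids)

    @property
    def n_constraints(self) -> int:
        return 1 + 2 * len(self.covariate_ids)


def pooled_sd(values_target: np.ndarray, values_comparator: np.ndarray) -> np.ndarray:
    """Unweighted two-group pooled SD, sample variances with n-1 denominator."""
    v1 = np.var(np.asarray(values_target, float), axis=0, ddof=1)
    v2 = np.var(np.asarray(values_comparator, float), axis=0, ddof=1)
    return np.sqrt((v1 + v2) / 2.0)


def build_problem(cohort: Cohort, config: CMConfig) -> CMProblem:
    """Assemble the balance-constrained selection problem.

    Pooled SDs are computed on the pre-match cohort passed in; covariates
    with zero pooled SD carry no balance information and are dropped from
    the constraint set.
    """
    cov_ids = sorted(config.matching_covariate_ids)
    t_ids = cohort.arm_ids(TARGET)
    c_ids = cohort.arm_ids(COMPARATOR)
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise ValueError("both arms must be nonempty")
    if not cov_ids:
        warnings.warn(
            "empty matching-covariate set: solving an unconstrained "
            "size-maximization problem",
            stacklevel=2,
        )
        Vt = np.zeros((len(t_ids), 0))
        Vc = np.zeros((len(c_ids), 0))
        return CMProblem(t_ids, c_ids, Vt, Vc, np.zeros(0), [], np.zeros(0))

    Vt = cohort.values(cov_ids, t_ids)
    Vc = cohort.values(cov_ids, c_ids)
    sds = pooled_sd(Vt, Vc)
    keep = sds > 0
    kept = [cid for cid, k in zip(cov_ids, keep) if k]
    return CMProblem(
        target_ids=t_ids,
        comparator_ids=c_ids,
        V_target=Vt[:, keep],
        V_comparator=Vc[:, keep],
        deltas=config.balance_criterion * sds[keep],
        covariate_ids=kept,
        pooled_sds=sds[keep],
    )


@contextlib.contextmanager
def _quiet_native_stdout():
    """Mute the solver's occasional C-level stdout chatter."""
    try:
        import sys

        fd = sys.stdout.fileno()
    except (OSError, ValueError, AttributeError):
        yield
        return
    saved = os.dup(fd)
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        sys.stdout.flush()
        os.dup2(devnull, fd)
        yield
    finally:
        sys.stdout.flush()
        os.dup2(saved, fd)
        os.close(saved)
        os.close(devnull)


def solve_cardinality_match(
    problem: CMProblem,
    config: CMConfig,
    scores: pd.Series | None = None,
) -> MatchResult:
    """Solve for the maximum balanced matched-sample size.

    Returns ``feasible=False`` with an empty pair list when no sample of
    at least one pair satisfies the constraints, or when the solver
    exhausts its time limit without an incumbent. Selected subsets are
    rank-paired on the propensity score when ``scores`` is given, else
    on subject id.
    """
    try:
        from scipy.optimize import Bounds, LinearConstraint, milp
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "cardinality matching requires a mixed-integer solver backend"
        ) from exc

    nt, nc = len(problem.target_ids), len(problem.comparator_ids)
    K = len(problem.covariate_ids)
    c = np.concatenate([-np.ones(nt), np.zeros(nc)])

    rows = [sp.csr_matrix(np.concatenate([np.ones(nt), -np.ones(nc)]))]
    lb = [0.0]
    ub = [0.0]
    for k in range(K):
        vt = problem.V_target[:, k]
        vc = problem.V_comparator[:, k]
        d = problem.deltas[k]
        # sum(a v) - sum(b v) - d sum(a) <= 0
        rows.append(sp.csr_matrix(np.concatenate([vt - d, -vc])))
        lb.append(-np.inf)
        ub.append(0.0)
        # sum(b v) - sum(a v) - d sum(a) <= 0
        rows.append(sp.csr_matrix(np.concatenate([-(vt + d), vc])))
        lb.append(-np.inf)
        ub.append(0.0)
    A = sp.vstack(rows, format="csc")

    with _quiet_native_stdout():
        res = milp(
            c,
            constraints=LinearConstraint(A, lb, ub),
            integrality=np.ones(nt + nc),
            bounds=Bounds(0, 1),
            options={
                "time_limit": config.solver_time_limit,
                "mip_rel_gap": config.solver_gap_tolerance,
            },
        )

    settings = {
        "balance_criterion": config.balance_criterion,
        "n_constrained_covariates": K,
        "n_variables": problem.n_variables,
        "n_constraints": problem.n_constraints,
        "solver_status": int(res.status),
        "solver_gap": (
            float(res.mip_gap) if getattr(res, "mip_gap", None) is not None
            else float("nan")
        ),
    }
    if res.x is None:
        return MatchResult(pairs=[], method="cm", settings=settings, feasible=False)
    sel = res.x > 0.5
    sel_t = problem.target_ids[sel[:nt]]
    sel_c = problem.comparator_ids[sel[nt:]]
    if len(sel_t) == 0 or len(sel_t) != len(sel_c):
        return MatchResult(pairs=[], method="cm", settings=settings, feasible=False)
    pairs = pair_selected(sel_t, sel_c, scores)
    return MatchResult(pairs=pairs, method="cm", settings=settings, feasible=True)


def pair_selected(
    selected_target,
    selected_comparator,
    scores: pd.Series | None = None,
) -> list[tuple[int, int]]:
    """Deterministic rank pairing of two equal-sized selected sets.

    The i-th target by ascending (score, id) is paired with the i-th
    comparator; any unconditional downstream analysis is invariant to
    this choice.
    """
    sel_t = np.sort(np.asarray(list(selected_target), dtype=np.int64))
    sel_c = np.sort(np.asarray(list(selected_comparator), dtype=np.int64))
    if len(sel_t) != len(sel_c):
        raise ValueError("selected sets must have equal size")
    if scores is not None:
        sel_t = sel_t[np.lexsort((sel_t, scores[sel_t].to_numpy()))]
        sel_c = sel_c[np.lexsort((sel_c, scores[sel_c].to_numpy()))]
    return [(int(t), int(c)) for t, c in zip(sel_t, sel_c)]
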