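from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from lsmatch import (
    CMConfig,
    build_problem,
    pair_selected,
    pooled_sd,
    solve_cardinality_match,
)

from conftest import make_cohort


def brute_force_max_size(Vt, Vc, criterion):
    """Exhaustive maximum balanced matched-sample size (tiny instances).

    Enumerates all equal-size subset pairs; the balance rule mirrors the
    ILP: |sum_A v - sum_B v| <= criterion * s_p * n for covariates with
    nonzero pre-match pooled SD.
    """
    Vt, Vc = np.atleast_2d(Vt).astype(float), np.atleast_2d(Vc).astype(float)
    sds = pooled_sd(Vt, Vc)
    keep = sds > 0
    Vt, Vc, sds = Vt[:, keep], Vc[:, keep], sds[keep]
    for n in range(min(len(Vt), len(Vc)), 0, -1):
        for A in combinations(range(len(Vt)), n):
            sa = Vt[list(A)].sum(axis=0)
            for B in combinations(range(len(Vc)), n):
                sb = Vc[list(B)].sum(axis=0)
                if np.all(np.abs(sa - sb) <= criterion * sds * n + 1e-9):
                    return n
    return 0


def _two_arm_cohort(Vt, Vc):
    Vt, Vc = np.atleast_2d(Vt), np.atleast_2d(Vc)
    arms = ["target"] * len(Vt) + ["comparator"] * len(Vc)
    return make_cohort(arms, X=np.vstack([Vt, Vc]))


class TestBuild:
    def test_fine_balance_deltas_are_zero(self):
        c = _two_arm_cohort(np.eye(3), np.eye(3))
        cfg = CMConfig(balance_criterion=0.0, matching_covariate_ids=["x_0000"])
        prob = build_problem(c, cfg)
        assert prob.deltas.tolist() == [0.0]

    def test_delta_scales_with_pooled_sd(self):
        # binary covariate with p=0.5 in both arms: pooled SD ~ 0.5
        Vt = np.array([[1], [1], [0], [0]])
        c = _two_arm_cohort(Vt, Vt)
        cfg = CMConfig(balance_criterion=0.10, matching_covariate_ids=["x_0000"])
        prob = build_problem(c, cfg)
        sd = np.sqrt(2 * (0.25 * 4 / 3) / 2)  # ddof=1 variance of (1,1,0,0)
        assert prob.deltas[0] == pytest.approx(0.10 * sd)

    def test_problem_dimensions(self):
        c = _two_arm_cohort(np.eye(4)[:, :3], np.ones((5, 3)) - np.eye(5)[:, :3])
        cfg = CMConfig(
            balance_criterion=0.05,
            matching_covariate_ids=["x_0000", "x_0001", "x_0002"],
        )
        prob = build_problem(c, cfg)
        assert prob.n_variables == 9
        assert prob.n_constraints == 1 + 2 * len(prob.covariate_ids)

    def test_zero_sd_covariates_excluded(self):
        Vt = np.array([[1, 1], [1, 0], [1, 1]])
        Vc = np.array([[1, 0], [1, 1], [1, 0]])
        c = _two_arm_cohort(Vt, Vc)
        cfg = CMConfig(
            balance_criterion=0.1, matching_covariate_ids=["x_0000", "x_0001"]
        )
        prob = build_problem(c, cfg)
        assert prob.covariate_ids == ["x_0001"]

    def test_empty_matching_set_warns(self):
        c = _two_arm_cohort(np.eye(2), np.eye(2))
        cfg = CMConfig(balance_criterion=0.1, matching_covariate_ids=[])
        with pytest.warns(UserWarning, match="unconstrained"):
            prob = build_problem(c, cfg)
        res = solve_cardinality_match(prob, cfg)
        assert res.n_pairs == 2


class TestSolve:
    def test_identical_rows_all_matched(self):
        V = np.array([[1, 0], [0, 1], [1, 1]])
        c = _two_arm_cohort(V, V)
        cfg = CMConfig(
            balance_criterion=0.0, matching_covariate_ids=["x_0000", "x_0001"]
        )
        res = solve_cardinality_match(build_problem(c, cfg), cfg)
        assert res.n_pairs == 3 and res.feasible

    def test_fine_balance_hand_enumerated(self):
        """Targets (1,1,0,0) vs comparators (1,0,0,0): max n is 3."""
        Vt = np.array([[1], [1], [0], [0]])
        Vc = np.array([[1], [0], [0], [0]])
        c = _two_arm_cohort(Vt, Vc)
        cfg = CMConfig(balance_criterion=0.0, matching_covariate_ids=["x_0000"])
        res = solve_cardinality_match(build_problem(c, cfg), cfg)
        assert res.n_pairs == 3
        assert brute_force_max_size(Vt, Vc, 0.0) == 3
        # matched sums equal under fine balance
        sel_t = set(res.matched_target_ids)
        sel_c = set(res.matched_comparator_ids)
        assert sum(Vt[i, 0] for i in sel_t) == sum(
            Vc[j - 4, 0] for j in sel_c
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_solver_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_c = rng.integers(3, 7), rng.integers(3, 7)
        k = rng.integers(1, 4)
        Vt = rng.binomial(1, 0.5, size=(n_t, k))
        Vc = rng.binomial(1, 0.5, size=(n_c, k))
        c = _two_arm_cohort(Vt, Vc)
        criterion = rng.choice([0.0, 0.05, 0.5])
        cfg = CMConfig(
            balance_criterion=float(criterion),
            matching_covariate_ids=[f"x_{j:04d}" for j in range(k)],
        )
        res = solve_cardinality_match(build_problem(c, cfg), cfg)
        assert res.n_pairs == brute_force_max_size(Vt, Vc, criterion)

    def test_retention_monotone_in_criterion(self, small_cohort):
        ids = [f"x_{j:04d}" for j in range(6)]
        sizes = []
        for crit in (0.0, 0.01, 0.05, 0.10):
            cfg = CMConfig(balance_criterion=crit, matching_covariate_ids=ids)
            res = solve_cardinality_match(build_problem(small_cohort, cfg), cfg)
            sizes.append(res.n_pairs)
        assert sizes == sorted(sizes)

    def test_balanceable_comparator_arm_fully_retained(self):
        """When every comparator can be balanced, n equals the smaller arm."""
        rng = np.random.default_rng(5)
        Vc = rng.binomial(1, 0.4, size=(30, 2))
        Vt = np.vstack([Vc, rng.binomial(1, 0.4, size=(40, 2))])
        c = _two_arm_cohort(Vt, Vc)
        cfg = CMConfig(
            balance_criterion=0.0, matching_covariate_ids=["x_0000", "x_0001"]
        )
        res = solve_cardinality_match(build_problem(c, cfg), cfg)
        assert res.n_pairs == 30

    def test_infeasible_returns_empty_and_flag(self):
        # separated continuous covariate: no subset sums can ever agree,
        # so only the empty sample satisfies fine balance
        c = make_cohort(
            ["target", "target", "comparator", "comparator"],
            age=[10.0, 12.0, 30.0, 31.0],
        )
        cfg = CMConfig(balance_criterion=0.0, matching_covariate_ids=["age"])
        res = solve_cardinality_match(build_problem(c, cfg), cfg)
        assert not res.feasible and res.pairs == []


class TestPairing:
    def test_singleton_and_bijection(self):
        assert pair_selected([5], [9]) == [(5, 9)]
        pairs = pair_selected([3, 1, 2], [6, 4, 5])
        assert sorted(t for t, _ in pairs) == [1, 2, 3]
        assert sorted(c for _, c in pairs) == [4, 5, 6]

    def test_rank_pairing_follows_scores(self):
        scores = pd.Series({1: 0.9, 2: 0.1, 11: 0.8, 12: 0.2})
        pairs = pair_selected([1, 2], [11, 12], scores)
        assert pairs == [(2, 12), (1, 11)]

    def test_unequal_sets_rejected(self):
        with pytest.raises(ValueError):
            pair_selected([1, 2], [3])
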