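"""Greedy 1:1 propensity score matching on the logit scale.

The caliper is a fraction (0.10 or 0.20) of the pooled standard
deviation of the logit of the pre-match propensity scores. Units of the
smaller arm are processed in a seeded random order; each takes the
closest unmatched opposite-arm unit within the caliper, without
replacement, ties broken by smallest subject id.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .cohort import COMPARATOR, TARGET


@dataclass
class PSMatchConfig:
    caliper_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.caliper_fraction <= 0:
            raise ValueError("caliper_fraction must be positive")


@dataclass
class MatchResult:
    """Matched 1:1 sample: (target_id, comparator_id) pairs.

    Shared by propensity score matching (``method="psm"``) and
    cardinality matching (``method="cm"``). ``feasible`` is False when a
    cardinality-matching solve found no nonempty balanced sample.
    """

    pairs: list[tuple[int, int]]
    method: str
    settings: dict = field(default_factory=dict)
    feasible: bool = True

    def __post_init__(self) -> None:
        flat = [s for p in self.pairs for s in p]
        if len(set(flat)) != len(flat):
            raise ValueError("a subject appears in more than one pair")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def matched_target_ids(self) -> np.ndarray:
        return np.array([t for t, _ in self.pairs], dtype=np.int64)

    @property
    def matched_comparator_ids(self) -> np.ndarray:
        return np.array([c for _, c in self.pairs], dtype=np.int64)

    @property
    def matched_ids(self) -> np.ndarray:
        return np.concatenate([self.matched_target_ids, self.matched_comparator_ids])

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.pairs, columns=["target_id", "comparator_id"]).to_csv(
            path, index=False
        )
        side = os.path.splitext(path)[0] + ".json"
        with open(side, "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "settings": self.settings,
                    "feasible": self.feasible,
                    "n_pairs": self.n_pairs,
                },
                fh,
                indent=1,
            )


def compute_caliper(
    scores: pd.Series, arms: pd.Series, caliper_fraction: float
) -> float:
    """Caliper width on the logit scale.

    ``caliper_fraction`` times the pooled SD of logit scores, where the
    pooled SD is ``sqrt((s2_target + s2_comparator) / 2)`` over the
    pre-match scores.
    """
    lg = logit(scores.astype(float))
    variances = []
    for arm in (TARGET, COMPARATOR):
        v = lg[arms == arm]
        if len(v) == 0:
            raise ValueError(f"{arm} arm is empty")
        variances.append(np.var(v, ddof=1) if len(v) > 1 else 0.0)
    pooled_sd = float(np.sqrt(np.mean(variances)))
    if not np.isfinite(pooled_sd) or pooled_sd == 0:
        raise ValueError("degenerate scores: zero pooled SD of logits")
    return caliper_fraction * pooled_sd


class _Avail:
    """Nearest-available-index lookups over a sorted array, with removal.

    Two disjoint-set forests with path compression: node ``x`` of the
    left forest represents index ``x - 1`` (node 0 is the "nothing to
    the left" sentinel), node ``x`` of the right forest represents index
    ``x`` (node ``n`` is the right sentinel). A node is a root while its
    index is still available.
    """

    def __init__(self, n: int):
        self.n = n
        self.pL = np.arange(n + 1)
        self.pR = np.arange(n + 1)

    @staticmethod
    def _find(p: np.ndarray, x: int) -> int:
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return int(root)

    def find_left(self, i: int) -> int:
        """Nearest available index <= i, or -1."""
        if i < 0:
            return -1
        return self._find(self.pL, i + 1) - 1

    def find_right(self, i: int) -> int:
        """Nearest available index >= i, or n."""
        if i >= self.n:
            return self.n
        return self._find(self.pR, i)

    def remove(self, i: int) -> None:
        self.pL[i + 1] = i
        self.pR[i] = i + 1


def greedy_match(
    scores: pd.Series,
    arms: pd.Series,
    config: PSMatchConfig,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching within a logit caliper."""
    if caliper is None:
        caliper = compute_caliper(scores, arms, config.caliper_fraction)
    lg = logit(scores.astype(float))
    ids = {arm: arms.index[arms == arm].to_numpy() for arm in (TARGET, COMPARATOR)}
    small_arm = min(ids, key=lambda a: len(ids[a]))
    big_arm = TARGET if small_arm == COMPARATOR else COMPARATOR

    rng = np.random.default_rng(config.seed)
    small_ids = rng.permutation(ids[small_arm])

    order = np.lexsort((ids[big_arm], lg[ids[big_arm]].to_numpy()))
    big_ids = ids[big_arm][order]
    big_lg = lg[big_ids].to_numpy()
    avail = _Avail(len(big_ids))

    pairs = []
    for sid in small_ids:
        v = lg[sid]
        pos = int(np.searchsorted(big_lg, v))
        l = avail.find_left(pos - 1)
        r = avail.find_right(pos)
        dl = v - big_lg[l] if l >= 0 else np.inf
        dr = big_lg[r] - v if r < len(big_ids) else np.inf
        d = min(dl, dr)
        if d > caliper:
            continue
        # collect every available unit at the minimal distance; smallest id wins
        cands = []
        j = l
        while j >= 0 and v - big_lg[j] == d:
            cands.append(j)
            j = avail.find_left(j - 1)
        j = r
        while j < len(big_ids) and big_lg[j] - v == d:
            cands.append(j)
            j = avail.find_right(j + 1)
        best = min(cands, key=lambda k: big_ids[k])
        avail.remove(best)
        bid = big_ids[best]
        pair = (sid, bid) if small_arm == TARGET else (bid, sid)
        pairs.append((int(pair[0]), int(pair[1])))

    return MatchResult(
        pairs=pairs,
        method="psm",
        settings={
            "caliper_fraction": config.caliper_fraction,
            "caliper": float(caliper),
            "seed": config.seed,
        },
        feasible=True,
    )
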