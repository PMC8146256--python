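"""Standardized mean differences and balance summaries.

The SMD of a covariate is ``(mean_target - mean_comparator) / s_p``
where ``s_p`` is always the *pre-match* pooled standard deviation
(unweighted two-group form), including when the means are computed on a
matched sample. ``|SMD| < 0.10`` is read as balanced. Per-draw reports
can be pooled so balance is assessed across subsample draws jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COMPARATOR, TARGET, Cohort
from .cardinality import pooled_sd
from .psm import MatchResult

BALANCE_THRESHOLD = 0.10


@dataclass
class BalanceEntry:
    covariate_id: str
    mean_target: float
    mean_comparator: float
    pooled_sd_prematch: float
    smd: float  # nan when pooled SD is zero
    defined: bool = True


@dataclass
class BalanceReport:
    entries: list[BalanceEntry]
    scope: str = "matching"  # {"candidate", "matching"}
    stage: str = "pre"  # {"pre", "post"}
    method: str = "pre-match"
    draw_id: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate_id": [e.covariate_id for e in self.entries],
                "scope": self.scope,
                "stage": self.stage,
                "method": self.method,
                "draw_id": self.draw_id,
                "mean_target": [e.mean_target for e in self.entries],
                "mean_comparator": [e.mean_comparator for e in self.entries],
                "pooled_sd_prematch": [e.pooled_sd_prematch for e in self.entries],
                "smd": [e.smd for e in self.entries],
                "defined": [e.defined for e in self.entries],
            }
        )

    def defined_smds(self) -> np.ndarray:
        return np.array([e.smd for e in self.entries if e.defined])


def compute_smd(
    values_target, values_comparator, pooled_sd_prematch: float
) -> float:
    """Signed standardized mean difference with a fixed denominator."""
    if pooled_sd_prematch <= 0:
        raise ValueError("pre-match pooled SD must be positive")
    return float(
        (np.mean(values_target) - np.mean(values_comparator)) / pooled_sd_prematch
    )


def balance_table(
    cohort: Cohort,
    match: MatchResult | None,
    covariate_ids,
    scope: str = "matching",
    draw_id: int = 0,
) -> BalanceReport:
    """Per-covariate balance entries, pre-match or on a matched sample.

    ``cohort`` is the pre-match population defining the pooled-SD
    denominators; when ``match`` is given, the means are recomputed on
    the matched subjects only.
    """
    covariate_ids = sorted(covariate_ids)
    t_ids = cohort.arm_ids(TARGET)
    c_ids = cohort.arm_ids(COMPARATOR)
    Vt_pre = cohort.values(covariate_ids, t_ids) if covariate_ids else np.zeros((0, 0))
    Vc_pre = cohort.values(covariate_ids, c_ids) if covariate_ids else np.zeros((0, 0))
    sds = pooled_sd(Vt_pre, Vc_pre) if covariate_ids else np.zeros(0)

    if match is None:
        Vt, Vc = Vt_pre, Vc_pre
        stage, method = "pre", "pre-match"
    else:
        Vt = cohort.values(covariate_ids, match.matched_target_ids)
        Vc = cohort.values(covariate_ids, match.matched_comparator_ids)
        stage, method = "post", match.method

    entries = []
    for j, cid in enumerate(covariate_ids):
        mt = float(Vt[:, j].mean()) if len(Vt) else np.nan
        mc = float(Vc[:, j].mean()) if len(Vc) else np.nan
        if sds[j] > 0:
            entries.append(
                BalanceEntry(cid, mt, mc, float(sds[j]), (mt - mc) / sds[j], True)
            )
        else:
            entries.append(BalanceEntry(cid, mt, mc, 0.0, np.nan, False))
    return BalanceReport(
        entries=entries, scope=scope, stage=stage, method=method, draw_id=draw_id
    )


def count_imbalanced(
    report: BalanceReport, threshold: float = BALANCE_THRESHOLD
) -> tuple[int, float]:
    """(count, proportion) of defined entries with ``|SMD| >= threshold``."""
    if not report.entries:
        raise ValueError("empty balance report")
    smds = report.defined_smds()
    if len(smds) == 0:
        return 0, float("nan")
    n_bad = int((np.abs(smds) >= threshold).sum())
    return n_bad, n_bad / len(smds)


def pool_reports(
    reports: list[BalanceReport], threshold: float = BALANCE_THRESHOLD
) -> dict:
    """Pool per-draw SMD distributions into one joint summary.

    Concatenates all defined SMDs across draws and reports the pooled
    mean absolute SMD, its SD and maximum, the pooled imbalance
    count/proportion, and the per-draw imbalance count and proportion
    averaged across draws.
    """
    if not reports:
        raise ValueError("no reports to pool")
    scopes = {r.scope for r in reports}
    stages = {r.stage for r in reports}
    if len(scopes) > 1 or len(stages) > 1:
        raise ValueError("reports mix scopes or stages")
    pooled = np.concatenate([r.defined_smds() for r in reports])
    per_draw = [count_imbalanced(r, threshold) for r in reports]
    counts = np.array([c for c, _ in per_draw], dtype=float)
    props = np.array([p for _, p in per_draw], dtype=float)
    abs_pooled = np.abs(pooled)
    return {
        "scope": reports[0].scope,
        "stage": reports[0].stage,
        "n_draws": len(reports),
        "n_pooled_entries": int(len(pooled)),
        "mean_abs_smd": float(abs_pooled.mean()) if len(pooled) else float("nan"),
        "sd_smd": float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
        "max_abs_smd": float(abs_pooled.max()) if len(pooled) else float("nan"),
        "pooled_imbalanced_count": int((abs_pooled >= threshold).sum()),
        "pooled_imbalanced_proportion": (
            float((abs_pooled >= threshold).mean()) if len(pooled) else float("nan")
        ),
        "mean_imbalanced_count_per_draw": float(counts.mean()),
        "mean_imbalanced_proportion_per_draw": float(np.nanmean(props)),
        "pooled_smds": pooled,
    }
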