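"""Intention-to-treat time-at-risk and unconditional Cox estimation.

Follow-up runs from day 1 post-index to the earliest of the study end,
the end of continuous exposure extended by a persistence window (a
maximum allowed gap between exposures, default 30 days), and the end of
observation. Subjects with less than a minimum time-at-risk (default
1 day) are excluded. Effect estimation is an unconditional Cox
proportional-hazards model with treatment as the only covariate and
Efron handling of tied event days; matched pairs are treated as an
analytic cohort, so estimates are invariant to how selected subjects
are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import TARGET, Cohort


@dataclass
class EffectEstimate:
    """Log hazard ratio and its standard error for one outcome."""

    outcome_id: str
    log_hr: float
    se: float
    n_events: int
    estimable: bool = True


def build_time_at_risk(
    cohort: Cohort,
    persistence_gap_days: int = 30,
    study_end_day: int | None = None,
    min_days: int = 1,
) -> pd.DataFrame:
    """Per-subject follow-up window (``start_day``, ``end_day``, ``days``).

    ``end_day = min(study_end, exposure_end + persistence_gap,
    observation_end)``; subjects with fewer than ``min_days`` at risk are
    dropped.
    """
    s = cohort.subjects
    start = s["index_day"].to_numpy() + 1
    end = np.minimum(
        s["exposure_end_day"].to_numpy() + persistence_gap_days,
        s["observation_end_day"].to_numpy(),
    )
    if study_end_day is not None:
        end = np.minimum(end, study_end_day)
    days = end - start + 1
    keep = days >= min_days
    return pd.DataFrame(
        {
            "subject_id": s.index.to_numpy()[keep],
            "start_day": start[keep],
            "end_day": end[keep],
            "days": days[keep],
        }
    )


def survival_frame(
    tar: pd.DataFrame,
    arms: pd.Series,
    events: pd.DataFrame,
    outcome_id: str,
) -> pd.DataFrame:
    """Duration/event/treatment rows for one outcome.

    An event counts when its day falls inside the subject's follow-up
    window; later events are censored at ``end_day``. ``tar`` may contain
    repeated subjects (stacked draws); events are joined per row.
    """
    ev = events[events["outcome_id"] == outcome_id]
    ev = ev.groupby("subject_id")["event_day"].min()
    event_day = tar["subject_id"].map(ev).to_numpy(dtype=float)
    start = tar["start_day"].to_numpy()
    end = tar["end_day"].to_numpy()
    has_event = (event_day >= start) & (event_day <= end)
    duration = np.where(has_event, event_day - start + 1, end - start + 1)
    return pd.DataFrame(
        {
            "subject_id": tar["subject_id"].to_numpy(),
            "duration": duration.astype(float),
            "event": has_event.astype(int),
            "treatment": (
                arms.reindex(tar["subject_id"]).to_numpy() == TARGET
            ).astype(int),
        }
    )


def fit_cox_frame(frame: pd.DataFrame, outcome_id: str = "") -> EffectEstimate:
    """Unconditional Cox fit of a prepared duration/event/treatment frame."""
    n_events = int(frame["event"].sum())
    events_per_arm = frame.groupby("treatment")["event"].sum()
    if (
        n_events == 0
        or frame["treatment"].nunique() < 2
        or (events_per_arm == 0).any()
    ):
        return EffectEstimate(outcome_id, np.nan, np.nan, n_events, estimable=False)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                frame[["duration", "event", "treatment"]],
                duration_col="duration",
                event_col="event",
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError:
        return EffectEstimate(outcome_id, np.nan, np.nan, n_events, estimable=False)
    log_hr = float(cph.params_["treatment"])
    se = float(cph.standard_errors_["treatment"])
    if not (np.isfinite(log_hr) and np.isfinite(se) and se > 0):
        return EffectEstimate(outcome_id, np.nan, np.nan, n_events, estimable=False)
    return EffectEstimate(outcome_id, log_hr, se, n_events, estimable=True)


def fit_cox(
    tar: pd.DataFrame,
    arms: pd.Series,
    events: pd.DataFrame,
    outcome_id: str,
) -> EffectEstimate:
    """Unconditional Cox log hazard ratio for one outcome."""
    return fit_cox_frame(survival_frame(tar, arms, events, outcome_id), outcome_id)
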