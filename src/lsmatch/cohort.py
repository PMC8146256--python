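"""Cohort container for two-arm new-user study data.

A :class:`Cohort` holds a subjects table (arm label, study dates and
continuous covariates such as age), a sparse binary covariate matrix in
which columns emulate condition/drug/procedure indicator features from
claims data, and a long-format outcome event table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

TARGET = "target"
COMPARATOR = "comparator"
ARMS = (TARGET, COMPARATOR)

#: columns of the subjects table that are not covariates
_STRUCTURAL_COLS = ("arm", "index_day", "exposure_end_day", "observation_end_day")


@dataclass
class Cohort:
    """Two-arm cohort with sparse binary and continuous covariates.

    Parameters
    ----------
    subjects
        Indexed by integer subject id. Must contain ``arm`` (``"target"``
        or ``"comparator"``), ``index_day``, ``exposure_end_day`` and
        ``observation_end_day``; every other column is treated as a
        continuous covariate.
    X
        ``(n_subjects, n_binary)`` sparse 0/1 matrix, rows aligned with
        ``subjects``.
    binary_ids
        Column identifiers of ``X``.
    events
        Long table with columns ``subject_id``, ``outcome_id``,
        ``event_day`` (day offsets on the same axis as the date columns).
        At most one row per (subject, outcome).
    """

    subjects: pd.DataFrame
    X: sp.csr_matrix
    binary_ids: np.ndarray
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject_id", "outcome_id", "event_day"]
        )
    )

    def __post_init__(self) -> None:
        self.binary_ids = np.asarray(self.binary_ids, dtype=object)
        if self.X.shape != (len(self.subjects), len(self.binary_ids)):
            raise ValueError(
                f"covariate matrix shape {self.X.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.binary_ids)} covariates"
            )
        if not self.subjects.index.is_unique:
            raise ValueError("duplicate subject ids")
        bad = set(self.subjects["arm"].unique()) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arm labels: {sorted(bad)}")
        self.X = sp.csr_matrix(self.X)

    # ------------------------------------------------------------------ basic
    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects.index.to_numpy()

    @property
    def arms(self) -> pd.Series:
        return self.subjects["arm"]

    @property
    def continuous_ids(self) -> list[str]:
        return [c for c in self.subjects.columns if c not in _STRUCTURAL_COLS]

    @property
    def covariate_ids(self) -> list[str]:
        return list(self.binary_ids) + self.continuous_ids

    def arm_ids(self, arm: str) -> np.ndarray:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        return self.subjects.index[self.subjects["arm"] == arm].to_numpy()

    @property
    def outcome_ids(self) -> list[str]:
        return sorted(self.events["outcome_id"].unique())

    # ------------------------------------------------------------- covariates
    def _rows(self, subject_ids) -> np.ndarray:
        pos = self.subjects.index.get_indexer(np.asarray(subject_ids))
        if (pos < 0).any():
            missing = np.asarray(subject_ids)[pos < 0][:5]
            raise KeyError(f"unknown subject ids, e.g. {missing.tolist()}")
        return pos

    def values(self, covariate_ids, subject_ids=None) -> np.ndarray:
        """Dense ``(n_subjects, k)`` matrix of the requested covariates."""
        covariate_ids = list(covariate_ids)
        rows = (
            slice(None) if subject_ids is None else self._rows(subject_ids)
        )
        bin_index = pd.Index(self.binary_ids)
        out = np.empty(
            (
                self.n if subject_ids is None else len(subject_ids),
                len(covariate_ids),
            ),
            dtype=float,
        )
        for j, cid in enumerate(covariate_ids):
            loc = bin_index.get_indexer([cid])[0]
            if loc >= 0:
                col = np.asarray(self.X[:, loc].todense()).ravel()
                out[:, j] = col[rows] if subject_ids is not None else col
            elif cid in self.subjects.columns and cid not in _STRUCTURAL_COLS:
                col = self.subjects[cid].to_numpy(dtype=float)
                out[:, j] = col[rows] if subject_ids is not None else col
            else:
                raise KeyError(f"unknown covariate {cid!r}")
        return out

    def frequencies(self) -> pd.Series:
        """Fraction of subjects with a nonzero value, per covariate.

        For the 0/1 claims-style indicators this is the observed code
        prevalence; continuous covariates count nonzero entries (age is
        effectively always "present").
        """
        if self.n == 0:
            raise ValueError("empty cohort")
        freq = {}
        nnz = np.asarray((self.X != 0).sum(axis=0)).ravel()
        for cid, k in zip(self.binary_ids, nnz):
            freq[cid] = k / self.n
        for cid in self.continuous_ids:
            freq[cid] = float((self.subjects[cid] != 0).mean())
        return pd.Series(freq, name="frequency")

    # ----------------------------------------------------------------- subset
    def subset(self, subject_ids) -> "Cohort":
        """Sub-cohort restricted to ``subject_ids`` (original ids kept)."""
        subject_ids = np.asarray(subject_ids)
        rows = self._rows(subject_ids)
        keep = set(subject_ids.tolist())
        ev = self.events[self.events["subject_id"].isin(keep)].reset_index(drop=True)
        return Cohort(
            subjects=self.subjects.iloc[rows].copy(),
            X=self.X[rows],
            binary_ids=self.binary_ids,
            events=ev,
        )

    # --------------------------------------------------------------------- io
    def to_csv(self, directory: str) -> None:
        """Write subjects, covariate triplets and events as CSV files."""
        os.makedirs(directory, exist_ok=True)
        self.subjects.rename_axis("subject_id").to_csv(
            os.path.join(directory, "subjects.csv")
        )
        coo = self.X.tocoo()
        trip = pd.DataFrame(
            {
                "subject_id": self.subjects.index.to_numpy()[coo.row],
                "covariate_id": self.binary_ids[coo.col],
                "value": coo.data.astype(int),
            }
        )
        trip.to_csv(os.path.join(directory, "covariates.csv"), index=False)
        pd.Series(self.binary_ids, name="covariate_id").to_csv(
            os.path.join(directory, "covariate_ids.csv"), index=False
        )
        self.events.to_csv(os.path.join(directory, "events.csv"), index=False)

    @classmethod
    def from_csv(cls, directory: str) -> "Cohort":
        subjects = pd.read_csv(
            os.path.join(directory, "subjects.csv"), index_col="subject_id"
        )
        binary_ids = pd.read_csv(os.path.join(directory, "covariate_ids.csv"))[
            "covariate_id"
        ].to_numpy(dtype=object)
        trip = pd.read_csv(os.path.join(directory, "covariates.csv"))
        row = subjects.index.get_indexer(trip["subject_id"])
        col = pd.Index(binary_ids).get_indexer(trip["covariate_id"])
        X = sp.csr_matrix(
            (trip["value"].to_numpy(), (row, col)),
            shape=(len(subjects), len(binary_ids)),
            dtype=np.int8,
        )
        events = pd.read_csv(os.path.join(directory, "events.csv"))
        if events.empty:
            events = pd.DataFrame(columns=["subject_id", "outcome_id", "event_day"])
        return cls(subjects=subjects, X=X, binary_ids=binary_ids, events=events)
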