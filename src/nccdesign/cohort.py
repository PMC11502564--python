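"""Cohort data model for right-censored (optionally left-truncated) follow-up.

A cohort is a collection of subjects with an observation window ``(entry, exit]``,
a binary event indicator (1 = the subject fails at ``exit``), and an optional
covariate vector.  Covariates may be missing for subjects that were never
sampled into a nested case-control (NCC) subsample; missingness is first-class
and estimators must never silently read a missing covariate.

The at-risk convention is ``Y_i(t) = 1  iff  entry_i < t <= exit_i``: a subject
is at risk at its own exit time, so the case at time t belongs to the risk set
at t.  With ``entry = 0`` (time-on-study scale) this is the usual ``x_i >= t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortRecord",
    "Cohort",
    "RiskSet",
    "read_cohort",
    "write_cohort",
    "read_ncc_sample_file",
    "write_ncc_sample_file",
]


@dataclass(frozen=True)
class CohortRecord:
    """One subject: follow-up window, event status and optional covariates."""

    id: int | str
    entry: float
    exit: float
    event: int
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.exit > self.entry:
            raise ValueError(
                f"subject {self.id!r}: exit ({self.exit}) must exceed entry ({self.entry})"
            )
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id!r}: event must be 0 or 1, got {self.event!r}")


@dataclass(frozen=True)
class RiskSet:
    """Subjects under observation and event-free just before (and at) time t."""

    time: float
    members: frozenset

    def __contains__(self, subject_id) -> bool:
        return subject_id in self.members

    def __len__(self) -> int:
        return len(self.members)


class Cohort:
    """Validated cohort with risk-set utilities and the ordered case schedule.

    Parameters
    ----------
    ids, entry, exit, event
        Per-subject arrays.  ``ids`` must be unique hashables.
    covariates
        Optional ``(n, p)`` float array; ``NaN`` encodes a missing covariate
        vector (all-or-nothing per subject is not required, but estimators
        check whatever entries they touch).
    covariate_names
        Column labels, default ``z1..zp``.
    ties
        ``"error"`` (default) rejects tied case times; ``"jitter"`` applies a
        deterministic rank-preserving perturbation of relative magnitude 1e-9
        (tied cases ordered by id) so a strict case schedule exists.
    """

    def __init__(
        self,
        ids: Sequence,
        entry: Sequence[float],
        exit: Sequence[float],
        event: Sequence[int],
        covariates: np.ndarray | None = None,
        covariate_names: Sequence[str] | None = None,
        ties: str = "error",
    ) -> None:
        self.ids = np.asarray(ids)
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit, dtype=float)
        self.event = np.asarray(event)
        n = self.ids.shape[0]
        for name, arr in (("entry", self.entry), ("exit", self.exit), ("event", self.event)):
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate subject ids")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be binary")
        self.event = self.event.astype(np.int8)
        bad = self.exit <= self.entry
        if np.any(bad):
            raise ValueError(f"exit <= entry for ids {self.ids[bad][:5].tolist()}")

        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                raise ValueError("covariate row count does not match cohort size")
        self.covariates = covariates
        p = 0 if covariates is None else covariates.shape[1]
        if covariate_names is None:
            covariate_names = [f"z{j + 1}" for j in range(p)]
        if len(covariate_names) != p:
            raise ValueError("covariate_names length does not match covariate columns")
        self.covariate_names = list(covariate_names)

        self._index = {sid: i for i, sid in enumerate(self.ids.tolist())}
        self._resolve_ties(ties)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[CohortRecord], ties: str = "error") -> "Cohort":
        records = list(records)
        ids = [r.id for r in records]
        entry = [r.entry for r in records]
        exit_ = [r.exit for r in records]
        event = [r.event for r in records]
        covs = [r.covariates for r in records]
        if all(c is None for c in covs):
            Z = None
        else:
            lens = {len(c) for c in covs if c is not None}
            if len(lens) != 1:
                raise ValueError("covariate vectors have inconsistent lengths")
            p = lens.pop()
            Z = np.full((len(records), p), np.nan)
            for i, c in enumerate(covs):
                if c is not None:
                    Z[i] = c
        return cls(ids, entry, exit_, event, Z, ties=ties)

    # -- tie handling ---------------------------------------------------------

    def _resolve_ties(self, ties: str) -> None:
        case_mask = self.event == 1
        times = self.exit[case_mask]
        if times.size == 0:
            return
        uniq, counts = np.unique(times, return_counts=True)
        if not np.any(counts > 1):
            return
        if ties == "error":
            raise ValueError(
                f"tied case times at {uniq[counts > 1][:5].tolist()}; "
                "pass ties='jitter' to break ties deterministically"
            )
        if ties != "jitter":
            raise ValueError(f"unknown ties policy {ties!r}")
        case_idx = np.flatnonzero(case_mask)
        for t in uniq[counts > 1]:
            tied = case_idx[self.exit[case_idx] == t]
            # rank-preserving: order tied cases by id, nudge by rank * 1e-9
            order = np.argsort(self.ids[tied].astype(str), kind="stable")
            scale = 1e-9 * max(abs(t), 1.0)
            for rank, j in enumerate(tied[order]):
                self.exit[j] = t + rank * scale

    # -- basic properties -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.event.sum())

    @property
    def case_times(self) -> np.ndarray:
        """Strictly increasing case times t_1 < ... < t_D."""
        idx = self._case_order()
        return self.exit[idx]

    @property
    def case_ids(self) -> np.ndarray:
        """Case ids aligned with :attr:`case_times`."""
        return self.ids[self._case_order()]

    def _case_order(self) -> np.ndarray:
        idx = np.flatnonzero(self.event == 1)
        return idx[np.argsort(self.exit[idx], kind="stable")]

    def event_schedule(self) -> list[tuple[float, object]]:
        """Ordered ``(t_k, case id)`` pairs, k = 1..D."""
        idx = self._case_order()
        times = self.exit[idx]
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("tied case times")
        return list(zip(times.tolist(), self.ids[idx].tolist()))

    # -- risk sets ------------------------------------------------------------

    def at_risk_mask(self, t: float) -> np.ndarray:
        """Boolean mask of subjects with entry < t <= exit."""
        if not t > 0:
            raise ValueError("risk sets are defined for t > 0")
        return (self.entry < t) & (t <= self.exit)

    def risk_set(self, t: float) -> RiskSet:
        return RiskSet(time=t, members=frozenset(self.ids[self.at_risk_mask(t)].tolist()))

    def risk_set_size(self, t: float) -> int:
        return int(self.at_risk_mask(t).sum())

    # -- lookups --------------------------------------------------------------

    def index_of(self, subject_ids) -> np.ndarray:
        """Positions of the given ids (raises KeyError on unknown id)."""
        return np.array([self._index[s] for s in np.asarray(subject_ids).tolist()], dtype=np.intp)

    def covariates_of(self, subject_ids, require: bool = True) -> np.ndarray:
        """Covariate rows for the given ids; by default missing rows are an error."""
        if self.covariates is None:
            raise ValueError("cohort carries no covariates")
        Z = self.covariates[self.index_of(subject_ids)]
        if require and np.any(np.isnan(Z)):
            missing = np.asarray(subject_ids)[np.any(np.isnan(Z), axis=1)]
            raise ValueError(f"missing covariates for subjects {missing[:5].tolist()}")
        return Z

    # -- I/O ------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {
            "id": self.ids,
            "entry": self.entry,
            "exit": self.exit,
            "event": self.event.astype(int),
        }
        frame = pd.DataFrame(data)
        if self.covariates is not None:
            for j, name in enumerate(self.covariate_names):
                frame[name] = self.covariates[:, j]
        return frame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort(n={self.n}, cases={self.n_cases}, p={self.n_covariates})"


def read_cohort(
    path,
    covariate_columns: Sequence[str] | None = None,
    ties: str = "error",
) -> Cohort:
    """Read a cohort from a comma-separated file.

    Required columns: ``id, entry, exit, event``.  Any further columns (or the
    subset named in ``covariate_columns``) are covariates; empty cells encode
    missing values.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "entry", "exit", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file lacks required columns: {sorted(missing)}")
    if covariate_columns is None:
        covariate_columns = [c for c in frame.columns if c not in required]
    Z = frame[list(covariate_columns)].to_numpy(dtype=float) if covariate_columns else None
    ids = frame["id"].to_numpy()
    return Cohort(
        ids,
        frame["entry"].to_numpy(dtype=float),
        frame["exit"].to_numpy(dtype=float),
        frame["event"].to_numpy(),
        Z,
        covariate_names=list(covariate_columns),
        ties=ties,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (empty cells for missing covariates).

    Floats are written with 17 significant digits so a read-back reproduces
    every field bit-exactly.
    """
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


# -- NCC sample file format ---------------------------------------------------
#
# First line:   # design=<standard|modified> m=<int>
# Then CSV:     k,case_time,case_id,control_ids   (control ids ';'-separated)


def write_ncc_sample_file(sample, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# design={sample.design} m={sample.m}\n")
        fh.write("k,case_time,case_id,control_ids\n")
        for k in range(len(sample.case_times)):
            controls = ";".join(str(c) for c in sample.matched_controls[k].tolist())
            fh.write(f"{k + 1},{float(sample.case_times[k])!r},{sample.case_ids[k]},{controls}\n")


def read_ncc_sample_file(path):
    """Read an NCC sample description; returns a :class:`~nccdesign.sampling.NCCSample` skeleton.

    Pool sizes and history are reconstructed later against a cohort (see
    :func:`nccdesign.sampling.attach_pools`).
    """
    from .sampling import NCCSample  # local import to avoid a cycle

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("NCC sample file must start with '# design=... m=...'")
        fields = dict(tok.split("=") for tok in header.lstrip("# ").split())
        design = fields["design"]
        m = int(fields["m"])
        body = pd.read_csv(fh, float_precision="round_trip", dtype={"control_ids": str})
    case_times = body["case_time"].to_numpy(dtype=float)
    case_ids = body["case_id"].to_numpy()
    controls = [
        np.array([_coerce(tok) for tok in str(cell).split(";")] if str(cell) not in ("", "nan") else [])
        for cell in body["control_ids"]
    ]
    return NCCSample(
        design=design,
        m=m,
        case_times=case_times,
        case_ids=case_ids,
        matched_controls=controls,
        pool_sizes=None,
        history=None,
        shortfall=np.array([len(c) < m for c in controls]),
    )


def _coerce(token: str):
    try:
        return int(token)
    except ValueError:
        return token
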