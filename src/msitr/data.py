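"""Domain types and long-format I/O for right-censored multistate trial data.

A subject's disease history is a right-continuous step process X(t) on the
state space {1, ..., S}, observed on [0, tilde_t] where tilde_t = min(T, C)
is the earlier of the (tau-truncated) absorbing-arrival time T = min(T*, tau)
and the censoring time C, with event indicator delta = I(T <= C).  Baseline
covariates Z and the randomized binary treatment A in {-1, +1} complete a
trial record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StatePath",
    "TrialRecord",
    "TrialDataset",
    "PreferenceWeight",
    "ValidationError",
    "SchemaError",
    "PositivityError",
    "read_multistate_table",
    "write_multistate_table",
    "estimate_propensity",
]


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class SchemaError(ValueError):
    """Input table does not match the expected columns."""


class PositivityError(ValueError):
    """Both treatment arms must be represented (positivity assumption)."""


@dataclass(frozen=True)
class StatePath:
    """Observed trajectory of one subject's censored multistate process.

    ``entries`` is the ordered sequence of (time, state) state-entry pairs,
    starting at (0, initial state).  The subject occupies the state of its
    most recent entry (cadlag convention).  ``tilde_t`` is the end of
    observation min(T, C) and ``delta`` = 1 if the endpoint is the event
    (absorbing arrival or administrative truncation at tau), 0 if censoring.
    """

    entries: tuple[tuple[float, int], ...]
    tilde_t: float
    delta: int
    absorbing_states: frozenset[int] = frozenset({3})

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("path has no state entries")
        times = [t for t, _ in self.entries]
        if times[0] != 0.0:
            raise ValidationError("first entry must occur at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("entry times must be strictly increasing")
        if self.tilde_t < 0 or any(t < 0 for t in times):
            raise ValidationError("times must be non-negative")
        if any(t > self.tilde_t for t in times):
            raise ValidationError("entry times must not exceed tilde_t")
        if self.delta not in (0, 1):
            raise ValidationError("delta must be 0 or 1")
        # no transition out of an absorbing state
        for (_, s), nxt in zip(self.entries, self.entries[1:]):
            if s in self.absorbing_states:
                raise ValidationError(
                    f"transition out of absorbing state {s} at time {nxt[0]}"
                )

    def state_at(self, t: float) -> int:
        """State occupied at time t (right-continuous lookup)."""
        state = self.entries[0][1]
        for time, s in self.entries:
            if time <= t:
                state = s
            else:
                break
        return state

    @property
    def states(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.entries)


@dataclass(frozen=True)
class TrialRecord:
    """One subject: covariates z, treatment a in {-1,+1}, observed path."""

    z: np.ndarray
    a: int
    path: StatePath
    subject_id: str | int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.atleast_1d(np.asarray(self.z, dtype=float)))
        if self.a not in (-1, 1):
            raise ValidationError(f"treatment must be -1 or +1, got {self.a}")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("covariates must be finite")


@dataclass
class TrialDataset:
    """Collection of trial records with analysis horizon tau and state count S."""

    records: list[TrialRecord]
    tau: float
    n_states: int

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        for rec in self.records:
            for _, s in rec.path.entries:
                if not 1 <= s <= self.n_states:
                    raise ValidationError(
                        f"state {s} outside 1..{self.n_states}"
                        + (f" (subject {rec.subject_id})" if rec.subject_id is not None else "")
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def z_matrix(self) -> np.ndarray:
        return np.vstack([rec.z for rec in self.records])

    @property
    def a_vector(self) -> np.ndarray:
        return np.array([rec.a for rec in self.records], dtype=float)

    @property
    def tilde_t(self) -> np.ndarray:
        return np.array([rec.path.tilde_t for rec in self.records], dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return np.array([rec.path.delta for rec in self.records], dtype=int)


@dataclass(frozen=True)
class PreferenceWeight:
    """Preference weights w in [0,1]^S valuing time spent in each state."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", tuple(arr))
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("preference weights must lie in [0, 1]")
        total = float(arr.sum())
        if not 0 < total < len(arr):
            raise ValidationError(
                "sum of preference weights must be strictly between 0 and S"
            )

    def __len__(self) -> int:
        return len(self.w)

    def __getitem__(self, j: int) -> float:
        return self.w[j]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


DEFAULT_SCHEMA = {
    "id": "id",
    "a": "a",
    "entry_time": "entry_time",
    "state": "state",
    "tilde_t": "tilde_t",
    "delta": "delta",
}


def _covariate_columns(df: pd.DataFrame, schema: dict[str, str]) -> list[str]:
    fixed = set(schema.values())
    zcols = [c for c in df.columns if c not in fixed]
    # keep stable z1..zp ordering as they appear in the file
    return zcols


def read_multistate_table(
    source,
    schema: dict[str, str] | None = None,
    tau: float | None = None,
    n_states: int | None = None,
    absorbing_states: Iterable[int] = (3,),
) -> TrialDataset:
    """Read a long-format multistate table (one row per state entry).

    Expected columns (names overridable via ``schema``): subject id,
    covariates z1..zp (any column not named in the schema), treatment a,
    entry_time, state, tilde_t, delta.  Rows are grouped by subject and
    sorted by entry time.  ``tau`` defaults to the maximum tilde_t.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, float_precision="round_trip")
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    zcols = _covariate_columns(df, schema)
    records: list[TrialRecord] = []
    max_state = 0
    for sid, grp in df.groupby(schema["id"], sort=True):
        grp = grp.sort_values(schema["entry_time"], kind="stable")
        times = grp[schema["entry_time"]].to_numpy(dtype=float)
        states = grp[schema["state"]].to_numpy(dtype=int)
        if np.unique(times).size != times.size:
            raise ValidationError(f"subject {sid}: duplicate entry times")
        tilde_t = float(grp[schema["tilde_t"]].iloc[0])
        delta = int(grp[schema["delta"]].iloc[0])
        a = int(grp[schema["a"]].iloc[0])
        z = grp[zcols].iloc[0].to_numpy(dtype=float)
        try:
            path = StatePath(
                entries=tuple(zip(times.tolist(), states.tolist())),
                tilde_t=tilde_t,
                delta=delta,
                absorbing_states=frozenset(absorbing_states),
            )
        except ValidationError as exc:
            raise ValidationError(f"subject {sid}: {exc}") from exc
        max_state = max(max_state, int(states.max()))
        records.append(TrialRecord(z=z, a=a, path=path, subject_id=sid))
    if n_states is None:
        n_states = max_state
    if tau is None:
        tau = float(max(rec.path.tilde_t for rec in records))
    return TrialDataset(records=records, tau=tau, n_states=n_states)


def write_multistate_table(data: TrialDataset, target) -> None:
    """Write a dataset in the long CSV format accepted by the reader."""
    rows = []
    for idx, rec in enumerate(data.records):
        sid = rec.subject_id if rec.subject_id is not None else idx
        for t, s in rec.path.entries:
            row = {"id": sid}
            for j, zj in enumerate(rec.z, start=1):
                row[f"z{j}"] = zj
            row.update(
                a=rec.a,
                entry_time=t,
                state=s,
                tilde_t=rec.path.tilde_t,
                delta=rec.path.delta,
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(target, index=False)


def estimate_propensity(data: TrialDataset) -> float:
    """Empirical randomization probability: fraction of subjects with a = +1.

    Even when the design probability is known, the empirical estimate is
    used in the weighting, which typically improves efficiency of inverse
    probability weighted estimators.
    """
    a = data.a_vector
    if len(a) == 0 or np.all(a == 1) or np.all(a == -1):
        raise PositivityError("both treatment arms must be present")
    return float(np.mean(a == 1))
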