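"""Nelson-Aalen estimation of the censoring hazard and IPCW weights.

Right censoring removes the tail of a subject's multistate trajectory.  To
correct the resulting bias, observed contributions are divided by the
estimated probability of remaining uncensored, S_C(t-) = exp{-Lambda(t-)},
i.e. multiplied by exp{+Lambda_hat(t-)}.  The cumulative hazard of the
censoring variable is estimated by the Nelson-Aalen estimator with the roles
of event and censoring reversed: counting process N_i(t) = (1-delta_i)
I(tilde_t_i <= t), risk set Y_i(t) = I(tilde_t_i >= t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialDataset

__all__ = ["CensoringHazard", "nelson_aalen_censoring", "ipcw_weight"]


@dataclass(frozen=True)
class CensoringHazard:
    """Right-continuous nondecreasing step function with Lambda(0) = 0.

    ``cum_values[k]`` is the value of the estimator at and after
    ``jump_times[k]``.
    """

    jump_times: np.ndarray
    cum_values: np.ndarray

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        cv = np.asarray(self.cum_values, dtype=float)
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "cum_values", cv)
        if jt.shape != cv.shape:
            raise ValueError("jump_times and cum_values must have equal length")
        if jt.size:
            if np.any(np.diff(jt) <= 0):
                raise ValueError("jump times must be strictly increasing")
            if np.any(jt <= 0):
                raise ValueError("jump times must be positive")
            if np.any(np.diff(cv) < 0) or cv[0] < 0:
                raise ValueError("cumulative hazard must be nondecreasing and >= 0")

    def __call__(self, t) -> np.ndarray | float:
        """Lambda_hat(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        vals = np.concatenate(([0.0], self.cum_values))[idx]
        return float(vals) if vals.ndim == 0 else vals

    def left_limit(self, t) -> np.ndarray | float:
        """Lambda_hat(t-): excludes a jump exactly at t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left")
        vals = np.concatenate(([0.0], self.cum_values))[idx]
        return float(vals) if vals.ndim == 0 else vals

    @property
    def increments(self) -> np.ndarray:
        return np.diff(np.concatenate(([0.0], self.cum_values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"jump_time": self.jump_times, "cum_hazard": self.cum_values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CensoringHazard":
        return cls(
            jump_times=df["jump_time"].to_numpy(dtype=float),
            cum_values=df["cum_hazard"].to_numpy(dtype=float),
        )


def nelson_aalen_censoring(data: TrialDataset) -> CensoringHazard:
    """Nelson-Aalen estimator of the censoring cumulative hazard.

    Lambda_hat(t) = sum over censoring times u <= t of
    (#censored at u) / #{i : tilde_t_i >= u}.  Tied censoring times are
    pooled; at a tie between an event and a censoring the event subject
    remains in the risk set (Y uses >=).
    """
    tt = data.tilde_t
    delta = data.delta
    cens_times, n_cens = np.unique(tt[delta == 0], return_counts=True)
    if cens_times.size == 0:
        return CensoringHazard(np.empty(0), np.empty(0))
    tt_sorted = np.sort(tt)
    at_risk = tt.size - np.searchsorted(tt_sorted, cens_times, side="left")
    return CensoringHazard(cens_times, np.cumsum(n_cens / at_risk))


def ipcw_weight(h: CensoringHazard, s: float) -> float:
    """Inverse-probability-of-censoring weight 1/S_C(s-) = exp{Lambda_hat(s-)}.

    The left limit means a subject's weight at its own censoring time does
    not include its own censoring jump.
    """
    if s < 0:
        raise ValueError("s must be non-negative")
    return float(np.exp(h.left_limit(s)))
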