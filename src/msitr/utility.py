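"""Benefit processes and preference-weighted utility integrals.

The benefit process of a subject is Y_w(t) = w_{X(t)}, the preference weight
of the state occupied at time t.  The utility is its Lebesgue integral over
[0, tau]: the weighted sum of restricted state-occupation times.  Under
censoring, the observable IPCW-weighted version integrates
Y_w(t) * I(t contributes) * exp{Lambda_hat((tilde_t ^ t)-)}, which is exact
breakpoint summation because the integrand is piecewise constant on the
common refinement of path breakpoints, hazard jump times, tilde_t and tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import CensoringHazard
from .data import PreferenceWeight, StatePath, TrialRecord, ValidationError

__all__ = [
    "BenefitTrajectory",
    "benefit_trajectory",
    "raw_utility",
    "ipcw_utility",
    "ipcw_utility_segments",
]


@dataclass(frozen=True)
class BenefitTrajectory:
    """Piecewise-constant benefit level Y_w(t) on [0, end].

    ``levels[k]`` holds on [breakpoints[k], breakpoints[k+1]); breakpoints
    include both endpoints, so len(breakpoints) = len(levels) + 1.
    """

    breakpoints: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if bp.size != lv.size + 1:
            raise ValueError("need len(breakpoints) == len(levels) + 1")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lv < 0):
            raise ValueError("benefit levels must be non-negative")

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        idx = int(np.clip(idx, 0, self.levels.size - 1))
        return float(self.levels[idx])

    def integral(self) -> float:
        return float(np.sum(np.diff(self.breakpoints) * self.levels))


def _check_states(path: StatePath, w: PreferenceWeight) -> None:
    for _, s in path.entries:
        if not 1 <= s <= len(w):
            raise ValidationError(f"state {s} outside 1..{len(w)}")


def benefit_trajectory(
    path: StatePath, w: PreferenceWeight, tau: float
) -> BenefitTrajectory:
    """Benefit process w_{X(t)} of one subject.

    For an event subject (delta=1) the trajectory is defined through tau (a
    subject absorbed before tau stays in the absorbing state); for a censored
    subject it is defined only up to tilde_t.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    _check_states(path, w)
    end = tau if path.delta == 1 else min(path.tilde_t, tau)
    times = [t for t, _ in path.entries if t < end]
    states = [s for t, s in path.entries if t < end]
    bp = np.array(times + [end], dtype=float)
    lv = np.array([w[s - 1] for s in states], dtype=float)
    if end == 0.0:  # degenerate: censored at time 0
        bp = np.array([0.0, 0.0 + np.finfo(float).tiny])
        lv = np.array([w[path.entries[0][1] - 1]])
    return BenefitTrajectory(bp, lv)


def raw_utility(path: StatePath, w: PreferenceWeight, tau: float) -> float:
    """Exact utility integral of a fully observed path over [0, tau]."""
    if path.delta != 1:
        raise ValidationError("raw_utility requires a fully observed path; "
                              "use ipcw_utility for censored records")
    return benefit_trajectory(path, w, tau).integral()


def ipcw_utility_segments(
    path: StatePath, w: PreferenceWeight, h: CensoringHazard, tau: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant segments of the IPCW-weighted benefit integrand.

    Returns (starts, ends, values) with values = Y_w(t) * exp{Lambda((tilde_t
    ^ t)-)} on each segment of the contribution region.  The contribution
    region comes from rewriting I(C >= T ^ t) in observables:
      delta = 1  => C >= T, so I(C >= T ^ t) = 1 for every t in [0, tau];
      delta = 0  => T ^ t > C  iff  t > tilde_t = C, so the indicator is
                    I(t <= tilde_t).
    """
    _check_states(path, w)
    end = tau if path.delta == 1 else min(path.tilde_t, tau)
    if end <= 0:
        z = np.empty(0)
        return z, z, z
    cut = min(path.tilde_t, tau)
    entry_times = np.fromiter((t for t, _ in path.entries), dtype=float)
    entry_states = np.fromiter((s for _, s in path.entries), dtype=np.intp)
    jumps = h.jump_times
    inner = jumps[(jumps > 0.0) & (jumps < min(cut, end))]
    grid = np.unique(np.concatenate(
        (entry_times[(entry_times > 0.0) & (entry_times < end)],
         inner, np.array([0.0, end, min(cut, end)]))
    ))
    starts, ends = grid[:-1], grid[1:]
    mids = 0.5 * (starts + ends)
    idx = np.searchsorted(entry_times, mids, side="right") - 1
    ylev = w.array[entry_states[idx] - 1]
    # weight exp{Lambda((tilde_t ^ t)-)}: on segments beyond tilde_t the
    # argument freezes at tilde_t and the left limit excludes any censoring
    # jump exactly at tilde_t; inside (0, tilde_t) no jump lies within a
    # segment so the right-continuous value at the midpoint is the left limit
    wts = np.where(
        starts >= cut,
        np.exp(h.left_limit(cut)),
        np.exp(h(np.minimum(mids, cut))),
    )
    return starts, ends, ylev * wts


def ipcw_utility(
    rec: TrialRecord, w: PreferenceWeight, h: CensoringHazard, tau: float
) -> float:
    """IPCW-weighted utility of one (possibly censored) record over [0, tau]."""
    starts, ends, vals = ipcw_utility_segments(rec.path, w, h, tau)
    return float(np.sum((ends - starts) * vals))
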