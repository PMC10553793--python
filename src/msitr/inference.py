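"""Value estimation and influence-function inference for treatment rules.

The value of a rule d is estimated by the IPCW inverse-probability-weighted
average

    V_hat(d) = (1/n) sum_i U_i I(A_i = d(Z_i)) / (A_i pi + (1-A_i)/2),

where U_i is the subject's IPCW-weighted utility.  sqrt(n)(V_hat - V) is
asymptotically normal; its influence function has three parts: the centered
weighted summand, a censoring-martingale correction for estimating the
Nelson-Aalen censoring hazard, and a correction for estimating the
randomization probability.  Simultaneous confidence intervals over several
preference weights (and contrasts against the one-size-fits-all rules
d = +1 and d = -1) use the max-norm of simulated Gaussian vectors with the
estimated covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .censoring import CensoringHazard, nelson_aalen_censoring
from .data import PreferenceWeight, TrialDataset, estimate_propensity
from .owl import DecisionFunction
from .utility import ipcw_utility_segments

__all__ = [
    "ValueEstimate",
    "InfluenceVector",
    "SimultaneousBand",
    "as_rule",
    "estimate_value",
    "jackknife_value",
    "influence_functions",
    "covariance_matrix",
    "simultaneous_band",
    "value_report",
]

Rule = Callable[[np.ndarray], np.ndarray]


def as_rule(d) -> Rule:
    """Coerce a rule specification to a callable z-matrix -> {-1,+1} array.

    Accepts a DecisionFunction, a constant +1/-1 (fixed rule), or any
    callable.
    """
    if isinstance(d, DecisionFunction):
        return lambda z: np.atleast_1d(d.decide(z))
    if isinstance(d, (int, float)) and d in (-1, 1):
        return lambda z: np.full(np.atleast_2d(z).shape[0], int(d))
    if callable(d):
        return lambda z: np.atleast_1d(np.asarray(d(z)))
    raise TypeError(f"cannot interpret {d!r} as a treatment rule")


@dataclass(frozen=True)
class ValueEstimate:
    v_hat: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # "plugin" | "jackknife"
    w: PreferenceWeight
    rule_id: str = ""


@dataclass(frozen=True)
class InfluenceVector:
    """Empirical influence values psi_i of sqrt(n)(V_hat - V)."""

    psi: np.ndarray

    @property
    def sigma2(self) -> float:
        """Variance estimate sigma^2 = n^{-1} sum psi_i^2 (divisor n)."""
        return float(np.mean(self.psi**2))

    @property
    def n(self) -> int:
        return self.psi.size

    @property
    def se(self) -> float:
        return float(np.sqrt(self.sigma2 / self.n))


def _weighted_pieces(data: TrialDataset, w: PreferenceWeight, h: CensoringHazard):
    """Per-subject IPCW integrand segments and total utilities."""
    segs = [ipcw_utility_segments(rec.path, w, h, data.tau) for rec in data.records]
    U = np.array([np.sum((e - s) * v) for s, e, v in segs])
    return segs, U


def estimate_value(
    data: TrialDataset,
    d,
    w: PreferenceWeight,
    h: CensoringHazard,
    pi_hat: float,
) -> float:
    """Plug-in IPCW value estimate of a rule d."""
    if not 0 < pi_hat < 1:
        raise ValueError("pi_hat must lie in (0, 1)")
    rule = as_rule(d)
    _, U = _weighted_pieces(data, w, h)
    a = data.a_vector
    denom = np.where(a == 1, pi_hat, 1.0 - pi_hat)
    align = (a == rule(data.z_matrix)).astype(float)
    return float(np.mean(U * align / denom))


def jackknife_value(
    data: TrialDataset,
    w: PreferenceWeight,
    lam: float,
    kind: str = "linear",
    sigma: float | None = None,
) -> float:
    """Leave-one-out cross-validated value estimate of the fitted rule.

    For each subject i the rule is refitted (same lambda) on the remaining
    n-1 subjects, with the censoring hazard and the propensity recomputed on
    that subsample for the refit; subject i's weighted summand then uses the
    full-sample hazard and propensity, so that when every held-out rule
    equals the full-data rule the estimate reduces exactly to the plug-in
    value.
    """
    from .owl import fit_gaussian_kernel, fit_linear  # avoid import cycle

    n = len(data)
    if n < 3:
        raise ValueError("jackknife requires n >= 3")
    pi_full = estimate_propensity(data)
    h_full = nelson_aalen_censoring(data)
    total = 0.0
    for i in range(n):
        rest = TrialDataset(
            records=[r for j, r in enumerate(data.records) if j != i],
            tau=data.tau,
            n_states=data.n_states,
        )
        pi_i = estimate_propensity(rest)
        h_i = nelson_aalen_censoring(rest)
        if kind == "linear":
            fit = fit_linear(rest, w, lam, h_i, pi_i)
        else:
            fit = fit_gaussian_kernel(rest, w, lam, sigma, h_i, pi_i)
        rec = data.records[i]
        s, e, v = ipcw_utility_segments(rec.path, w, h_full, data.tau)
        U_i = float(np.sum((e - s) * v))
        denom = pi_full if rec.a == 1 else 1.0 - pi_full
        d_i = fit.f.decide(rec.z)
        total += U_i * float(rec.a == d_i) / denom
    return total / n


def influence_functions(
    data: TrialDataset,
    d,
    w: PreferenceWeight,
    h: CensoringHazard,
    pi_hat: float,
    pi_fixed: bool = False,
) -> InfluenceVector:
    """Empirical influence values of the plug-in value estimator.

    psi_i = (g_i - V_hat)
            + int rho(u)/ybar(u) dM_i^C(u)          (Nelson-Aalen correction)
            - c_pi (I(A_i = 1) - pi_hat),            (propensity correction)

    where g_i is subject i's weighted summand, rho(u) is the sample average
    of the part of the weighted integrand over {t : tilde_t_j ^ t >= u},
    ybar(u) the average at-risk indicator, and M_i^C the estimated censoring
    martingale.  With ``pi_fixed=True`` the propensity correction is dropped
    (randomization probability treated as known).
    """
    if not 0 < pi_hat < 1:
        raise ValueError("pi_hat must lie in (0, 1)")
    rule = as_rule(d)
    n = len(data)
    segs, U = _weighted_pieces(data, w, h)
    a = data.a_vector
    tt = data.tilde_t
    delta = data.delta
    denom = np.where(a == 1, pi_hat, 1.0 - pi_hat)
    align = (a == rule(data.z_matrix)).astype(float)
    g = U * align / denom
    v_hat = float(np.mean(g))
    psi = g - v_hat

    jumps = h.jump_times
    if jumps.size:
        dlam = h.increments
        ybar = np.array([np.mean(tt >= u) for u in jumps])
        # rho(u_k) = mean_j I(tt_j >= u_k) c_j * tail_j(u_k), with tail the
        # weighted integrand mass of subject j on [u_k, tau]
        c = align / denom
        rho = np.zeros(jumps.size)
        for j in range(n):
            if c[j] == 0.0:
                continue
            s, e, v = segs[j]
            if s.size == 0:
                continue
            tail = (v[:, None] * np.clip(e[:, None] - np.maximum(s[:, None], jumps[None, :]), 0.0, None)).sum(0)
            rho += c[j] * np.where(tt[j] >= jumps, tail, 0.0)
        rho /= n
        q = rho * dlam / ybar
        q_cum = np.cumsum(q)
        # compensator part: -sum_{u_k <= tt_i} q_k
        idx = np.searchsorted(jumps, tt, side="right")
        comp = np.concatenate(([0.0], q_cum))[idx]
        # counting part: censored subjects jump at their own tt_i
        count = np.zeros(n)
        cens = delta == 0
        if np.any(cens):
            pos = np.searchsorted(jumps, tt[cens])
            count[cens] = rho[pos] / ybar[pos]
        psi = psi + count - comp

    if not pi_fixed:
        c_pi = float(np.mean(g * a / denom))
        psi = psi - c_pi * ((a == 1).astype(float) - pi_hat)
    return InfluenceVector(psi=psi)


def covariance_matrix(
    data: TrialDataset,
    entries: Sequence[tuple[object, PreferenceWeight]],
    h: CensoringHazard,
    pi_hat: float,
    pi_fixed: bool = False,
) -> np.ndarray:
    """Covariance Omega_hat across (rule, weight) entries.

    Diagonal entries are the influence-function variances; off-diagonals are
    empirical cross-products n^{-1} sum_i psi_{i,l} psi_{i,l'}.  The result
    is symmetrized and eigenvalue-clipped to PSD if the minimum eigenvalue
    falls below -1e-10.
    """
    if not entries:
        raise ValueError("need at least one (rule, weight) entry")
    psis = np.column_stack(
        [influence_functions(data, d, w, h, pi_hat, pi_fixed).psi for d, w in entries]
    )
    omega = psis.T @ psis / len(data)
    omega = 0.5 * (omega + omega.T)
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin < -1e-10:
        warnings.warn(f"projecting Omega to PSD (min eigenvalue {eigmin:.2e})")
        vals, vecs = np.linalg.eigh(omega)
        omega = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        omega = 0.5 * (omega + omega.T)
    return omega


@dataclass(frozen=True)
class SimultaneousBand:
    estimates: np.ndarray
    omega_hat: np.ndarray
    q_matrix: np.ndarray
    c_alpha: float
    intervals: np.ndarray  # (M, 2)
    B: int
    seed: int


def simultaneous_band(
    estimates: np.ndarray,
    omega_hat: np.ndarray,
    n: int,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    contrasts: np.ndarray | None = None,
) -> SimultaneousBand:
    """Simultaneous 1-alpha confidence intervals via Gaussian multipliers.

    Draws B vectors G_b ~ N(0, Omega_hat), scales by Q = diag(1/sigma_l) and
    takes the 1-alpha empirical percentile of ||Q G_b||_inf as the critical
    value c_alpha; intervals are estimate_l +/- c_alpha sigma_l / sqrt(n).
    Optional ``contrasts`` L maps the base estimates to reported rows
    (e.g. differences against fixed rules): the band is built for L*estimates
    with covariance L Omega L'.
    """
    estimates = np.atleast_1d(np.asarray(estimates, dtype=float))
    omega = np.atleast_2d(np.asarray(omega_hat, dtype=float))
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin < -1e-8:
        raise ValueError(f"omega_hat is not PSD (min eigenvalue {eigmin:.2e})")
    if contrasts is not None:
        L = np.atleast_2d(np.asarray(contrasts, dtype=float))
        estimates = L @ estimates
        omega = L @ omega @ L.T
        omega = 0.5 * (omega + omega.T)
    M = estimates.size
    sig = np.sqrt(np.clip(np.diag(omega), 0.0, None))
    if np.any(sig == 0):
        raise ValueError("zero variance component; cannot scale by Q")
    rng = np.random.default_rng(seed)
    jitter = 1e-10 * np.eye(M)
    try:
        chol = np.linalg.cholesky(omega + jitter)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(omega)
        chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    G = rng.standard_normal((B, M)) @ chol.T
    stats = np.max(np.abs(G) / sig, axis=1)
    c_alpha = float(np.quantile(stats, 1.0 - alpha))
    half = c_alpha * sig / np.sqrt(n)
    intervals = np.column_stack([estimates - half, estimates + half])
    return SimultaneousBand(
        estimates=estimates,
        omega_hat=omega,
        q_matrix=np.diag(1.0 / sig),
        c_alpha=c_alpha,
        intervals=intervals,
        B=B,
        seed=seed,
    )


def value_report(
    data: TrialDataset,
    fitted: dict[PreferenceWeight, DecisionFunction],
    h: CensoringHazard | None = None,
    pi_hat: float | None = None,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-weight value of the fitted rule and contrasts vs the fixed rules.

    For each preference weight w reports V_hat(d_w), V_hat(d_w) - V_hat(+1)
    and V_hat(d_w) - V_hat(-1) with pointwise and simultaneous 1-alpha
    confidence intervals (the simultaneous band accounts for all reported
    parameters jointly).
    """
    if h is None:
        h = nelson_aalen_censoring(data)
    if pi_hat is None:
        pi_hat = estimate_propensity(data)
    weights = list(fitted.keys())
    entries: list[tuple[object, PreferenceWeight]] = []
    for w in weights:
        entries += [(fitted[w], w), (1, w), (-1, w)]
    est = np.array([estimate_value(data, d, w, h, pi_hat) for d, w in entries])
    omega = covariance_matrix(data, entries, h, pi_hat)
    # rows per weight: value of the fitted rule, and its differences vs +1/-1
    L = []
    labels = []
    for m, w in enumerate(weights):
        base = 3 * m
        row_v = np.zeros(len(entries)); row_v[base] = 1.0
        row_p = row_v.copy(); row_p[base + 1] = -1.0
        row_m = row_v.copy(); row_m[base + 2] = -1.0
        L += [row_v, row_p, row_m]
        w_label = "(" + ", ".join(f"{float(x):g}" for x in w.w) + ")"
        labels += [
            (w_label, "V(d_hat)"),
            (w_label, "V(d_hat) - V(+1)"),
            (w_label, "V(d_hat) - V(-1)"),
        ]
    L = np.array(L)
    band = simultaneous_band(est, omega, n=len(data), alpha=alpha, B=B,
                             seed=seed, contrasts=L)
    z = norm.ppf(1 - alpha / 2)
    sig = np.sqrt(np.diag(band.omega_hat))
    se = sig / np.sqrt(len(data))
    df = pd.DataFrame(
        {
            "w": [l[0] for l in labels],
            "parameter": [l[1] for l in labels],
            "estimate": band.estimates,
            "se": se,
            "ci_low": band.estimates - z * se,
            "ci_high": band.estimates + z * se,
            "sim_ci_low": band.intervals[:, 0],
            "sim_ci_high": band.intervals[:, 1],
        }
    )
    df.attrs["c_alpha"] = band.c_alpha
    df.attrs["B"] = B
    df.attrs["seed"] = seed
    return df
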