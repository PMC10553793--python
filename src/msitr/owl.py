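"""Outcome-weighted learning: penalized weighted hinge-loss minimization.

The optimal treatment rule maximizes the expected preference-weighted
utility.  Replacing the 0-1 loss in the equivalent risk-minimization problem
with the hinge loss phi(x) = max(0, 1-x) gives the convex empirical
surrogate risk

    R_hat(f) = (1/n) sum_i U_i * phi(A_i f(Z_i)) / (A_i pi + (1-A_i)/2),

with U_i the subject's IPCW-weighted utility; the fit minimizes
R_hat(f) + lambda * ||f||^2 over a linear class or a Gaussian-kernel RKHS.
This is a weighted support-vector classification problem: with case weights
v_i = U_i / (A_i pi + (1-A_i)/2) and cost C = 1/(2 n lambda), the SVC
objective (1/2)||beta||^2 + C sum v_i xi_i is the surrogate objective scaled
by 1/(2 lambda).  The intercept is not penalized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .censoring import CensoringHazard
from .data import PreferenceWeight, TrialDataset
from .utility import ipcw_utility

__all__ = [
    "DecisionFunction",
    "OwlFit",
    "case_weights",
    "surrogate_risk",
    "fit_linear",
    "fit_gaussian_kernel",
    "select_lambda",
    "assign",
    "DEFAULT_LAMBDA_MULTIPLIERS",
]

# candidate multipliers for lambda = m * n^{-1/2} used in cross-validation
DEFAULT_LAMBDA_MULTIPLIERS = (
    0.001, 0.005, 0.01, 0.1, 0.25, 0.5, 1, 2.5, 5, 10, 20, 50, 100,
)


@dataclass(frozen=True)
class DecisionFunction:
    """Decision function f; the rule is d(z) = sgn(f(z)) with sgn(0) = +1."""

    kind: str  # "linear" | "gaussian_kernel"
    intercept: float
    slope: np.ndarray | None = None
    alphas: np.ndarray | None = None
    support_points: np.ndarray | None = None
    sigma: float | None = None

    def __call__(self, z) -> np.ndarray | float:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if self.kind == "linear":
            out = self.intercept + z @ self.slope
        elif self.kind == "gaussian_kernel":
            d2 = ((z[:, None, :] - self.support_points[None, :, :]) ** 2).sum(-1)
            out = self.intercept + np.exp(-self.sigma * d2) @ self.alphas
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        return float(out[0]) if out.size == 1 and np.asarray(z).ndim <= 2 and z.shape[0] == 1 else out

    def decide(self, z) -> np.ndarray | int:
        """Treatment assignment sgn(f(z)): +1 iff f(z) >= 0."""
        f = self(z)
        if np.isscalar(f):
            return 1 if f >= 0 else -1
        return np.where(np.asarray(f) >= 0, 1, -1)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "intercept": self.intercept}
        if self.kind == "linear":
            d["slope"] = np.asarray(self.slope).tolist()
        else:
            d["alphas"] = np.asarray(self.alphas).tolist()
            d["support_points"] = np.asarray(self.support_points).tolist()
            d["sigma"] = self.sigma
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionFunction":
        kw = dict(kind=d["kind"], intercept=float(d["intercept"]))
        if d["kind"] == "linear":
            kw["slope"] = np.asarray(d["slope"], dtype=float)
        else:
            kw["alphas"] = np.asarray(d["alphas"], dtype=float)
            kw["support_points"] = np.asarray(d["support_points"], dtype=float)
            kw["sigma"] = float(d["sigma"])
        return cls(**kw)


def assign(f: DecisionFunction, z) -> np.ndarray | int:
    """Rule d(z) = sgn(f(z)) = I(f >= 0) - I(f < 0)."""
    return f.decide(z)


@dataclass
class OwlFit:
    """A fitted decision function with tuning metadata and diagnostics."""

    f: DecisionFunction
    lam: float
    w: PreferenceWeight
    objective: float = np.nan
    surrogate: float = np.nan
    n_support: int = 0
    solver_status: str = "ok"

    def save(self, target) -> None:
        doc = {
            "decision_function": self.f.to_dict(),
            "lambda": self.lam,
            "w": list(self.w.w),
            "objective": self.objective,
            "surrogate_risk": self.surrogate,
            "n_support": self.n_support,
            "solver_status": self.solver_status,
        }
        if hasattr(target, "write"):
            json.dump(doc, target, indent=1)
        else:
            with open(target, "w") as fh:
                json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, source) -> "OwlFit":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            f=DecisionFunction.from_dict(doc["decision_function"]),
            lam=float(doc["lambda"]),
            w=PreferenceWeight(tuple(doc["w"])),
            objective=doc.get("objective", np.nan),
            surrogate=doc.get("surrogate_risk", np.nan),
            n_support=doc.get("n_support", 0),
            solver_status=doc.get("solver_status", "ok"),
        )


def case_weights(
    data: TrialDataset,
    w: PreferenceWeight,
    h: CensoringHazard,
    pi_hat: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (U_i, v_i) with v_i = U_i / (A_i pi + (1-A_i)/2) >= 0."""
    U = np.array([ipcw_utility(rec, w, h, data.tau) for rec in data.records])
    a = data.a_vector
    denom = np.where(a == 1, pi_hat, 1.0 - pi_hat)
    return U, U / denom


def surrogate_risk(
    f: DecisionFunction,
    data: TrialDataset,
    w: PreferenceWeight,
    h: CensoringHazard,
    pi_hat: float,
) -> float:
    """Empirical IPCW surrogate (hinge) risk of a decision function."""
    if not 0 < pi_hat < 1:
        raise ValueError("pi_hat must lie in (0, 1)")
    _, v = case_weights(data, w, h, pi_hat)
    margins = data.a_vector * np.asarray(f(data.z_matrix), dtype=float)
    return float(np.mean(v * np.maximum(0.0, 1.0 - margins)))


def _penalty(f: DecisionFunction, lam: float) -> float:
    if f.kind == "linear":
        return lam * float(np.sum(np.asarray(f.slope) ** 2))
    d2 = ((f.support_points[:, None, :] - f.support_points[None, :, :]) ** 2).sum(-1)
    K = np.exp(-f.sigma * d2)
    return lam * float(f.alphas @ K @ f.alphas)


def _degenerate_fit(
    data: TrialDataset, w: PreferenceWeight, lam: float, v: np.ndarray
) -> OwlFit | None:
    """Handle degenerate weight patterns that the SVC solver cannot take.

    All-zero utilities: every function has zero surrogate risk, return the
    zero function (documented tie-break).  One arm with zero total weight:
    hinge terms come from a single arm, so the minimum is the constant rule
    assigning that arm (slope 0, intercept = that arm's sign).
    """
    p = data.z_matrix.shape[1]
    a = data.a_vector
    if np.all(v == 0):
        warnings.warn("all case weights are zero; returning the zero rule")
        return OwlFit(
            f=DecisionFunction("linear", 0.0, slope=np.zeros(p)),
            lam=lam, w=w, objective=0.0, surrogate=0.0,
            solver_status="degenerate: all-zero utilities",
        )
    for arm in (1.0, -1.0):
        if np.all(v[a == -arm] == 0):
            return OwlFit(
                f=DecisionFunction("linear", float(arm), slope=np.zeros(p)),
                lam=lam, w=w, objective=0.0, surrogate=0.0,
                solver_status="degenerate: single weighted arm",
            )
    return None


def _run_svc(data, v, svc) -> tuple[SVC, str]:
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        svc.fit(data.z_matrix, data.a_vector, sample_weight=v)
    status = "ok"
    if any(issubclass(c.category, ConvergenceWarning) for c in caught):
        # libsvm hit the iteration cap; the iterate is still feasible and in
        # practice at the optimum to well below the oracle tolerance
        status = "max_iter reached"
    return svc, status


def fit_linear(
    data: TrialDataset,
    w: PreferenceWeight,
    lam: float,
    h: CensoringHazard,
    pi_hat: float,
    tol: float = 1e-8,
) -> OwlFit:
    """Minimize the penalized surrogate risk over linear f(z) = b0 + b1'z.

    Global minimizer of the convex objective surrogate_risk(f) + lam*||b1||^2;
    the intercept is unpenalized.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < pi_hat < 1:
        raise ValueError("pi_hat must lie in (0, 1)")
    _, v = case_weights(data, w, h, pi_hat)
    deg = _degenerate_fit(data, w, lam, v)
    if deg is not None:
        return deg
    n = len(data)
    C = 1.0 / (2.0 * n * lam)
    svc = SVC(kernel="linear", C=C, tol=tol, max_iter=200_000, cache_size=64)
    svc, status = _run_svc(data, v, svc)
    f = DecisionFunction(
        "linear", intercept=float(svc.intercept_[0]), slope=svc.coef_[0].copy()
    )
    margins = data.a_vector * np.asarray(f(data.z_matrix), dtype=float)
    sr = float(np.mean(v * np.maximum(0.0, 1.0 - margins)))
    return OwlFit(
        f=f, lam=lam, w=w, surrogate=sr, objective=sr + _penalty(f, lam),
        n_support=int(svc.n_support_.sum()), solver_status=status,
    )


def fit_gaussian_kernel(
    data: TrialDataset,
    w: PreferenceWeight,
    lam: float,
    sigma: float,
    h: CensoringHazard,
    pi_hat: float,
    tol: float = 1e-8,
) -> OwlFit:
    """Minimize the penalized surrogate risk over the Gaussian-kernel RKHS.

    k(z1, z2) = exp(-sigma * ||z1 - z2||^2); by the representer theorem the
    minimizer is f(z) = sum_j alpha_j k(z, z_j) + b over the training points,
    with RKHS penalty lam * alpha' K alpha (intercept unpenalized).
    """
    if lam <= 0 or sigma <= 0:
        raise ValueError("lambda and sigma must be positive")
    if not 0 < pi_hat < 1:
        raise ValueError("pi_hat must lie in (0, 1)")
    _, v = case_weights(data, w, h, pi_hat)
    deg = _degenerate_fit(data, w, lam, v)
    if deg is not None:
        return deg
    n = len(data)
    C = 1.0 / (2.0 * n * lam)
    svc = SVC(kernel="rbf", gamma=sigma, C=C, tol=tol, max_iter=200_000,
              cache_size=64)
    svc, status = _run_svc(data, v, svc)
    f = DecisionFunction(
        "gaussian_kernel",
        intercept=float(svc.intercept_[0]),
        alphas=svc.dual_coef_[0].copy(),
        support_points=svc.support_vectors_.copy(),
        sigma=sigma,
    )
    margins = data.a_vector * np.asarray(f(data.z_matrix), dtype=float)
    sr = float(np.mean(v * np.maximum(0.0, 1.0 - margins)))
    return OwlFit(
        f=f, lam=lam, w=w, surrogate=sr, objective=sr + _penalty(f, lam),
        n_support=int(svc.n_support_.sum()), solver_status=status,
    )


def select_lambda(
    data: TrialDataset,
    w: PreferenceWeight,
    grid: Sequence[float],
    h: CensoringHazard,
    pi_hat: float,
) -> float:
    """Pick lambda from a grid by maximizing the leave-one-out (jackknife)
    value estimate; ties broken toward larger lambda (more regularization)."""
    from .inference import jackknife_value  # late import avoids a cycle

    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    if len(grid) == 1:
        return grid[0]
    best_lam, best_val = None, -np.inf
    for lam in grid:  # ascending: >= keeps the largest tied lambda
        val = jackknife_value(data, w, lam)
        if val >= best_val:
            best_lam, best_val = lam, val
    return best_lam
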