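"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the convex solve goes
through scipy's SLSQP on the primal slack formulation, and the censoring
hazard through a direct risk-set computation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def oracle_linear_objective(z: np.ndarray, a: np.ndarray, v: np.ndarray,
                            lam: float) -> tuple[float, np.ndarray, float]:
    """Solve min_{b0,b} mean(v * hinge(a*(b0+z@b))) + lam*||b||^2 by SLSQP
    on the slack-variable quadratic program.  Returns (objective, b, b0)."""
    n, p = z.shape

    def obj(x):
        b = x[1:1 + p]
        xi = x[1 + p:]
        return float(np.mean(v * xi) + lam * np.sum(b * b))

    def jac(x):
        b = x[1:1 + p]
        return np.concatenate(([0.0], 2 * lam * b, v / n))

    cons = [
        {"type": "ineq", "fun": lambda x: x[1 + p:]},
        {"type": "ineq",
         "fun": lambda x: x[1 + p:] - (1.0 - a * (x[0] + z @ x[1:1 + p]))},
    ]
    x0 = np.zeros(1 + p + n)
    x0[1 + p:] = 1.0
    res = minimize(obj, x0, jac=jac, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-12})
    return res.fun, res.x[1:1 + p], res.x[0]


def reverse_km_cumhazard(tilde_t: np.ndarray, delta: np.ndarray,
                         t: float) -> float:
    """Censoring cumulative hazard at t from a direct risk-set sum."""
    total = 0.0
    for u in np.unique(tilde_t[delta == 0]):
        if u <= t:
            total += np.sum((tilde_t == u) & (delta == 0)) / np.sum(tilde_t >= u)
    return float(total)
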