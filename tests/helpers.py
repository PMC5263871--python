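"""Independent oracles used by the tests.

These deliberately avoid the package's closed forms: debt areas come from
numeric quadrature of the interpolating trajectory, and REML solutions from
dense grid search (optionally golden-section refined). They are slow and
simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import simpson

from recoverydebt.meta import reml_loglik


def quadrature_rdt(x_start: float, x_end: float, x_ref: float, t_years: float,
                   kind: str = "exponential", panels: int = 10_000) -> float:
    """Per-annum debt by Simpson quadrature of x_ref - f(t) over (0, T).

    ``f`` interpolates the two endpoints exponentially (f = x_start e^{rt})
    or linearly. Inputs are the working (already transformed/adjusted)
    values, matching the oracle's role of checking the closed forms only.
    """
    t = np.linspace(0.0, t_years, panels + 1)
    if kind == "exponential":
        if x_start == x_end:
            f = np.full_like(t, x_start)
        else:
            r = math.log(x_end / x_start) / t_years
            f = x_start * np.exp(r * t)
    else:
        f = x_start + (x_end - x_start) * t / t_years
    rd = simpson(x_ref - f, x=t)
    return float(rd / t_years)


def ratio_from_rdt(rdt: float, x_ref: float) -> float:
    """The percent homogenization, re-derived independently for the oracle."""
    a = abs(x_ref)
    if rdt < 0:
        return 0.0
    return 100.0 * rdt / a if rdt <= a else 100.0 * a / rdt


def grid_reml(y, v, study, X=None, cap: float | None = None,
              coarse: int = 41, zooms: int = 4, fine: int = 21):
    """Dense grid search of the REML surface over (tau2_study, tau2_effect).

    A coarse grid over [0, cap]^2 followed by shrinking zoom grids around
    the running optimum. Returns (loglik, tau2_study, tau2_effect, final
    grid resolution).
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if X is None:
        X = np.ones((y.size, 1))
    if cap is None:
        cap = max(4.0 * float(np.var(y)), 10.0 * float(np.mean(v)), 1.0)

    def ll(ts, te):
        return reml_loglik(y, v, X, np.asarray(study), ts, te)

    ts_grid = np.linspace(0.0, cap, coarse)
    te_grid = np.linspace(0.0, cap, coarse)
    best = (-np.inf, 0.0, 0.0)
    for ts in ts_grid:
        for te in te_grid:
            val = ll(ts, te)
            if val > best[0]:
                best = (val, ts, te)
    width = cap / (coarse - 1)
    for _ in range(zooms):
        ts0, te0 = best[1], best[2]
        ts_grid = np.linspace(max(ts0 - width, 0.0), ts0 + width, fine)
        te_grid = np.linspace(max(te0 - width, 0.0), te0 + width, fine)
        for ts in ts_grid:
            for te in te_grid:
                val = ll(ts, te)
                if val > best[0]:
                    best = (val, ts, te)
        width = 2.0 * width / (fine - 1)
    return best[0], best[1], best[2], width


def golden_two_level(y, v, cap: float | None = None, tol: float = 1e-12):
    """Two-level random-effects REML by grid + golden-section on tau2.

    One effect per study, between-study component fixed at 0: the model
    collapses to the standard random-effects meta-analysis with a single
    heterogeneity variance. Returns (tau2, mu).
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    study = np.array([f"s{i}" for i in range(y.size)])
    X = np.ones((y.size, 1))

    def nll(t2):
        return -reml_loglik(y, v, X, study, 0.0, t2)

    if cap is None:
        cap = max(4.0 * float(np.var(y)), 10.0 * float(np.mean(v)), 1.0)
    grid = np.linspace(0.0, cap, 401)
    vals = [nll(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = nll(c), nll(d)
    while b - a > tol * max(1.0, b):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = nll(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = nll(d)
    t2 = 0.5 * (a + b)
    w = 1.0 / (v + t2)
    mu = float(np.sum(w * y) / np.sum(w))
    return t2, mu
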