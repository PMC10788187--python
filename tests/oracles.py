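"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths (and scipy helpers) used by the
package: B-splines via the textbook Cox-de Boor recursion, natural cubic
splines via a truncated-power construction, attribution via an explicit
per-day loop, and univariate REML via direct 1-D search.
"""

from __future__ import annotations

import numpy as np


def cox_de_boor(x: float, t: np.ndarray, j: int, k: int) -> float:
    """B_{j,k}(x) by the Cox-de Boor recursion on knot vector t."""
    if k == 0:
        # half-open intervals, closed at the right end of the basis domain
        if t[j] <= x < t[j + 1]:
            return 1.0
        if x == t[-1] and t[j] < t[j + 1] and t[j + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[j + k] - t[j]
    if d1 > 0:
        out += (x - t[j]) / d1 * cox_de_boor(x, t, j, k - 1)
    d2 = t[j + k + 1] - t[j + 1]
    if d2 > 0:
        out += (t[j + k + 1] - x) / d2 * cox_de_boor(x, t, j + 1, k - 1)
    return out


def bspline_basis_oracle(x: np.ndarray, interior, boundary, degree: int) -> np.ndarray:
    """Full B-spline basis matrix via Cox-de Boor."""
    lo, hi = boundary
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    m = len(t) - degree - 1
    out = np.empty((len(x), m))
    for i, xi in enumerate(np.asarray(x, dtype=float)):
        for j in range(m):
            out[i, j] = cox_de_boor(xi, t, j, degree)
    return out


def natural_cubic_space_oracle(x: np.ndarray, interior, boundary) -> np.ndarray:
    """A basis spanning the natural cubic spline space (truncated powers).

    Columns: 1, x, d_k(x) - d_{K-1}(x) for k = 1..K-2 where
    d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)
    with xi the full ordered knot sequence (boundary + interior).
    """
    x = np.asarray(x, dtype=float)
    xi = np.sort(np.concatenate([[boundary[0], boundary[1]], interior]))
    K = len(xi)

    def d(k):
        return ((np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[K - 1], 0.0) ** 3)
                / (xi[K - 1] - xi[k]))

    cols = [np.ones_like(x), x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def attribution_loop_oracle(curve_fn, temps, deaths, mmt, max_lag: int):
    """Day-by-day backward attribution with an explicit python loop.

    curve_fn maps temperature to the overall cumulative log-RR; days with
    fewer than max_lag preceding days are skipped (incomplete history).
    """
    n = len(temps)
    an = np.full(n, np.nan)
    for t in range(max_lag, n):
        b = curve_fn(temps[t]) - curve_fn(mmt)
        an[t] = deaths[t] * (1.0 - np.exp(-b))
    return an


def univariate_reml_oracle(thetas, variances):
    """Scalar random-effects REML by grid + golden-section refinement."""
    thetas = np.asarray(thetas, dtype=float)
    s2 = np.asarray(variances, dtype=float)

    def nll(tau2):
        w = 1.0 / (s2 + tau2)
        mu = np.sum(w * thetas) / np.sum(w)
        return 0.5 * (np.sum(np.log(s2 + tau2)) + np.log(np.sum(w))
                      + np.sum(w * (thetas - mu) ** 2))

    hi = 10.0 * np.var(thetas) + 1e-8
    grid = np.linspace(0.0, hi, 2001)
    best = grid[np.argmin([nll(g) for g in grid])]
    lo, up = max(best - hi / 2000, 0.0), best + hi / 2000
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, up
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(200):
        if nll(c) < nll(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    tau2 = 0.5 * (a + b)
    w = 1.0 / (s2 + tau2)
    mu = float(np.sum(w * thetas) / np.sum(w))
    return mu, float(tau2)
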