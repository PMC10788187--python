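"""One-dimensional spline bases.

Provides the bases used throughout the model: a quadratic B-spline for the
exposure dimension, natural cubic splines for the lag dimension, confounders
and the long-term time trend, plus the knot-placement rules (empirical
percentiles for exposure, log-equispaced values for the lag axis).

Conventions
-----------
* Quantiles use linear interpolation between order statistics ("type 7").
* Boundary knots default to the min/max of the observed variable.
* A B-spline basis "without intercept" drops the first column of the full
  basis (the full basis forms a partition of unity inside the boundaries).
* Natural cubic bases are built by constraining a cubic B-spline basis to
  have zero second derivative at (and linearity beyond) the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "quantile_knots",
    "log_lag_knots",
    "evaluate_basis",
    "natural_cubic_spec",
    "bspline_quadratic_spec",
    "time_basis",
]

_KINDS = ("bspline_quadratic", "natural_cubic", "constant")


@dataclass(frozen=True)
class BasisSpec:
    """Definition of a one-dimensional spline basis.

    Parameters
    ----------
    kind : {"bspline_quadratic", "natural_cubic"}
    interior_knots : tuple of float
        Strictly increasing, strictly inside the boundary knots.
    boundary_knots : (float, float)
    intercept : bool
        Whether the basis spans the constant function.
    """

    kind: str
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {_KINDS}")
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary_knots must be increasing, got {self.boundary_knots}")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and not np.all(np.diff(ik) > 0):
            raise ValueError(f"interior_knots must be strictly increasing, got {self.interior_knots}")
        if ik.size and (ik[0] <= lo or ik[-1] >= hi):
            raise ValueError(
                f"interior_knots must lie strictly inside boundary_knots "
                f"({lo}, {hi}), got {self.interior_knots}"
            )
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in ik))
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def degree(self) -> int:
        return 2 if self.kind == "bspline_quadratic" else 3

    @property
    def df(self) -> int:
        """Number of basis columns."""
        if self.kind == "constant":
            return 1
        n_int = len(self.interior_knots)
        if self.kind == "bspline_quadratic":
            return n_int + self.degree + (1 if self.intercept else 0)
        return n_int + 1 + (1 if self.intercept else 0)


@dataclass
class BasisMatrix:
    """A realized basis: an ``n x df`` design matrix with its spec."""

    values: np.ndarray
    spec: BasisSpec
    column_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("basis matrix contains non-finite entries")


def quantile_knots(x: np.ndarray, percentiles) -> np.ndarray:
    """Empirical percentiles of ``x`` (linear-interpolation rule), sorted."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot place quantile knots on an empty vector")
    p = np.asarray(percentiles, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    return np.sort(np.percentile(x, p, method="linear"))


def log_lag_knots(max_lag: int, n_knots: int = 3) -> np.ndarray:
    """Knots equally spaced on the log-lag axis between lag 1 and ``max_lag``.

    knot_j = max_lag ** (j / (n_knots + 1)), j = 1..n_knots.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if n_knots >= max_lag:
        raise ValueError(f"n_knots ({n_knots}) must be < max_lag ({max_lag})")
    j = np.arange(1, n_knots + 1)
    return np.asarray(float(max_lag) ** (j / (n_knots + 1)))


def _augmented_knots(spec: BasisSpec) -> np.ndarray:
    k = spec.degree
    lo, hi = spec.boundary_knots
    return np.concatenate([[lo] * (k + 1), spec.interior_knots, [hi] * (k + 1)])


def _design(x: np.ndarray, t: np.ndarray, k: int, deriv: int = 0) -> np.ndarray:
    """Dense B-spline design matrix (or a derivative of it) at points x."""
    m = len(t) - k - 1
    if deriv == 0:
        return BSpline.design_matrix(x, t, k, extrapolate=False).toarray()
    out = np.empty((len(x), m))
    for j in range(m):
        c = np.zeros(m)
        c[j] = 1.0
        out[:, j] = BSpline(t, c, k, extrapolate=False).derivative(deriv)(x)
    return out


def _natural_transform(spec: BasisSpec) -> np.ndarray:
    """Projection from the cubic B-spline basis onto the natural-spline subspace.

    QR of the boundary second-derivative constraints; columns 2.. of Q span
    the null space in which the second derivative vanishes at both boundaries.
    """
    t = _augmented_knots(spec)
    const = _design(np.asarray(spec.boundary_knots, dtype=float), t, 3, deriv=2)
    if not spec.intercept:
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return q[:, 2:]


def evaluate_basis(x, spec: BasisSpec, extrapolate: bool = False) -> BasisMatrix:
    """Evaluate a basis at the points ``x``.

    Points beyond the boundary knots raise unless ``extrapolate=True``, in
    which case the basis is extended linearly (value plus first derivative at
    the nearest boundary). Natural cubic bases are linear beyond the
    boundaries by construction, so this matches their analytic continuation.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if spec.kind == "constant":
        return BasisMatrix(values=np.ones((x.size, 1)), spec=spec, column_labels=["const"])
    lo, hi = spec.boundary_knots
    below, above = x < lo, x > hi
    outside = below | above
    if np.any(outside) and not extrapolate:
        bad = x[outside]
        raise ValueError(
            f"{outside.sum()} point(s) outside boundary knots ({lo}, {hi}); "
            f"e.g. {bad[:3]}; pass extrapolate=True for prediction grids"
        )

    t = _augmented_knots(spec)
    xin = np.clip(x, lo, hi)
    full = _design(xin, t, spec.degree)
    if np.any(outside):
        d1 = _design(np.array([lo, hi]), t, spec.degree, deriv=1)
        v0 = _design(np.array([lo, hi]), t, spec.degree)
        if np.any(below):
            full[below] = v0[0] + np.outer(x[below] - lo, d1[0])
        if np.any(above):
            full[above] = v0[1] + np.outer(x[above] - hi, d1[1])

    if spec.kind == "bspline_quadratic":
        values = full if spec.intercept else full[:, 1:]
        labels = [f"bs2_{j+1}" for j in range(values.shape[1])]
    else:
        base = full if spec.intercept else full[:, 1:]
        values = base @ _natural_transform(spec)
        labels = [f"ns_{j+1}" for j in range(values.shape[1])]
    return BasisMatrix(values=values, spec=spec, column_labels=labels)


def bspline_quadratic_spec(
    x, percentiles=(25.0, 50.0, 75.0), boundary=None, intercept: bool = False
) -> BasisSpec:
    """Quadratic B-spline spec with interior knots at percentiles of ``x``."""
    x = np.asarray(x, dtype=float)
    knots = quantile_knots(x, percentiles)
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    return BasisSpec("bspline_quadratic", tuple(knots), boundary, intercept)


def natural_cubic_spec(x, df: int, intercept: bool = False, boundary=None) -> BasisSpec:
    """Natural cubic spec with ``df`` columns; interior knots at equally
    spaced quantiles of ``x`` (the R ``ns(x, df)`` placement)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    n_int = df - 1 - (1 if intercept else 0)
    if n_int < 0:
        raise ValueError(f"df={df} too small for a natural cubic basis")
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    if n_int:
        p = 100.0 * np.arange(1, n_int + 1) / (n_int + 1)
        knots = quantile_knots(x, p)
        # guard against ties collapsing onto the boundary
        knots = np.unique(knots[(knots > boundary[0]) & (knots < boundary[1])])
    else:
        knots = np.empty(0)
    return BasisSpec("natural_cubic", tuple(knots), tuple(boundary), intercept)


def time_basis(dates, df_per_year: int) -> BasisMatrix:
    """Natural cubic basis on the day index with ``round(df_per_year * years)``
    total degrees of freedom; interior knots at equally spaced quantiles."""
    if df_per_year < 1:
        raise ValueError("df_per_year must be >= 1")
    dates = pd.DatetimeIndex(dates)
    if len(dates) < 2:
        raise ValueError("need at least two dates")
    deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        raise ValueError("dates must be strictly consecutive calendar days")
    n = len(dates)
    years = n / 365.25
    df = int(round(df_per_year * years))
    idx = np.arange(n, dtype=float)
    spec = natural_cubic_spec(idx, df=df, intercept=False)
    bm = evaluate_basis(idx, spec)
    bm.column_labels = [f"time_{j+1}" for j in range(bm.values.shape[1])]
    return bm
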