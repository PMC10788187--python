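"""Bi-dimensional exposure-lag cross-basis.

Combines an exposure basis (vx functions of temperature) with a lag basis
(vl functions of lag 0..L, evaluated at integer lags) into an
``n x (vx*vl)`` design matrix, reduces fitted coefficients to the overall
cumulative exposure-response, and predicts centered RR curves and
lag-response curves.

Column ordering is exposure-major: column ``j*vl + k`` pairs exposure basis
function ``j`` with lag basis function ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .splines import BasisSpec, evaluate_basis

__all__ = [
    "CrossBasisSpec",
    "CrossBasis",
    "ReducedFit",
    "CurvePrediction",
    "LagCurvePrediction",
    "build_crossbasis",
    "reduce_overall",
    "predict_curve",
    "predict_lag_curve",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class CrossBasisSpec:
    exposure_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def vx(self) -> int:
        return self.exposure_spec.df

    @property
    def vl(self) -> int:
        return self.lag_spec.df

    @property
    def ncol(self) -> int:
        return self.vx * self.vl

    def lag_matrix(self) -> np.ndarray:
        """Lag basis evaluated at integer lags 0..L, shape (L+1, vl)."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        return evaluate_basis(lags, self.lag_spec, extrapolate=True).values


@dataclass
class CrossBasis:
    """Realized cross-basis matrix.

    Rows with incomplete lag history (the first ``max_lag`` days) hold NaN
    and are flagged False in ``complete``; they must be excluded from any
    regression.
    """

    values: np.ndarray
    spec: CrossBasisSpec
    complete: np.ndarray

    @property
    def column_labels(self) -> list[str]:
        vl = self.spec.vl
        return [f"cb_x{j+1}_l{k+1}" for j in range(self.spec.vx) for k in range(vl)]


@dataclass
class ReducedFit:
    """Overall cumulative exposure-response coefficients for one city."""

    coef: np.ndarray
    vcov: np.ndarray
    exposure_spec: BasisSpec
    # temperatures at percentiles 0..100 by 0.1 (length 1001), if attached
    temp_percentiles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = self.coef.size
        if self.vcov.shape != (k, k):
            raise ValueError("coef/vcov dimension mismatch")
        sym_err = np.max(np.abs(self.vcov - self.vcov.T)) if k else 0.0
        if sym_err > 1e-8:
            raise ValueError(f"vcov asymmetric beyond tolerance ({sym_err:.2e})")
        self.vcov = 0.5 * (self.vcov + self.vcov.T)
        if k and np.min(np.linalg.eigvalsh(self.vcov)) < -1e-10 * max(1.0, np.trace(self.vcov)):
            raise ValueError("vcov is not positive semi-definite")


@dataclass
class CurvePrediction:
    """Centered cumulative exposure-response curve on a temperature grid."""

    grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    center: float
    rr: np.ndarray = field(init=False)
    rr_low: np.ndarray = field(init=False)
    rr_high: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rr = np.exp(self.log_rr)
        self.rr_low = np.exp(self.log_rr - _Z95 * self.se)
        self.rr_high = np.exp(self.log_rr + _Z95 * self.se)


@dataclass
class LagCurvePrediction:
    lags: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    at_temp: float
    center: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - _Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + _Z95 * self.se)


def build_crossbasis(x, spec: CrossBasisSpec) -> CrossBasis:
    """Build the cross-basis matrix for a temperature series.

    Entry ``(t, j*vl+k) = sum_l R_j(x[t-l]) * C_k(l)`` over lags 0..L.
    """
    x = np.asarray(x, dtype=float)
    L = spec.max_lag
    n = x.size
    if n <= L:
        raise ValueError(f"series length {n} must exceed max_lag {L}")
    R = evaluate_basis(x, spec.exposure_spec).values  # (n, vx)
    C = spec.lag_matrix()  # (L+1, vl)
    vals = np.full((n, spec.ncol), np.nan)
    idx = np.arange(L, n)
    # stacked lagged exposure basis: (n-L, L+1, vx)
    W = np.stack([R[idx - l] for l in range(L + 1)], axis=1)
    vals[L:] = np.einsum("tlj,lk->tjk", W, C).reshape(n - L, spec.ncol)
    complete = np.zeros(n, dtype=bool)
    complete[L:] = True
    return CrossBasis(values=vals, spec=spec, complete=complete)


def reduction_matrix(spec: CrossBasisSpec) -> np.ndarray:
    """The vx x (vx*vl) matrix mapping full coefficients to the overall
    cumulative parameterization: each exposure block is contracted against
    the lag basis summed over integer lags."""
    w = spec.lag_matrix().sum(axis=0)  # (vl,)
    M = np.zeros((spec.vx, spec.ncol))
    for j in range(spec.vx):
        M[j, j * spec.vl : (j + 1) * spec.vl] = w
    return M


def reduce_overall(
    full_coef, full_vcov, spec: CrossBasisSpec, temp_percentiles=None
) -> ReducedFit:
    """Reduce full cross-basis coefficients to the overall cumulative curve."""
    full_coef = np.asarray(full_coef, dtype=float)
    full_vcov = np.asarray(full_vcov, dtype=float)
    if full_coef.shape != (spec.ncol,) or full_vcov.shape != (spec.ncol, spec.ncol):
        raise ValueError(
            f"expected coef length {spec.ncol} and matching vcov, "
            f"got {full_coef.shape} / {full_vcov.shape}"
        )
    M = reduction_matrix(spec)
    return ReducedFit(
        coef=M @ full_coef,
        vcov=M @ full_vcov @ M.T,
        exposure_spec=spec.exposure_spec,
        temp_percentiles=None if temp_percentiles is None else np.asarray(temp_percentiles, float),
    )


def average_exposure_spec(specs: list[BasisSpec]) -> BasisSpec:
    """Representative exposure basis for pooled coefficients.

    Per-city bases are percentile-anchored and therefore comparable on the
    coefficient scale; the pooled curve is presented on the basis whose
    knots and boundaries are the across-city averages.
    """
    if not specs:
        raise ValueError("need at least one exposure spec")
    kinds = {s.kind for s in specs}
    if len(kinds) > 1 or {s.intercept for s in specs} != {specs[0].intercept}:
        raise ValueError("exposure specs are not comparable")
    ik = np.mean([s.interior_knots for s in specs], axis=0)
    bk = np.mean([s.boundary_knots for s in specs], axis=0)
    return BasisSpec(specs[0].kind, tuple(ik), (float(bk[0]), float(bk[1])), specs[0].intercept)


def _centered_design(exposure_spec: BasisSpec, grid, center: float) -> np.ndarray:
    lo, hi = exposure_spec.boundary_knots
    if not lo <= center <= hi:
        raise ValueError(f"center {center} outside basis boundary ({lo}, {hi})")
    B = evaluate_basis(grid, exposure_spec, extrapolate=True).values
    Bc = evaluate_basis([center], exposure_spec).values
    return B - Bc


def predict_curve(fit: ReducedFit, grid, center: float) -> CurvePrediction:
    """Centered log-RR curve with pointwise 95% bands; log_rr(center) == 0."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    X = _centered_design(fit.exposure_spec, grid, center)
    log_rr = X @ fit.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.vcov, X), 0.0))
    return CurvePrediction(grid=grid, log_rr=log_rr, se=se, center=float(center))


def predict_lag_curve(
    full_coef, full_vcov, spec: CrossBasisSpec, at_temp: float, center: float
) -> LagCurvePrediction:
    """Lag-specific RR at ``at_temp`` vs ``center`` for integer lags 0..L."""
    full_coef = np.asarray(full_coef, dtype=float)
    full_vcov = np.asarray(full_vcov, dtype=float)
    delta = _centered_design(spec.exposure_spec, [at_temp], center)[0]  # (vx,)
    C = spec.lag_matrix()  # (L+1, vl)
    # row l: kron(delta, C[l]) in exposure-major order
    Z = np.einsum("j,lk->ljk", delta, C).reshape(spec.max_lag + 1, spec.ncol)
    log_rr = Z @ full_coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, full_vcov, Z), 0.0))
    return LagCurvePrediction(
        lags=np.arange(spec.max_lag + 1),
        log_rr=log_rr,
        se=se,
        at_temp=float(at_temp),
        center=float(center),
    )
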