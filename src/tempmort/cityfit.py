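"""First-stage quasi-likelihood regression per city and stratum.

Daily deaths are regressed on the temperature cross-basis plus natural
cubic splines of relative humidity, PM2.5 and O3, a long-term/seasonal time
spline, and day-of-week indicators. The cross-basis coefficient block and
its covariance are extracted and reduced to the overall cumulative
exposure-response curve, which feeds the second stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .crossbasis import (
    CrossBasisSpec,
    ReducedFit,
    build_crossbasis,
    reduce_overall,
)
from .splines import (
    BasisSpec,
    bspline_quadratic_spec,
    evaluate_basis,
    log_lag_knots,
    natural_cubic_spec,
    time_basis,
)
from .synthetic import DailyCitySeries

__all__ = ["ModelSpec", "CityFit", "fit_city", "drop_missing", "PERCENTILE_GRID"]

# percentile grid 0..100 by 0.1, used for MMT search and attribution levels
PERCENTILE_GRID = np.linspace(0.0, 100.0, 1001)


@dataclass(frozen=True)
class ModelSpec:
    """First-stage model configuration (defaults match the main analysis)."""

    max_lag: int = 25
    exposure_percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)
    n_lag_knots: int = 3
    confounder_df: int = 4
    time_df_per_year: int = 8
    dow: bool = True
    family: str = "poisson"
    include_pm25: bool = True
    include_o3: bool = True

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.confounder_df < 1 or self.time_df_per_year < 1:
            raise ValueError("all degrees of freedom must be >= 1")
        if self.family not in ("poisson", "quasipoisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class CityFit:
    """Fitted first-stage model for one city and stratum."""

    city_id: str
    stratum: str
    crossbasis_spec: CrossBasisSpec
    full_coef: np.ndarray
    full_vcov: np.ndarray
    dispersion: float
    n_days_used: int
    converged: bool
    n_iter: int
    reduced: ReducedFit
    temp_percentiles: np.ndarray  # temperature at PERCENTILE_GRID
    warnings_: list[str] = field(default_factory=list)
    params_: np.ndarray | None = None  # full coefficient vector (diagnostics)


def drop_missing(series: DailyCitySeries, stratum: str, max_lag: int) -> np.ndarray:
    """Boolean mask of usable regression rows.

    A row needs: complete lag history (day index > max_lag - 1 and no missing
    temperature in its lag window), a non-missing outcome, and non-missing
    same-day covariates. Missing temperatures still occupy calendar slots so
    later rows' lag histories stay aligned.
    """
    y = np.asarray(series.deaths[stratum], dtype=float)
    n = series.n_days
    temp_ok = np.isfinite(series.temp_mean)
    # complete lag history: all of t-L..t have observed temperature
    hist_ok = np.zeros(n, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(temp_ok.astype(int))])
    L = max_lag
    idx = np.arange(L, n)
    hist_ok[L:] = (csum[idx + 1] - csum[idx - L]) == L + 1
    row_ok = (
        hist_ok
        & np.isfinite(y)
        & np.isfinite(series.rh)
        & np.isfinite(series.pm25)
        & np.isfinite(series.o3)
    )
    n_candidate = n - L
    frac_missing = 1.0 - row_ok.sum() / n_candidate
    if frac_missing > 0.5:
        raise ValueError(
            f"city {series.city_id!r} stratum {stratum!r}: "
            f"{100 * frac_missing:.1f}% of rows unusable (limit 50%)"
        )
    if frac_missing > 0.2:
        warnings.warn(
            f"city {series.city_id!r} stratum {stratum!r}: "
            f"{100 * frac_missing:.1f}% of rows missing",
            stacklevel=2,
        )
    return row_ok


def _design(series: DailyCitySeries, stratum: str, spec: ModelSpec):
    """Assemble the full regression design matrix and metadata."""
    temp = series.temp_mean
    obs_temp = temp[np.isfinite(temp)]
    exposure_spec = bspline_quadratic_spec(obs_temp, spec.exposure_percentiles)
    lag_knots = log_lag_knots(spec.max_lag, spec.n_lag_knots)
    lag_spec = BasisSpec(
        "natural_cubic", tuple(lag_knots), (0.0, float(spec.max_lag)), intercept=True
    )
    cb_spec = CrossBasisSpec(exposure_spec, lag_spec, spec.max_lag)
    # NaN temperatures would poison the basis; impute for construction only,
    # the affected rows are masked out by drop_missing
    temp_f = np.where(np.isfinite(temp), temp, np.median(obs_temp))
    cb = build_crossbasis(temp_f, cb_spec)

    cols = [np.ones((series.n_days, 1))]
    names = ["intercept"]
    cols.append(cb.values)
    names += cb.column_labels

    def add_ns(x, label):
        x = np.asarray(x, dtype=float)
        xs = natural_cubic_spec(x[np.isfinite(x)], df=spec.confounder_df)
        xf = np.where(np.isfinite(x), x, np.median(x[np.isfinite(x)]))
        bm = evaluate_basis(xf, xs, extrapolate=True)
        cols.append(bm.values)
        names.extend(f"{label}_{j+1}" for j in range(bm.values.shape[1]))

    add_ns(series.rh, "rh")
    if spec.include_pm25:
        add_ns(series.pm25, "pm25")
    if spec.include_o3:
        add_ns(series.o3, "o3")

    tb = time_basis(series.dates, spec.time_df_per_year)
    cols.append(tb.values)
    names += tb.column_labels

    if spec.dow:
        dow = series.dates.dayofweek.to_numpy()
        dummies = (dow[:, None] == np.arange(1, 7)[None, :]).astype(float)
        cols.append(dummies)
        names += [f"dow_{d}" for d in range(1, 7)]

    X = np.hstack(cols)
    cb_slice = slice(1, 1 + cb_spec.ncol)
    return X, names, cb_spec, cb_slice


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_city(series: DailyCitySeries, stratum: str, spec: ModelSpec) -> CityFit:
    """Fit the first-stage log-linear model for one city and stratum."""
    if stratum not in series.deaths:
        raise KeyError(f"stratum {stratum!r} not present in city {series.city_id!r}")
    if series.n_days < 2 * 365:
        raise ValueError(
            f"city {series.city_id!r}: need >= 2 years of data, got {series.n_days} days"
        )
    warns: list[str] = []
    y_all = np.asarray(series.deaths[stratum], dtype=float)
    if y_all[np.isfinite(y_all)].mean() < 3:
        warns.append(
            f"mean daily deaths < 3 in city {series.city_id!r} stratum {stratum!r}; "
            "first-stage estimates will be noisy (BLUP shrinkage recommended)"
        )

    X, names, cb_spec, cb_slice = _design(series, stratum, spec)
    mask = drop_missing(series, stratum, spec.max_lag)
    Xu, yu = X[mask], y_all[mask]
    _check_rank(Xu, names)

    model = sm.GLM(yu, Xu, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-9)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge for city {series.city_id!r} stratum {stratum!r} "
            f"(deviance {res.deviance:.3g} after {res.fit_history['iteration']} iterations)"
        )

    dof = Xu.shape[0] - Xu.shape[1]
    dispersion = float(res.pearson_chi2 / dof)
    vcov = np.asarray(res.cov_params())
    if spec.family == "quasipoisson":
        vcov = vcov * dispersion

    full_coef = np.asarray(res.params)[cb_slice]
    full_vcov = vcov[cb_slice, cb_slice]

    temp_obs = series.temp_mean[np.isfinite(series.temp_mean)]
    pct = np.percentile(temp_obs, PERCENTILE_GRID, method="linear")
    reduced = reduce_overall(full_coef, full_vcov, cb_spec, temp_percentiles=pct)

    return CityFit(
        city_id=series.city_id,
        stratum=stratum,
        crossbasis_spec=cb_spec,
        full_coef=full_coef,
        full_vcov=full_vcov,
        dispersion=dispersion,
        n_days_used=int(mask.sum()),
        converged=converged,
        n_iter=int(res.fit_history["iteration"]) if hasattr(res, "fit_history") else -1,
        reduced=reduced,
        temp_percentiles=pct,
        warnings_=warns,
        params_=np.asarray(res.params),
    )
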