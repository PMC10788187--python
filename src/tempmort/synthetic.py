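"""Synthetic multi-city daily mortality panels with a known ground truth.

Temperature is a seasonal sinusoid (annual minimum in January) plus AR(1)
Gaussian noise. Daily deaths are Poisson with a log rate combining a
baseline level, smooth seasonal/long-term trends, day-of-week offsets and a
known exposure-lag-response surface: a cumulative log-RR curve that is zero
at its minimum-mortality temperature, distributed over lags by per-side
share vectors (acute heat concentrated at lags 0-3, prolonged cold spread
over the full lag window). Strata are multinomial splits of the daily total.

Every generator takes an explicit seed and is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CityClimateSpec",
    "TrueRiskSurface",
    "BaselineMortalitySpec",
    "DailyCitySeries",
    "simulate_temperature",
    "simulate_city",
    "write_panel",
    "read_panel",
    "default_city_climates",
    "default_risk_surface",
    "null_risk_surface",
    "reference_panel",
    "default_strata_weights",
]

PANEL_COLUMNS = ["city", "date", "stratum", "deaths", "temp_mean", "rh", "pm25", "o3"]


@dataclass(frozen=True)
class CityClimateSpec:
    """Climate parameters for one synthetic city."""

    city_id: str
    n_years: int = 6
    annual_mean_temp: float = 18.0
    seasonal_amplitude: float = 8.0
    ar_coefficient: float = 0.7
    daily_sd: float = 2.5
    rh_mean: float = 72.0
    rh_sd: float = 10.0
    pm25_mean: float = 40.0
    pm25_sd: float = 20.0
    o3_mean: float = 85.0
    o3_sd: float = 35.0
    start_year: int = 2016

    def __post_init__(self) -> None:
        for name in ("n_years",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.seasonal_amplitude < 0:
            raise ValueError(f"seasonal_amplitude must be >= 0, got {self.seasonal_amplitude}")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError(f"|ar_coefficient| must be < 1, got {self.ar_coefficient}")
        for name in ("daily_sd", "rh_sd", "pm25_sd", "o3_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class TrueRiskSurface:
    """Ground-truth exposure-lag-response surface.

    ``curve`` maps temperature to cumulative log-RR relative to its minimum
    (zero at ``true_mmt``, >= 0 elsewhere). ``heat_lag_shares`` and
    ``cold_lag_shares`` distribute that cumulative effect over lags 0..L and
    each sum to one.
    """

    curve: Callable[[np.ndarray], np.ndarray]
    heat_lag_shares: np.ndarray
    cold_lag_shares: np.ndarray
    true_mmt: float
    max_lag: int

    def __post_init__(self) -> None:
        self.heat_lag_shares = np.asarray(self.heat_lag_shares, dtype=float)
        self.cold_lag_shares = np.asarray(self.cold_lag_shares, dtype=float)
        for name, shares in (("heat", self.heat_lag_shares), ("cold", self.cold_lag_shares)):
            if shares.shape != (self.max_lag + 1,):
                raise ValueError(f"{name}_lag_shares must have length max_lag+1")
            if abs(shares.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name}_lag_shares must sum to 1 (got {shares.sum()})")
        v = float(np.asarray(self.curve(np.array([self.true_mmt])))[0])
        if abs(v) > 1e-9:
            raise ValueError(f"curve(true_mmt) must be 0, got {v}")

    def lag_share(self, temps: np.ndarray) -> np.ndarray:
        """Per-day share matrix (n, L+1): heat shares above MMT, cold below."""
        temps = np.asarray(temps, dtype=float)
        out = np.where(
            (temps >= self.true_mmt)[:, None], self.heat_lag_shares, self.cold_lag_shares
        )
        return out


@dataclass(frozen=True)
class BaselineMortalitySpec:
    """Baseline mortality process: level, smooth trend, day-of-week offsets."""

    mean_daily_deaths: float = 60.0
    trend_df_per_year: int = 2
    trend_amplitude: float = 0.03
    dow_effects: tuple[float, ...] = (0.01, 0.0, -0.01, 0.0, 0.01, 0.005, -0.015)

    def __post_init__(self) -> None:
        if self.mean_daily_deaths <= 0:
            raise ValueError("mean_daily_deaths must be > 0")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if abs(sum(self.dow_effects)) > 1e-9:
            raise ValueError("dow_effects must sum to 0")


@dataclass
class DailyCitySeries:
    """One city's aligned daily vectors; ``deaths`` keyed by stratum label."""

    city_id: str
    dates: pd.DatetimeIndex
    deaths: dict[str, np.ndarray]
    temp_mean: np.ndarray
    rh: np.ndarray
    pm25: np.ndarray
    o3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.dates)
        if "total" not in self.deaths:
            raise ValueError("deaths must include the 'total' stratum")
        for key, arr in self.deaths.items():
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ValueError(f"deaths[{key!r}] length {arr.shape} != {n}")
            if np.any(arr < 0):
                raise ValueError(f"deaths[{key!r}] has negative counts")
            self.deaths[key] = arr.astype(np.int64)
        for name in ("temp_mean", "rh", "pm25", "o3"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, v)
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            bad = np.nonzero(deltas != 1)[0][0]
            raise ValueError(
                f"dates must be consecutive; gap between "
                f"{self.dates[bad].date()} and {self.dates[bad + 1].date()}"
            )

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def strata(self) -> list[str]:
        return list(self.deaths)


def _dates_for(spec: CityClimateSpec) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=spec.start_year, month=1, day=1)
    end = pd.Timestamp(year=spec.start_year + spec.n_years - 1, month=12, day=31)
    return pd.date_range(start, end, freq="D")


def _seasonal_mean(dates: pd.DatetimeIndex, spec: CityClimateSpec) -> np.ndarray:
    # phase chosen so the annual minimum falls mid-January
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = 15.0 + 365.25 / 4.0
    return spec.annual_mean_temp + spec.seasonal_amplitude * np.sin(
        2.0 * np.pi * (doy - phase) / 365.25
    )


def _ar1(n: int, ar: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - ar**2) if ar != 0 else sd
    eps = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    prev = rng.normal(0.0, sd)
    for t in range(n):
        prev = ar * prev + eps[t]
        out[t] = prev
    return out


def simulate_temperature(spec: CityClimateSpec, seed) -> np.ndarray:
    """Daily mean temperature: seasonal sinusoid + AR(1) noise."""
    rng = np.random.default_rng(seed)
    dates = _dates_for(spec)
    return _seasonal_mean(dates, spec) + _ar1(
        len(dates), spec.ar_coefficient, spec.daily_sd, rng
    )


def simulate_city(
    climate: CityClimateSpec,
    risk: TrueRiskSurface,
    baseline: BaselineMortalitySpec,
    strata_weights: Mapping[str, float] | None = None,
    seed=0,
    overdispersion: float = 1.0,
) -> DailyCitySeries:
    """Simulate one city's daily series from the ground-truth surface.

    An extra ``max_lag`` days of temperature are generated before the first
    emitted day (burn-in), so every emitted death count has a complete lag
    history feeding its rate.
    """
    rng = np.random.default_rng(seed)
    dates = _dates_for(climate)
    L = risk.max_lag
    if L >= len(dates):
        raise ValueError(f"lag history ({L}) longer than series ({len(dates)})")
    ext_dates = pd.date_range(dates[0] - pd.Timedelta(days=L), dates[-1], freq="D")
    temp_ext = _seasonal_mean(ext_dates, climate) + _ar1(
        len(ext_dates), climate.ar_coefficient, climate.daily_sd, rng
    )
    n = len(dates)
    temp = temp_ext[L:]

    rh = np.clip(rng.normal(climate.rh_mean, climate.rh_sd, size=n), 0.0, 100.0)
    pm25 = _lognormal(climate.pm25_mean, climate.pm25_sd, n, rng)
    o3 = _lognormal(climate.o3_mean, climate.o3_sd, n, rng)

    # distributed-lag risk contribution, burn-in giving full histories
    curve_ext = np.asarray(risk.curve(temp_ext), dtype=float)
    if np.any(curve_ext < -1e-9):
        raise ValueError("risk curve must be >= 0 everywhere")
    share_ext = risk.lag_share(temp_ext)  # (n+L, L+1)
    risk_term = np.zeros(n)
    for l in range(L + 1):
        # exposure on day (t - l) contributes share[l] of its cumulative effect
        sl = slice(L - l, L - l + n)
        risk_term += share_ext[sl, l] * curve_ext[sl]

    t_idx = np.arange(n, dtype=float)
    doy = dates.dayofyear.to_numpy(dtype=float)
    trend = baseline.trend_amplitude * (
        0.5 * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25) + (t_idx / n - 0.5)
    )
    dow = np.asarray(baseline.dow_effects)[dates.dayofweek.to_numpy()]

    lam = np.exp(np.log(baseline.mean_daily_deaths) + trend + dow + risk_term)
    if overdispersion > 1.0:
        shape = lam / (overdispersion - 1.0)
        lam = lam * rng.gamma(shape, 1.0 / shape)
    total = rng.poisson(lam)

    deaths: dict[str, np.ndarray] = {"total": total}
    if strata_weights:
        labels = list(strata_weights)
        p = np.asarray([strata_weights[k] for k in labels], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"strata weights must sum to 1, got {p.sum()}")
        draws = rng.multinomial(total, p)  # (n, n_strata)
        for j, lab in enumerate(labels):
            deaths[lab] = draws[:, j]

    return DailyCitySeries(
        city_id=climate.city_id,
        dates=dates,
        deaths=deaths,
        temp_mean=temp,
        rh=rh,
        pm25=pm25,
        o3=o3,
    )


def _lognormal(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws with approximately the given natural-scale mean/sd."""
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# default ground truth and reference panel


def _geometric_shares(n: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(n, dtype=float)
    return w / w.sum()


def default_risk_surface(
    true_mmt: float = 25.0,
    max_lag: int = 25,
    cold_coef: float = 2.0e-3,
    heat_coef: float = 1.0e-2,
) -> TrueRiskSurface:
    """Piecewise-quadratic U-shape: prolonged cold effects, acute heat.

    The cold limb spans a much wider temperature range than the heat limb,
    so it carries the larger cumulative log-RR at the observed extremes
    (cold-dominant burden); heat has a larger per-degree curvature over its
    short span. Heat shares decay geometrically over lags 0-3, cold shares
    decay slowly over the full window.
    """
    def curve(x):
        x = np.asarray(x, dtype=float)
        d = x - true_mmt
        return np.where(d < 0, cold_coef * d**2, heat_coef * d**2)

    heat = np.zeros(max_lag + 1)
    heat[:4] = _geometric_shares(4, 0.4)
    cold = _geometric_shares(max_lag + 1, 0.85)
    return TrueRiskSurface(
        curve=curve,
        heat_lag_shares=heat,
        cold_lag_shares=cold,
        true_mmt=true_mmt,
        max_lag=max_lag,
    )


def null_risk_surface(max_lag: int = 25) -> TrueRiskSurface:
    """Flat surface: temperature has no effect on mortality."""
    return TrueRiskSurface(
        curve=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        heat_lag_shares=_geometric_shares(max_lag + 1, 0.5),
        cold_lag_shares=_geometric_shares(max_lag + 1, 0.9),
        true_mmt=20.0,
        max_lag=max_lag,
    )


def default_city_climates(n_cities: int = 4, n_years: int = 6) -> list[CityClimateSpec]:
    """Four basin-like city climates (subtropical, humid, polluted winters)."""
    base = [
        CityClimateSpec("city_a", n_years, 17.5, 8.5, 0.72, 2.2, 79.7, 9.4, 47.4, 33.0, 94.2, 47.2),
        CityClimateSpec("city_b", n_years, 19.0, 8.3, 0.70, 2.3, 78.6, 12.1, 54.0, 37.4, 82.7, 38.5),
        CityClimateSpec("city_c", n_years, 18.0, 8.4, 0.68, 2.4, 70.1, 14.6, 26.5, 17.2, 72.9, 31.6),
        CityClimateSpec("city_d", n_years, 21.5, 6.8, 0.70, 2.0, 54.2, 20.0, 29.4, 12.7, 88.9, 30.4),
    ]
    return base[:n_cities]


def default_strata_weights() -> dict[str, dict[str, float]]:
    """Complementary stratum pairs used by the stratified pipeline."""
    return {
        "sex": {"male": 0.52, "female": 0.48},
        "age": {"age_0_64": 0.25, "age_65_plus": 0.75},
        "education": {"edu_low": 0.65, "edu_high": 0.35},
        "marital": {"married": 0.6, "other_marital": 0.4},
    }


def reference_panel(
    seed: int = 1234,
    n_cities: int = 4,
    n_years: int = 6,
    risk: TrueRiskSurface | None = None,
    mean_deaths: Sequence[float] = (240.0, 58.0, 47.0, 18.0),
    with_strata: bool = True,
) -> list[DailyCitySeries]:
    """The packaged multi-city reference panel with known ground truth."""
    if risk is None:
        risk = default_risk_surface()
    climates = default_city_climates(n_cities, n_years)
    groups = default_strata_weights() if with_strata else None
    panel = []
    for i, climate in enumerate(climates):
        baseline = BaselineMortalitySpec(mean_daily_deaths=float(mean_deaths[i % len(mean_deaths)]))
        series = simulate_city(
            climate,
            risk,
            baseline,
            strata_weights=None,
            seed=np.random.SeedSequence([seed, i]),
        )
        if groups:
            _attach_strata(series, groups, np.random.default_rng(np.random.SeedSequence([seed, i, 7])))
        panel.append(series)
    return panel


def _attach_strata(
    series: DailyCitySeries,
    groups: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> None:
    """Split the daily totals into each grouping's strata (multinomial)."""
    total = series.deaths["total"]
    for weights in groups.values():
        labels = list(weights)
        p = np.asarray([weights[k] for k in labels], dtype=float)
        draws = rng.multinomial(total, p / p.sum())
        for j, lab in enumerate(labels):
            series.deaths[lab] = draws[:, j]


# ---------------------------------------------------------------------------
# CSV panel I/O


def write_panel(panel: Sequence[DailyCitySeries], path) -> None:
    """Write a long-format CSV: one row per city x date x stratum."""
    frames = []
    for s in panel:
        for stratum, counts in s.deaths.items():
            frames.append(
                pd.DataFrame(
                    {
                        "city": s.city_id,
                        "date": s.dates.strftime("%Y-%m-%d"),
                        "stratum": stratum,
                        "deaths": counts,
                        "temp_mean": s.temp_mean,
                        "rh": s.rh,
                        "pm25": s.pm25,
                        "o3": s.o3,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_panel(path) -> list[DailyCitySeries]:
    """Read a panel CSV, validating the schema.

    Raises ``ValueError`` naming the offending rows for missing columns,
    date gaps, or negative counts.
    """
    df = pd.read_csv(path, dtype={"city": str, "stratum": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing required columns: {missing}")
    neg = df[df["deaths"] < 0]
    if len(neg):
        raise ValueError(
            f"negative death counts at rows {neg.index[:5].tolist()} "
            f"(city={neg['city'].iloc[0]}, date={neg['date'].iloc[0]})"
        )
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    panel = []
    for city, g in df.groupby("city", sort=True):
        strata = {}
        dates = None
        covs = None
        for stratum, gs in g.groupby("stratum", sort=True):
            gs = gs.sort_values("date")
            d = pd.DatetimeIndex(gs["date"])
            deltas = np.diff(d.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas != 1):
                bad = np.nonzero(deltas != 1)[0][0]
                raise ValueError(
                    f"city {city!r} stratum {stratum!r}: date gap between "
                    f"{d[bad].date()} and {d[bad + 1].date()}"
                )
            if dates is None:
                dates = d
                covs = (
                    gs["temp_mean"].to_numpy(float),
                    gs["rh"].to_numpy(float),
                    gs["pm25"].to_numpy(float),
                    gs["o3"].to_numpy(float),
                )
            elif not dates.equals(d):
                raise ValueError(f"city {city!r}: strata cover different date ranges")
            strata[stratum] = gs["deaths"].to_numpy(np.int64)
        panel.append(
            DailyCitySeries(
                city_id=str(city),
                dates=dates,
                deaths=strata,
                temp_mean=covs[0],
                rh=covs[1],
                pm25=covs[2],
                o3=covs[3],
            )
        )
    return panel


def write_truth_sidecar(path, risk: TrueRiskSurface, seed: int, grid=None) -> None:
    """JSON sidecar recording the ground-truth surface for recovery tests."""
    if grid is None:
        grid = np.arange(-10.0, 40.1, 0.5)
    grid = np.asarray(grid, dtype=float)
    payload = {
        "seed": int(seed),
        "true_mmt": risk.true_mmt,
        "max_lag": risk.max_lag,
        "curve_grid": grid.tolist(),
        "curve_values": np.asarray(risk.curve(grid), dtype=float).tolist(),
        "heat_lag_shares": risk.heat_lag_shares.tolist(),
        "cold_lag_shares": risk.cold_lag_shares.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
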