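"""Attributable burden of non-optimal temperature.

Finds each city's minimum-mortality temperature/percentile (MMT/MMP) on a
0.1-percentile grid between the 1st and 99th percentiles, attributes daily
deaths backward using the overall cumulative curve centered at the MMT,
decomposes the burden into extreme/moderate cold/heat by the 1st and 99th
percentile cutoffs, and builds 95% empirical confidence intervals by Monte
Carlo resampling of the coefficient vector (MMT held fixed at its point
estimate across draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cityfit import PERCENTILE_GRID
from .splines import BasisSpec, evaluate_basis

__all__ = [
    "MMTResult",
    "TemperatureLevels",
    "AttributionResult",
    "find_mmt",
    "attribute_daily",
    "decompose",
    "monte_carlo_eci",
    "attribute_city",
    "aggregate_cities",
    "COMPONENTS",
]

COMPONENTS = (
    "total",
    "cold",
    "heat",
    "extreme_cold",
    "moderate_cold",
    "moderate_heat",
    "extreme_heat",
)


@dataclass
class MMTResult:
    mmt: float
    mmp: float
    source: str = "blup"
    grid: str = "percentiles 1-99 by 0.1"


@dataclass
class TemperatureLevels:
    """Cutoffs splitting observed temperatures into the four burden levels."""

    p1: float
    mmt: float
    p99: float

    def __post_init__(self) -> None:
        if not self.p1 < self.p99:
            raise ValueError("p1 must be below p99")

    def classify(self, temps: np.ndarray) -> np.ndarray:
        """0=extreme cold, 1=moderate cold, 2=moderate heat, 3=extreme heat."""
        temps = np.asarray(temps, dtype=float)
        out = np.full(temps.shape, 1, dtype=int)
        out[temps < self.p1] = 0
        out[temps >= self.mmt] = 2
        out[temps > self.p99] = 3
        return out


@dataclass
class AttributionResult:
    """Attributable numbers/fractions by component with 95% eCIs."""

    city_id: str
    stratum: str
    total_deaths: int
    an: dict[str, float]
    af: dict[str, float]
    an_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    af_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    mmt: MMTResult | None = None
    levels: TemperatureLevels | None = None


def find_mmt(
    coef: np.ndarray,
    exposure_spec: BasisSpec,
    percentile_table: np.ndarray,
    prange: tuple[float, float] = (1.0, 99.0),
    source: str = "blup",
) -> MMTResult:
    """Percentile minimizing the cumulative log-RR curve, ties toward 50."""
    percentile_table = np.asarray(percentile_table, dtype=float)
    if percentile_table.shape != PERCENTILE_GRID.shape:
        raise ValueError(
            f"percentile table must cover 0-100 by 0.1 ({PERCENTILE_GRID.size} values)"
        )
    sel = (PERCENTILE_GRID >= prange[0]) & (PERCENTILE_GRID <= prange[1])
    pct = PERCENTILE_GRID[sel]
    temps = percentile_table[sel]
    B = evaluate_basis(temps, exposure_spec, extrapolate=True).values
    log_rr = B @ np.asarray(coef, dtype=float)
    if not np.all(np.isfinite(log_rr)):
        raise ValueError("curve evaluates to non-finite values on the percentile grid")
    best = log_rr.min()
    ties = np.nonzero(log_rr <= best + 1e-12)[0]
    # break ties toward the median percentile
    pick = ties[np.argmin(np.abs(pct[ties] - 50.0))]
    return MMTResult(mmt=float(temps[pick]), mmp=float(pct[pick]), source=source)


def _centered_logrr(coef, exposure_spec, temps, mmt) -> np.ndarray:
    B = evaluate_basis(temps, exposure_spec, extrapolate=True).values
    Bm = evaluate_basis([mmt], exposure_spec, extrapolate=True).values
    return (B - Bm) @ np.asarray(coef, dtype=float)


def attribute_daily(
    coef: np.ndarray,
    exposure_spec: BasisSpec,
    temps: np.ndarray,
    deaths: np.ndarray,
    mmt: float,
    attributable_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Backward-attributed deaths per day: AN_t = deaths_t * (1 - exp(-b_t))
    with b_t the cumulative log-RR of day t's temperature relative to MMT.

    Days excluded by ``attributable_mask`` (e.g. incomplete lag history)
    return NaN.
    """
    temps = np.asarray(temps, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    lo, hi = np.nanmin(temps), np.nanmax(temps)
    if not lo <= mmt <= hi:
        raise ValueError(f"MMT {mmt} outside observed temperature range ({lo}, {hi})")
    b = _centered_logrr(coef, exposure_spec, temps, mmt)
    an = deaths * (1.0 - np.exp(-b))
    if attributable_mask is not None:
        an = np.where(attributable_mask, an, np.nan)
    return an


def decompose(
    an: np.ndarray,
    temps: np.ndarray,
    deaths: np.ndarray,
    levels: TemperatureLevels,
) -> tuple[dict[str, float], dict[str, float], int]:
    """Sum daily AN into the seven components; AF = 100 * AN / total deaths
    over the attributed (non-NaN) days."""
    an = np.asarray(an, dtype=float)
    ok = np.isfinite(an)
    cls = levels.classify(np.asarray(temps, dtype=float))
    total_deaths = int(np.asarray(deaths)[ok].sum())
    an_by: dict[str, float] = {}
    an_by["extreme_cold"] = float(an[ok & (cls == 0)].sum())
    an_by["moderate_cold"] = float(an[ok & (cls == 1)].sum())
    an_by["moderate_heat"] = float(an[ok & (cls == 2)].sum())
    an_by["extreme_heat"] = float(an[ok & (cls == 3)].sum())
    an_by["cold"] = an_by["extreme_cold"] + an_by["moderate_cold"]
    an_by["heat"] = an_by["moderate_heat"] + an_by["extreme_heat"]
    an_by["total"] = an_by["cold"] + an_by["heat"]
    af_by = {k: 100.0 * v / total_deaths for k, v in an_by.items()}
    return an_by, af_by, total_deaths


def _mvn_draws(coef, vcov, n_sim, rng) -> np.ndarray:
    coef = np.asarray(coef, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    asym = np.max(np.abs(vcov - vcov.T))
    if asym > 1e-8:
        raise ValueError(f"coefficient vcov asymmetric ({asym:.2e})")
    vcov = 0.5 * (vcov + vcov.T)
    w, v = np.linalg.eigh(vcov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("coefficient vcov is not positive semi-definite")
    root = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n_sim, coef.size))
    return coef + z @ root.T


def monte_carlo_eci(
    coef: np.ndarray,
    vcov: np.ndarray,
    exposure_spec: BasisSpec,
    temps: np.ndarray,
    deaths: np.ndarray,
    mmt: float,
    levels: TemperatureLevels,
    n_sim: int = 1000,
    rng: np.random.Generator | int = 0,
    attributable_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-draw component AN totals (each array length ``n_sim``).

    Coefficients are drawn from N(coef, vcov); MMT stays fixed at the point
    estimate so the estimand does not change across draws.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    temps = np.asarray(temps, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    ok = np.ones(temps.shape, bool) if attributable_mask is None else np.asarray(attributable_mask, bool)

    draws = _mvn_draws(coef, vcov, n_sim, rng)  # (n_sim, vx)
    B = evaluate_basis(temps[ok], exposure_spec, extrapolate=True).values
    Bm = evaluate_basis([mmt], exposure_spec, extrapolate=True).values
    b = (B - Bm) @ draws.T  # (n_days_ok, n_sim)
    an = deaths[ok, None] * (1.0 - np.exp(-b))
    cls = levels.classify(temps[ok])
    out: dict[str, np.ndarray] = {
        "extreme_cold": an[cls == 0].sum(axis=0),
        "moderate_cold": an[cls == 1].sum(axis=0),
        "moderate_heat": an[cls == 2].sum(axis=0),
        "extreme_heat": an[cls == 3].sum(axis=0),
    }
    out["cold"] = out["extreme_cold"] + out["moderate_cold"]
    out["heat"] = out["moderate_heat"] + out["extreme_heat"]
    out["total"] = out["cold"] + out["heat"]
    return out


def _finalize(
    city_id, stratum, an_by, af_by, total_deaths, draw_an, mmt_res, levels
) -> AttributionResult:
    an_ci, af_ci = {}, {}
    for comp in COMPONENTS:
        lo, hi = np.percentile(draw_an[comp], [2.5, 97.5])
        an_ci[comp] = (float(lo), float(hi))
        af_ci[comp] = (100.0 * lo / total_deaths, 100.0 * hi / total_deaths)
    return AttributionResult(
        city_id=city_id,
        stratum=stratum,
        total_deaths=total_deaths,
        an=an_by,
        af=af_by,
        an_ci=an_ci,
        af_ci=af_ci,
        draws=draw_an,
        mmt=mmt_res,
        levels=levels,
    )


def attribute_city(
    coef: np.ndarray,
    vcov: np.ndarray,
    exposure_spec: BasisSpec,
    temps: np.ndarray,
    deaths: np.ndarray,
    percentile_table: np.ndarray,
    attributable_mask: np.ndarray | None = None,
    n_sim: int = 1000,
    rng: np.random.Generator | int = 0,
    city_id: str = "",
    stratum: str = "total",
    source: str = "blup",
) -> AttributionResult:
    """Full attribution for one city: MMT search, point decomposition, eCIs."""
    mmt_res = find_mmt(coef, exposure_spec, percentile_table, source=source)
    percentile_table = np.asarray(percentile_table, dtype=float)
    levels = TemperatureLevels(
        p1=float(percentile_table[PERCENTILE_GRID == 1.0][0]),
        mmt=mmt_res.mmt,
        p99=float(percentile_table[PERCENTILE_GRID == 99.0][0]),
    )
    an = attribute_daily(coef, exposure_spec, temps, deaths, mmt_res.mmt, attributable_mask)
    an_by, af_by, total_deaths = decompose(an, temps, deaths, levels)
    draw_an = monte_carlo_eci(
        coef, vcov, exposure_spec, temps, deaths, mmt_res.mmt, levels,
        n_sim=n_sim, rng=rng, attributable_mask=attributable_mask,
    )
    return _finalize(city_id, stratum, an_by, af_by, total_deaths, draw_an, mmt_res, levels)


def aggregate_cities(results: list[AttributionResult]) -> AttributionResult:
    """Death-weighted pooling: sum ANs (point and per shared draw index)
    across cities, AF = 100 * sum(AN) / sum(deaths)."""
    if len(results) == 0:
        raise ValueError("need at least one city result")
    if len(results) == 1:
        return results[0]
    n_sims = {r.draws["total"].size for r in results if r.draws}
    if len(n_sims) > 1:
        raise ValueError(f"cities have mismatched n_sim: {sorted(n_sims)}")
    total_deaths = sum(r.total_deaths for r in results)
    an_by = {c: sum(r.an[c] for r in results) for c in COMPONENTS}
    af_by = {c: 100.0 * an_by[c] / total_deaths for c in COMPONENTS}
    draw_an = {c: np.sum([r.draws[c] for r in results], axis=0) for c in COMPONENTS}
    return _finalize(
        "pooled", results[0].stratum, an_by, af_by, total_deaths, draw_an, None, None
    )
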