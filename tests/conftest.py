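import numpy as np
import pytest

from tempmort.cityfit import ModelSpec, fit_city
from tempmort.synthetic import (
    BaselineMortalitySpec,
    CityClimateSpec,
    DailyCitySeries,
    default_risk_surface,
    null_risk_surface,
    reference_panel,
    simulate_city,
)

REF_SEED = 1234


@pytest.fixture(scope="session")
def ref_panel():
    """The packaged 4-city x 6-year reference panel (known U-shaped truth)."""
    return reference_panel(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_risk():
    return default_risk_surface()


@pytest.fixture(scope="session")
def small_panel():
    """Cheap 2-city x 3-year panel without strata, for fast pipeline tests."""
    return reference_panel(seed=99, n_cities=2, n_years=3, with_strata=False)


@pytest.fixture(scope="session")
def ref_fits(ref_panel):
    """First-stage fits of the reference panel 'total' stratum (shared)."""
    spec = ModelSpec()
    return [fit_city(s, "total", spec) for s in ref_panel]


@pytest.fixture(scope="session")
def null_city():
    """One 4-year city simulated under the flat (no temperature effect) surface."""
    climate = CityClimateSpec("null_city", n_years=4, annual_mean_temp=18.0)
    return simulate_city(
        climate,
        null_risk_surface(),
        BaselineMortalitySpec(mean_daily_deaths=50.0),
        seed=7,
    )


def toy_series(n_days=60, deaths=10, temps=None, city_id="toy") -> DailyCitySeries:
    """Hand-sized series for enumeration oracles."""
    import pandas as pd

    dates = pd.date_range("2020-01-01", periods=n_days, freq="D")
    if temps is None:
        rng = np.random.default_rng(123)
        temps = 15.0 + 10.0 * np.sin(np.linspace(0, 4 * np.pi, n_days)) + rng.normal(0, 2, n_days)
    temps = np.asarray(temps, dtype=float)
    d = np.full(n_days, deaths, dtype=np.int64) if np.isscalar(deaths) else np.asarray(deaths)
    t = np.arange(n_days)
    return DailyCitySeries(
        city_id=city_id,
        dates=dates,
        deaths={"total": d},
        temp_mean=temps,
        rh=70.0 + 5.0 * np.sin(0.1 * t),
        pm25=40.0 + 10.0 * np.cos(0.07 * t),
        o3=80.0 + 15.0 * np.sin(0.05 * t + 1.0),
    )
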