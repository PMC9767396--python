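import warnings

import numpy as np
import pytest

from hemoforecast import (
    ArimaOrder,
    MonthlySeries,
    PanelConfig,
    SarimaParams,
    simulate_group_panel,
    simulate_sarima_series,
)


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Statsmodels emits convergence/frequency chatter on tiny fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def ar1_series() -> MonthlySeries:
    """AR(1) with phi=0.7 around level 10, 400 months, fixed seed."""
    return simulate_sarima_series(
        SarimaParams(ar=(0.7,)), mean=10.0, n_months=400, seed=42
    )


@pytest.fixture(scope="session")
def seasonal_series() -> MonthlySeries:
    """Strongly seasonal monthly series (deterministic cycle + AR noise)."""
    noise = simulate_sarima_series(
        SarimaParams(ar=(0.3,)), innovation_sd=1.0, n_months=120, seed=7
    )
    cycle = 20.0 * np.sin(2 * np.pi * np.arange(120) / 12.0)
    return noise.with_values(100.0 + cycle + noise.values)


@pytest.fixture(scope="session")
def default_panel() -> dict[str, MonthlySeries]:
    return simulate_group_panel(PanelConfig(seed=123))


@pytest.fixture(scope="session")
def short_order() -> ArimaOrder:
    return ArimaOrder(1, 0, 0, 0, 0, 0, 12)
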