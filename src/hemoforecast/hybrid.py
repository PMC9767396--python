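"""Hybrid ARIMA + neural-network forecasting.

The series is treated as the sum of a linear component, a nonlinear
component and noise.  Stage 1 fits a seasonal ARIMA (the linear part);
stage 2 trains an MLP-autoregression ensemble on the ARIMA residuals (the
nonlinear part).  The hybrid forecast is the elementwise sum of the two
stage forecasts, and the final hybrid residual is the ARIMA residual minus
the ensemble's fitted value — white noise when both stages are adequate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import AnnArchitecture, AnnEnsemble, fit_ensemble
from .arima import ArimaOrder, SeasonalARIMAResults, fit_sarima
from .diagnostics import DiagnosticsReport, residual_diagnostics
from .series import MonthlySeries

__all__ = [
    "DEFAULT_RESIDUAL_ARCHITECTURE",
    "HybridFit",
    "HybridARIMAANN",
    "fit_hybrid",
    "forecast_hybrid",
]

#: One hidden layer of 5 neurons on 12 lagged residuals, 100-network
#: ensemble — the residual architecture used for every blood group.
DEFAULT_RESIDUAL_ARCHITECTURE = AnnArchitecture(hidden_layers=(5,), lags=12, reps=100)


@dataclass
class HybridFit:
    """Stage-1 ARIMA fit plus the ensemble trained on its residuals."""

    arima_fit: SeasonalARIMAResults
    residual_ensemble: AnnEnsemble

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.residual_ensemble.training_values, self.arima_fit.residuals
        ):
            raise ValueError(
                "residual ensemble was not trained on the ARIMA residuals"
            )

    @property
    def residuals(self) -> np.ndarray:
        """Final hybrid residuals: ARIMA residual minus the ensemble's
        in-sample fitted value (defined from row ``lags`` on)."""
        r = self.arima_fit.residuals
        fitted = self.residual_ensemble.fitted_values()
        return r[self.residual_ensemble.architecture.lags :] - fitted

    def forecast(self, h: int) -> np.ndarray:
        """Hybrid forecast = ARIMA forecast + residual-ensemble forecast."""
        if h < 1:
            raise ValueError("h must be >= 1")
        return self.arima_fit.forecast(h) + self.residual_ensemble.forecast(h)

    def diagnostics(self, alpha: float = 0.01, seed: int | None = 0) -> DiagnosticsReport:
        return residual_diagnostics(self.residuals, alpha=alpha, seed=seed)

    def summary(self) -> str:
        return "\n".join(
            [
                "Hybrid ARIMA + ANN",
                "-- stage 1 --",
                self.arima_fit.summary(),
                "-- stage 2 (on residuals) --",
                self.residual_ensemble.summary(),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "arima": self.arima_fit.to_dict(),
            "residual_ann": self.residual_ensemble.to_dict(),
        }


class HybridARIMAANN:
    """Model-style front end for the two-stage hybrid."""

    def __init__(
        self,
        endog,
        order: ArimaOrder,
        residual_architecture: AnnArchitecture = DEFAULT_RESIDUAL_ARCHITECTURE,
    ):
        self.endog = endog
        self.order = order
        self.residual_architecture = residual_architecture

    def fit(self, seed=None, tol: float = 1e-4, max_iter: int = 1000) -> HybridFit:
        arima_fit = fit_sarima(self.endog, self.order)
        ensemble = fit_ensemble(
            arima_fit.residuals,
            self.residual_architecture,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
        )
        return HybridFit(arima_fit=arima_fit, residual_ensemble=ensemble)


def fit_hybrid(
    series: MonthlySeries | np.ndarray,
    arima_order: ArimaOrder,
    residual_architecture: AnnArchitecture = DEFAULT_RESIDUAL_ARCHITECTURE,
    seed=None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> HybridFit:
    """Fit ARIMA, then an MLP ensemble on its residuals."""
    return HybridARIMAANN(series, arima_order, residual_architecture).fit(
        seed=seed, tol=tol, max_iter=max_iter
    )


def forecast_hybrid(fit: HybridFit, h: int) -> np.ndarray:
    """Elementwise sum of the two stage forecasts, h steps ahead."""
    return fit.forecast(h)
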