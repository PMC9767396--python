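"""Seasonal ARIMA estimation, information-criterion order search and
forecasting.

The model is the classical ARIMA(p,d,q)(P,D,Q)_s: after d nonseasonal and D
seasonal differences the series is a linear combination of its own past and
past innovations, at lag 1 and at the seasonal period.  Estimation is exact
Gaussian maximum likelihood via the state-space machinery of statsmodels;
this module owns the order grid, the AICc-based selection rule, the
information-criterion arithmetic and the residual-diagnostics surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .diagnostics import DiagnosticsReport, residual_diagnostics
from .series import MonthlySeries

__all__ = [
    "ArimaOrder",
    "SeasonalARIMA",
    "SeasonalARIMAResults",
    "fit_sarima",
    "information_criteria",
    "search_order",
    "forecast_sarima",
]


@dataclass(frozen=True)
class ArimaOrder:
    """Orders of an ARIMA(p,d,q)(P,D,Q)_period model."""

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    period: int = 12

    def __post_init__(self) -> None:
        for name in ("p", "d", "q", "P", "D", "Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d > 2:
            raise ValueError("d must be <= 2")
        if self.D > 1:
            raise ValueError("D must be <= 1")
        if self.period < 1:
            raise ValueError("period must be >= 1")

    @property
    def nonseasonal(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.period)

    @property
    def n_coeffs(self) -> int:
        return self.p + self.q + self.P + self.Q

    def __str__(self) -> str:
        return (
            f"({self.p},{self.d},{self.q})"
            f"({self.P},{self.D},{self.Q})_{self.period}"
        )


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """AIC, AICc and BIC from a log-likelihood with ``k`` free parameters on
    ``n`` observations.

    AIC = -2 loglik + 2k; AICc = AIC + 2k(k+1)/(n-k-1); BIC = -2 loglik +
    k ln n.  ``n`` must exceed ``k + 1`` for the AICc correction.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = -2.0 * loglik + k * np.log(n)
    return float(aic), float(aicc), float(bic)


class SeasonalARIMAResults:
    """Fitted seasonal ARIMA: orders, coefficients, innovation variance,
    likelihood, information criteria, residuals and forecasts."""

    def __init__(self, model: "SeasonalARIMA", sm_results, converged: bool):
        self.model = model
        self.order = model.order
        self._res = sm_results
        self.converged = bool(converged)
        self.params = dict(zip(sm_results.param_names, np.asarray(sm_results.params)))
        self.sigma2 = float(self.params.get("sigma2", np.nan))
        self.loglik = float(sm_results.llf)
        self.k_params = int(np.asarray(sm_results.params).size)
        self.n_obs = int(sm_results.nobs) - self._startup
        self.aic, self.aicc, self.bic = information_criteria(
            self.loglik, self.k_params, self.n_obs
        )

    @property
    def _startup(self) -> int:
        return self.order.d + self.order.D * self.order.period

    @property
    def residuals(self) -> np.ndarray:
        """One-step-ahead innovations, start-up values after differencing
        dropped."""
        return np.asarray(self._res.resid)[self._startup :]

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)[self._startup :]

    def forecast(self, h: int, conf_level: float | None = None):
        """Minimum-MSE forecasts ``h`` steps ahead; with ``conf_level`` also
        the prediction interval as an ``(h, 2)`` array."""
        if h < 1:
            raise ValueError("h must be >= 1")
        if conf_level is None:
            return np.asarray(self._res.forecast(steps=h))
        pred = self._res.get_forecast(steps=h)
        return (
            np.asarray(pred.predicted_mean),
            np.asarray(pred.conf_int(alpha=1.0 - conf_level)),
        )

    def diagnostics(self, alpha: float = 0.01, seed: int | None = 0) -> DiagnosticsReport:
        """Four-test residual battery (White NN, McLeod-Li, Box-Ljung,
        Shapiro-Wilk) at level ``alpha``."""
        return residual_diagnostics(self.residuals, alpha=alpha, seed=seed)

    def summary(self) -> str:
        lines = [
            f"Seasonal ARIMA {self.order}",
            f"  n_obs: {self.n_obs}   converged: {self.converged}",
            f"  loglik: {self.loglik:.3f}   sigma2: {self.sigma2:.6g}",
            f"  AIC: {self.aic:.2f}   AICc: {self.aicc:.2f}   BIC: {self.bic:.2f}",
            "  coefficients:",
        ]
        lines += [
            f"    {name:>12s}  {value: .4f}"
            for name, value in self.params.items()
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "order": str(self.order),
            "params": {k: float(v) for k, v in self.params.items()},
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "aicc": self.aicc,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


class SeasonalARIMA:
    """Seasonal ARIMA model for one monthly demand series.

    An intercept is included whenever no differencing is applied
    (d = D = 0); differenced models are fitted mean-free.  ``fit`` retries
    from a zero start vector when the first optimisation does not converge
    and flags the result instead of failing silently.
    """

    def __init__(self, endog, order: ArimaOrder, trend: str | None = None):
        values = endog.values if isinstance(endog, MonthlySeries) else np.asarray(endog, float)
        if trend is None:
            trend = "c" if (order.d == 0 and order.D == 0) else "n"
        n_params = order.n_coeffs + (1 if trend == "c" else 0) + 1
        if values.size < n_params + 2 * order.period:
            raise ValueError(
                f"series too short for {order}: need at least "
                f"{n_params + 2 * order.period} observations, got {values.size}"
            )
        self.endog = values
        self.order = order
        self.trend = trend

    def fit(self) -> SeasonalARIMAResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_model = SARIMAX(
                self.endog,
                order=self.order.nonseasonal,
                seasonal_order=self.order.seasonal,
                trend=self.trend,
            )
            res = sm_model.fit(disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged:
                start = np.zeros_like(np.asarray(res.params))
                start[-1] = max(np.var(self.endog), 1e-8)  # sigma2 start
                retry = sm_model.fit(start_params=start, disp=0)
                if bool(retry.mle_retvals.get("converged", True)):
                    res, converged = retry, True
                elif retry.llf > res.llf:
                    res = retry
        return SeasonalARIMAResults(self, res, converged)


def fit_sarima(series, order: ArimaOrder, trend: str | None = None) -> SeasonalARIMAResults:
    """Fit a seasonal ARIMA of the given order to a series."""
    return SeasonalARIMA(series, order, trend=trend).fit()


def forecast_sarima(fit: SeasonalARIMAResults, h: int) -> np.ndarray:
    """Point forecasts ``h`` steps ahead from a fitted seasonal ARIMA."""
    return fit.forecast(h)


def search_order(
    series,
    d: int = 0,
    D: int = 0,
    p_max: int = 3,
    q_max: int = 3,
    P_max: int = 2,
    Q_max: int = 2,
    period: int = 12,
    return_trace: bool = False,
):
    """Grid-search seasonal ARIMA orders, minimising AICc.

    ``d`` and ``D`` are fixed by the preprocessing decisions; the grid spans
    p,q in 0..p_max/q_max and P,Q in 0..P_max/Q_max.  Ties in AICc are broken
    by fewer parameters, then by lower BIC.  Candidates whose optimisation
    fails are skipped with a warning; if every candidate fails an error lists
    the failures.
    """
    trace: list[dict] = []
    best: SeasonalARIMAResults | None = None
    failures: list[str] = []
    for p, q, P, Q in product(
        range(p_max + 1), range(q_max + 1), range(P_max + 1), range(Q_max + 1)
    ):
        order = ArimaOrder(p, d, q, P, D, Q, period)
        try:
            fit = fit_sarima(series, order)
        except Exception as exc:  # noqa: BLE001 - candidate isolation
            failures.append(f"{order}: {exc}")
            warnings.warn(f"order {order} failed: {exc}", stacklevel=2)
            continue
        trace.append(
            {"order": str(order), "aicc": fit.aicc, "aic": fit.aic, "bic": fit.bic,
             "k": fit.k_params, "converged": fit.converged}
        )
        if best is None or (fit.aicc, fit.k_params, fit.bic) < (
            best.aicc, best.k_params, best.bic
        ):
            best = fit
    if best is None:
        raise RuntimeError(
            "every candidate order failed to fit:\n" + "\n".join(failures)
        )
    if return_trace:
        return best, trace
    return best
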