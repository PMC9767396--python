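"""Residual diagnostic battery.

Four tests are applied to model residuals: the White neural-network test for
neglected nonlinearity, the McLeod-Li test for conditional
heteroscedasticity, the Box-Ljung portmanteau test for residual
autocorrelation, and the Shapiro-Wilk test for normality.  Residuals pass
when every p-value exceeds the chosen level (0.01 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import shapiro_wilk
from .series import MonthlySeries

__all__ = [
    "ljung_box",
    "mcleod_li",
    "white_nn_test",
    "DiagnosticsReport",
    "residual_diagnostics",
]


def _values(x) -> np.ndarray:
    if isinstance(x, MonthlySeries):
        return x.values
    return np.asarray(x, dtype=float)


def _sample_acf(x: np.ndarray, nlags: int) -> np.ndarray:
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom <= 0:
        raise ValueError("degenerate (constant) input")
    return np.array(
        [np.dot(xc[j:], xc[: x.size - j]) / denom for j in range(1, nlags + 1)]
    )


def ljung_box(residuals, lag: int = 1, fitted_params: int = 0) -> tuple[float, int, float]:
    """Box-Ljung portmanteau test of residual autocorrelation.

    Q = n(n+2) * sum_{j=1..lag} r_j^2 / (n-j), referred to a chi-square with
    ``lag - fitted_params`` degrees of freedom.  Returns ``(Q, df, p)``.
    """
    x = _values(residuals)
    if lag <= 0:
        raise ValueError("lag must be >= 1")
    n = x.size
    if n <= lag:
        raise ValueError("need more observations than lags")
    r = _sample_acf(x, lag)
    q = n * (n + 2.0) * float(np.sum(r**2 / (n - np.arange(1, lag + 1))))
    df = lag - fitted_params
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return q, df, float(stats.chi2.sf(q, df))


def mcleod_li(residuals, lag: int = 2) -> tuple[float, int, float]:
    """McLeod-Li test for conditional heteroscedasticity: the Box-Ljung
    statistic computed on the squared residuals."""
    x = _values(residuals)
    return ljung_box(x**2, lag=lag)


def white_nn_test(
    x,
    lags: int = 1,
    q_hidden: int = 2,
    n_units: int = 10,
    seed: int | None = 0,
) -> tuple[float, int, float]:
    """White's neural-network test for neglected nonlinearity.

    A linear autoregression on ``lags`` lagged values is augmented with the
    top ``q_hidden`` principal components of ``n_units`` logistic hidden
    units with random directions; the statistic is m * R^2 of the auxiliary
    regression of the linear residuals on lags and components (m = usable
    rows), chi-square with df = ``q_hidden`` under linearity.  Deterministic
    given ``seed``.  Returns ``(X2, df, p)``.
    """
    y = _values(x)
    if y.size < 30:
        raise ValueError("need at least 30 observations")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) input")
    m = y.size - lags
    X = np.column_stack([y[lags - j - 1 : lags - j - 1 + m] for j in range(lags)])
    target = y[lags:]

    # standardized design for the hidden units, so activations are not saturated
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    gamma = rng.uniform(-2.0, 2.0, size=(lags + 1, n_units))
    act = 1.0 / (1.0 + np.exp(-(gamma[0] + Xs @ gamma[1:])))

    # principal components of the centred activations
    A = act - act.mean(axis=0)
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    comps = A @ vt[:q_hidden].T

    Z0 = np.column_stack([np.ones(m), X])
    u = target - Z0 @ np.linalg.lstsq(Z0, target, rcond=None)[0]
    Z1 = np.column_stack([Z0, comps])
    resid_aux = u - Z1 @ np.linalg.lstsq(Z1, u, rcond=None)[0]
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("degenerate linear fit (zero residual variance)")
    r2 = 1.0 - float(np.sum(resid_aux**2)) / ss_tot
    stat = m * r2
    return stat, q_hidden, float(stats.chi2.sf(stat, q_hidden))


@dataclass(frozen=True)
class DiagnosticsReport:
    """Results of the four-test residual battery at level ``alpha``.

    Each entry is a ``(statistic, df, p)`` triple except Shapiro-Wilk, whose
    df slot is None.  A test passes when p > alpha.
    """

    white_nn: tuple[float, int, float]
    mcleod_li: tuple[float, int, float]
    ljung_box: tuple[float, int, float]
    shapiro_wilk: tuple[float, None, float]
    alpha: float = 0.01

    @property
    def passes(self) -> dict[str, bool]:
        return {
            "white_nn": self.white_nn[2] > self.alpha,
            "mcleod_li": self.mcleod_li[2] > self.alpha,
            "ljung_box": self.ljung_box[2] > self.alpha,
            "shapiro_wilk": self.shapiro_wilk[2] > self.alpha,
        }

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "white_nn": {"stat": self.white_nn[0], "df": self.white_nn[1], "p": self.white_nn[2]},
            "mcleod_li": {"stat": self.mcleod_li[0], "df": self.mcleod_li[1], "p": self.mcleod_li[2]},
            "ljung_box": {"stat": self.ljung_box[0], "df": self.ljung_box[1], "p": self.ljung_box[2]},
            "shapiro_wilk": {"W": self.shapiro_wilk[0], "p": self.shapiro_wilk[2]},
            "passes": self.passes,
        }


def residual_diagnostics(
    residuals,
    alpha: float = 0.01,
    lb_lag: int = 1,
    ml_lag: int = 2,
    seed: int | None = 0,
) -> DiagnosticsReport:
    """Run the four-test battery on a residual series.

    Shapiro-Wilk is applied to standardized residuals; the Box-Ljung lag
    defaults to 1 and the McLeod-Li lag to 2.
    """
    r = _values(residuals)
    if r.size < 30:
        raise ValueError("need at least 30 residuals")
    std = r.std()
    z = (r - r.mean()) / (std if std > 0 else 1.0)
    w, p_sw = shapiro_wilk(z)
    return DiagnosticsReport(
        white_nn=white_nn_test(r, seed=seed),
        mcleod_li=mcleod_li(r, lag=ml_lag),
        ljung_box=ljung_box(r, lag=lb_lag),
        shapiro_wilk=(w, None, p_sw),
        alpha=alpha,
    )
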