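"""Normality assessment, variance-stabilising transforms, classical seasonal
decomposition and differencing-order decisions.

Every series is screened with the Shapiro-Wilk test before modelling; series
that fail are Box-Cox transformed with the power chosen by profile-likelihood
maximisation (a power within 0.01 of zero collapses to a plain log).  The
seasonal differencing order D is decided by the seasonal-strength statistic
of a classical additive decomposition, the nonseasonal order d by repeated
KPSS stationarity testing of successive differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.seasonal import seasonal_decompose
from statsmodels.tsa.stattools import kpss

from .series import MonthlySeries

__all__ = [
    "TransformSpec",
    "Decomposition",
    "shapiro_wilk",
    "select_transform",
    "apply_transform",
    "invert_transform",
    "classical_decompose",
    "seasonal_strength",
    "seasonal_difference_order",
    "nonseasonal_difference_order",
]


def _values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class TransformSpec:
    """A normalising transform: ``none``, ``log`` or ``box-cox``.

    ``offset`` is added before transforming (and removed on inversion) so
    that series touching zero remain in-domain.  ``lmbda`` is the Box-Cox
    power; it is ignored for the other kinds.
    """

    kind: str = "none"
    lmbda: float | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "log", "box-cox"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "box-cox" and self.lmbda is None:
            raise ValueError("box-cox transform requires lmbda")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; returns ``(W, p)``.

    Requires 3 <= n <= 5000 finite values.
    """
    x = _values(values)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


_LAMBDA_GRID = np.round(np.arange(-1.0, 2.0 + 1e-9, 0.01), 10)


def select_transform(series, alpha: float = 0.05, offset: float = 0.0) -> TransformSpec:
    """Choose a normalising transform for a demand series.

    If the raw series already passes Shapiro-Wilk at ``alpha`` the identity
    transform is returned.  Otherwise the Box-Cox power is picked by
    profile-likelihood maximisation over a grid on [-1, 2] (step 0.01); a
    maximiser within 0.01 of zero collapses to the log transform.
    """
    x = _values(series)
    if np.any(x + offset <= 0):
        raise ValueError(
            "series must be strictly positive after offset; "
            "set a larger `offset` to shift nonpositive values into domain"
        )
    _, p = shapiro_wilk(x)
    if p >= alpha:
        return TransformSpec(kind="none", offset=0.0)
    shifted = x + offset
    llf = np.array([stats.boxcox_llf(lm, shifted) for lm in _LAMBDA_GRID])
    lmbda = float(_LAMBDA_GRID[int(np.argmax(llf))])
    if abs(lmbda) < 0.01 + 1e-12:
        return TransformSpec(kind="log", offset=offset)
    return TransformSpec(kind="box-cox", lmbda=lmbda, offset=offset)


def apply_transform(series, spec: TransformSpec):
    """Apply ``spec`` to a series (MonthlySeries in, MonthlySeries out)."""
    x = _values(series) + spec.offset
    if spec.kind == "none":
        out = _values(series)
    elif spec.kind == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        out = np.log(x)
    else:
        if np.any(x <= 0):
            raise ValueError("box-cox transform requires strictly positive values")
        # (x^l - 1)/l is numerically unstable for tiny |l|; it IS log there
        lm = spec.lmbda if abs(spec.lmbda) >= 1e-6 else 0.0
        out = stats.boxcox(x, lmbda=lm)
    if isinstance(series, MonthlySeries):
        return series.with_values(out)
    return out


def invert_transform(series, spec: TransformSpec):
    """Inverse of :func:`apply_transform`; round-trips within 1e-8."""
    z = _values(series)
    if spec.kind == "none":
        out = z - 0.0
    elif spec.kind == "log":
        out = np.exp(z) - spec.offset
    else:
        lm = spec.lmbda
        if abs(lm) < 1e-6:
            out = np.exp(z) - spec.offset
        else:
            base = lm * z + 1.0
            if np.any(base <= 0):
                raise ValueError("values outside the image of the box-cox transform")
            out = base ** (1.0 / lm) - spec.offset
    if isinstance(series, MonthlySeries):
        return series.with_values(out)
    return out


@dataclass(frozen=True)
class Decomposition:
    """Additive classical decomposition: observed = trend + seasonal + remainder.

    ``trend`` is NaN at the edges where the centred moving average is
    undefined; ``seasonal`` repeats with the stated period and sums to ~0
    over one cycle.
    """

    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    period: int

    @property
    def seasonal_effects(self) -> np.ndarray:
        """The period distinct month effects, first cycle."""
        return self.seasonal[: self.period]


def classical_decompose(series, period: int = 12) -> Decomposition:
    """Classical additive decomposition (centred moving-average trend,
    month-wise mean seasonal effects re-centred to sum 0)."""
    x = _values(series)
    if x.size < 2 * period:
        raise ValueError("decomposition requires at least two full periods")
    res = seasonal_decompose(x, model="additive", period=period, two_sided=True)
    return Decomposition(
        trend=np.asarray(res.trend, dtype=float),
        seasonal=np.asarray(res.seasonal, dtype=float),
        remainder=np.asarray(res.resid, dtype=float),
        period=period,
    )


def seasonal_strength(series, period: int = 12) -> float:
    """F_s = max(0, 1 - Var(remainder) / Var(seasonal + remainder)).

    Defined as 0 for (near-)constant series where both variances vanish.
    """
    dec = classical_decompose(series, period=period)
    ok = np.isfinite(dec.remainder)
    rem = dec.remainder[ok]
    joint = dec.seasonal[ok] + rem
    denom = float(np.var(joint))
    if denom <= 1e-12:
        return 0.0
    return max(0.0, 1.0 - float(np.var(rem)) / denom)


def seasonal_difference_order(series, period: int = 12, threshold: float = 0.64) -> int:
    """Seasonal differencing order D in {0, 1}: 1 when the seasonal strength
    of the series exceeds ``threshold``."""
    x = _values(series)
    if x.size < 3 * period:
        raise ValueError("need at least three full periods")
    return int(seasonal_strength(x, period=period) > threshold)


def nonseasonal_difference_order(series, max_d: int = 2, alpha: float = 0.05) -> int:
    """Smallest d <= max_d at which a KPSS level-stationarity test no longer
    rejects at ``alpha``."""
    x = _values(series)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    for d in range(max_d + 1):
        z = np.diff(x, n=d) if d else x
        if np.allclose(z, z[0]):
            return d  # constant: trivially stationary
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p, *_ = kpss(z, regression="c", nlags="auto")
        if p > alpha:
            return d
    return max_d
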