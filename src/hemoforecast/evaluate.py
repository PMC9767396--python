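"""Train/test protocol, error metrics and the three-model comparison.

The validation protocol is a single fixed split: the final 12 months are
held out, everything before is training.  Each group's training block is
(optionally) normalised, the differencing orders are decided, and seasonal
ARIMA, the MLP-autoregression ensemble and the hybrid are fitted and asked
for the held-out horizon.  MAE and MSE are reported on the original demand
scale and, when a transform was applied, additionally on the transformed
(modelling) scale; ANN/ARIMA and Hybrid/ARIMA error ratios summarise the
comparison per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import AnnArchitecture, fit_ensemble
from .arima import ArimaOrder, fit_sarima, search_order
from .hybrid import fit_hybrid
from .preprocess import (
    TransformSpec,
    apply_transform,
    invert_transform,
    nonseasonal_difference_order,
    seasonal_difference_order,
    select_transform,
)
from .series import MonthlySeries

__all__ = [
    "CompareConfig",
    "ComparisonTable",
    "train_test_split",
    "mae",
    "mse",
    "error_ratios",
    "run_comparison",
    "overall_demand_forecast",
]

logger = logging.getLogger(__name__)

MODELS = ("arima", "ann", "hybrid")


def train_test_split(series, test_horizon: int = 12):
    """Split into the first n-h months (training) and the final h months
    (testing); contiguous, no shuffling."""
    if test_horizon <= 0:
        raise ValueError("test_horizon must be >= 1")
    if isinstance(series, MonthlySeries):
        n, period = len(series), series.period
    else:
        series = np.asarray(series, float)
        n, period = series.size, 12
    if test_horizon >= n:
        raise ValueError("test horizon must be shorter than the series")
    if n - test_horizon < 2 * period:
        raise ValueError("training block must cover at least two full periods")
    if isinstance(series, MonthlySeries):
        return series.slice(0, n - test_horizon), series.slice(n - test_horizon)
    return series[: n - test_horizon], series[n - test_horizon :]


def _paired(actual, predicted):
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if a.size != p.size or a.size == 0:
        raise ValueError("actual and predicted must have equal, nonzero length")
    return a, p


def mae(actual, predicted) -> float:
    """Mean absolute error."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def mse(actual, predicted) -> float:
    """Mean squared error."""
    a, p = _paired(actual, predicted)
    return float(np.mean((a - p) ** 2))


_RATIO_SOURCES = {
    "mae_ratio_ann_arima": ("mae_ann", "mae_arima"),
    "mae_ratio_hybrid_arima": ("mae_hybrid", "mae_arima"),
    "mse_ratio_ann_arima": ("mse_ann", "mse_arima"),
    "mse_ratio_hybrid_arima": ("mse_hybrid", "mse_arima"),
}


def error_ratios(errors: pd.DataFrame) -> pd.DataFrame:
    """Append the four ANN/ARIMA and Hybrid/ARIMA ratio columns to a table
    of per-group MAE/MSE cells.

    Full precision is retained; display rounding to 2 decimals is left to
    the formatter.  A zero ARIMA error makes the ratio undefined (NaN) and
    is flagged in the ``ratio_undefined`` column.
    """
    needed = {f"{m}_{mod}" for m in ("mae", "mse") for mod in MODELS}
    missing = needed - set(errors.columns)
    if missing:
        raise ValueError(f"missing error columns: {sorted(missing)}")
    out = errors.copy()
    undefined = pd.Series(False, index=out.index)
    for col, (num, den) in _RATIO_SOURCES.items():
        denom = out[den].to_numpy(float)
        bad = denom == 0
        undefined |= bad
        with np.errstate(divide="ignore", invalid="ignore"):
            out[col] = np.where(bad, np.nan, out[num].to_numpy(float) / denom)
    out["ratio_undefined"] = undefined
    return out


@dataclass
class ComparisonTable:
    """Per-group MAE/MSE of the three models plus ratio columns.

    ``table`` carries original-scale errors (the ratio columns are computed
    from it); ``table_transformed`` the same cells on the modelling scale
    for groups that were transformed.  ``errors`` records groups whose fit
    failed.
    """

    table: pd.DataFrame
    table_transformed: pd.DataFrame | None = None
    transforms: dict[str, TransformSpec] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def winners(self) -> pd.Series:
        """Winning model per group by test MAE (original scale)."""
        cols = [f"mae_{m}" for m in MODELS]
        idx = self.table[cols].to_numpy(float).argmin(axis=1)
        return pd.Series([MODELS[i] for i in idx], index=self.table.index, name="winner")

    def formatted(self) -> pd.DataFrame:
        """Display table: errors in 3-significant-digit scientific notation,
        ratios rounded to 2 decimals."""
        out = pd.DataFrame(index=self.table.index)
        for col in self.table.columns:
            if col.startswith(("mae_ratio", "mse_ratio")):
                out[col] = self.table[col].map(lambda v: f"{v:.2f}")
            elif col.startswith(("mae_", "mse_")):
                out[col] = self.table[col].map(lambda v: f"{v:.2E}")
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="group")

    def to_dict(self) -> dict:
        return {
            "errors_original_scale": self.table.to_dict(orient="index"),
            "errors_transformed_scale": (
                self.table_transformed.to_dict(orient="index")
                if self.table_transformed is not None
                else None
            ),
            "transforms": {
                g: {"kind": t.kind, "lmbda": t.lmbda, "offset": t.offset}
                for g, t in self.transforms.items()
            },
            "winners": self.winners.to_dict(),
            "failed_groups": self.errors,
        }


@dataclass(frozen=True)
class CompareConfig:
    """Knobs of the three-way comparison.

    ``transform='auto'`` runs the Shapiro-Wilk/Box-Cox selection per group;
    ``'none'`` models raw demand.  The ARIMA order is grid-searched within
    the given bounds unless ``arima_orders`` pins an order per group.  The
    ANN architecture is fixed per config (greedy search is available through
    :class:`~hemoforecast.ann.MLPAutoregression` when wanted).
    """

    test_horizon: int = 12
    transform: str = "auto"
    arima_orders: dict[str, ArimaOrder] | None = None
    p_max: int = 3
    q_max: int = 3
    P_max: int = 2
    Q_max: int = 2
    ann_architecture: AnnArchitecture = AnnArchitecture((5,), lags=12, reps=100)
    hybrid_architecture: AnnArchitecture = AnnArchitecture((5,), lags=12, reps=100)
    period: int = 12


def _prepare(train: MonthlySeries, cfg: CompareConfig) -> tuple[MonthlySeries, TransformSpec]:
    if cfg.transform == "none":
        return train, TransformSpec(kind="none")
    offset = 0.0
    if train.values.min() <= 0:
        offset = 1.0 - float(train.values.min())
    spec = select_transform(train, offset=offset)
    return apply_transform(train, spec), spec


def _fit_three(
    train_t: MonthlySeries,
    cfg: CompareConfig,
    group: str,
    seed: np.random.SeedSequence,
):
    if cfg.arima_orders and group in cfg.arima_orders:
        arima_fit = fit_sarima(train_t, cfg.arima_orders[group])
    else:
        d = nonseasonal_difference_order(train_t)
        D = seasonal_difference_order(train_t, period=cfg.period)
        arima_fit = search_order(
            train_t, d=d, D=D,
            p_max=cfg.p_max, q_max=cfg.q_max, P_max=cfg.P_max, Q_max=cfg.Q_max,
            period=cfg.period,
        )
    ann_seed, hyb_seed = seed.spawn(2)
    ensemble = fit_ensemble(train_t, cfg.ann_architecture, seed=ann_seed)
    hybrid = fit_hybrid(
        train_t, arima_fit.order, cfg.hybrid_architecture, seed=hyb_seed
    )
    return arima_fit, ensemble, hybrid


def run_comparison(
    panel: dict[str, MonthlySeries],
    config: CompareConfig | None = None,
    seed: int = 0,
) -> tuple[ComparisonTable, dict[str, pd.DataFrame]]:
    """Fit all three models per group and compare them on the held-out block.

    Returns the comparison table and, per group, a tidy frame of the test
    months with columns ``month, actual, arima, ann, hybrid`` (original
    scale).  Per-group failures are isolated: the run continues and the
    failure is recorded on the table.
    """
    cfg = config or CompareConfig()
    master = np.random.SeedSequence(seed)
    group_seeds = dict(zip(panel.keys(), master.spawn(len(panel))))
    rows, rows_t, transforms, failures = {}, {}, {}, {}
    forecasts: dict[str, pd.DataFrame] = {}

    for group, series in panel.items():
        try:
            train, test = train_test_split(series, cfg.test_horizon)
            train_t, spec = _prepare(train, cfg)
            transforms[group] = spec
            arima_fit, ensemble, hybrid = _fit_three(
                train_t, cfg, group, group_seeds[group]
            )
            h = cfg.test_horizon
            preds_t = {
                "arima": arima_fit.forecast(h),
                "ann": ensemble.forecast(h),
                "hybrid": hybrid.forecast(h),
            }
            preds = {m: invert_transform(v, spec) for m, v in preds_t.items()}
            actual = test.values
            rows[group] = {
                **{f"mae_{m}": mae(actual, preds[m]) for m in MODELS},
                **{f"mse_{m}": mse(actual, preds[m]) for m in MODELS},
            }
            if spec.kind != "none":
                actual_t = apply_transform(test, spec).values
                rows_t[group] = {
                    **{f"mae_{m}": mae(actual_t, preds_t[m]) for m in MODELS},
                    **{f"mse_{m}": mse(actual_t, preds_t[m]) for m in MODELS},
                }
            forecasts[group] = pd.DataFrame(
                {
                    "month": test.months,
                    "group": group,
                    "actual": actual,
                    **{m: preds[m] for m in MODELS},
                }
            )
            logger.info(
                "group %s: arima %s, ann layers %s; winner by MAE: %s",
                group, arima_fit.order, cfg.ann_architecture.hidden_layers,
                min(MODELS, key=lambda m: rows[group][f"mae_{m}"]),
            )
        except Exception as exc:  # noqa: BLE001 - per-group isolation
            failures[group] = str(exc)
            logger.error("group %s failed: %s", group, exc)

    table = error_ratios(pd.DataFrame.from_dict(rows, orient="index"))
    table_t = (
        error_ratios(pd.DataFrame.from_dict(rows_t, orient="index")) if rows_t else None
    )
    return (
        ComparisonTable(
            table=table,
            table_transformed=table_t,
            transforms=transforms,
            errors=failures,
        ),
        forecasts,
    )


def _ols_slope(y: np.ndarray) -> float:
    t = np.arange(y.size, dtype=float)
    return float(np.polyfit(t, y, 1)[0])


def overall_demand_forecast(
    panel: dict[str, MonthlySeries],
    config: CompareConfig | None = None,
    seed: int = 0,
    horizon: int = 12,
) -> dict:
    """Forecast the summed demand of all groups with each of the three
    models (fitted on the total itself, not by summing per-group forecasts).

    Returns the total series, per-model forecasts and the sign-carrying OLS
    slope of each forecast path.
    """
    cfg = config or CompareConfig()
    series_list = list(panel.values())
    first = series_list[0]
    for s in series_list[1:]:
        if len(s) != len(first) or s.start != first.start:
            raise ValueError("panel groups are not month-aligned")
    total = MonthlySeries(
        label="total",
        values=np.sum([s.values for s in series_list], axis=0),
        start=first.start,
        period=first.period,
    )
    total_t, spec = _prepare(total, cfg)
    arima_fit, ensemble, hybrid = _fit_three(
        total_t, cfg, "total", np.random.SeedSequence(seed)
    )
    preds = {
        "arima": invert_transform(arima_fit.forecast(horizon), spec),
        "ann": invert_transform(ensemble.forecast(horizon), spec),
        "hybrid": invert_transform(hybrid.forecast(horizon), spec),
    }
    return {
        "total": total,
        "transform": spec,
        "forecasts": preds,
        "trend_slopes": {m: _ols_slope(v) for m, v in preds.items()},
    }
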