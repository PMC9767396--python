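"""Panel CSV readers/writers and run configuration.

Panels travel as tidy UTF-8 CSV with header ``month,group,demand``; months
are ``YYYY-MM`` labels and each group's months must be consecutive with no
gaps (no imputation is attempted).  Run configuration is a flat YAML/JSON
mapping validated against a fixed schema before any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import MonthlySeries, month_range

__all__ = ["read_panel", "write_panel", "RunConfig"]


def write_panel(panel: dict[str, MonthlySeries], path) -> None:
    """Write a panel as tidy CSV (``month,group,demand``)."""
    frames = [s.to_frame() for s in panel.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_panel(path) -> dict[str, MonthlySeries]:
    """Read a tidy panel CSV back into per-group series.

    Months must parse as ``YYYY-MM`` and be consecutive within each group;
    duplicate (month, group) pairs, gaps and non-numeric demand are rejected
    with the offending rows named.
    """
    df = pd.read_csv(path, dtype={"month": str, "group": str})
    required = {"month", "group", "demand"}
    if missing := required - set(df.columns):
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    demand = pd.to_numeric(df["demand"], errors="coerce")
    if demand.isna().any():
        bad = (df.index[demand.isna()] + 2).tolist()  # header is line 1
        raise ValueError(f"non-numeric demand at CSV line(s) {bad}")
    try:
        periods = pd.PeriodIndex(df["month"], freq="M")
    except Exception as exc:
        raise ValueError(f"months must be YYYY-MM: {exc}") from None
    df = df.assign(_period=periods, demand=demand)

    dup = df.duplicated(subset=["month", "group"], keep=False)
    if dup.any():
        bad = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (month, group) at CSV line(s) {bad}")

    panel: dict[str, MonthlySeries] = {}
    for group, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("_period")
        expected = pd.period_range(sub["_period"].iloc[0], periods=len(sub), freq="M")
        if not (sub["_period"].to_numpy() == expected.to_numpy()).all():
            have = set(sub["_period"])
            gaps = [str(p) for p in expected if p not in have]
            raise ValueError(f"group {group!r} has missing months: {gaps}")
        panel[str(group)] = MonthlySeries(
            label=str(group),
            values=sub["demand"].to_numpy(float),
            start=str(sub["_period"].iloc[0]),
        )
    return panel


_KNOWN_KEYS = {
    "input",
    "n_months",
    "seed",
    "start",
    "transform",
    "test_horizon",
    "p_max",
    "q_max",
    "P_max",
    "Q_max",
    "ann_hidden_layers",
    "ann_lags",
    "ann_reps",
    "hybrid_hidden_layers",
    "hybrid_lags",
    "hybrid_reps",
    "output_dir",
    "log_level",
}


@dataclass
class RunConfig:
    """Fully serialisable configuration of one end-to-end run.

    ``input`` is a panel CSV path, or None to simulate the default
    eight-group panel (``n_months`` months from ``seed``).  The remaining
    fields mirror :class:`~hemoforecast.evaluate.CompareConfig` plus output
    and logging choices; a persisted config reconstructs its run exactly.
    """

    input: str | None = None
    n_months: int = 96
    seed: int = 0
    start: str = "2012-01"
    transform: str = "auto"
    test_horizon: int = 12
    p_max: int = 3
    q_max: int = 3
    P_max: int = 2
    Q_max: int = 2
    ann_hidden_layers: tuple[int, ...] = (5,)
    ann_lags: int = 12
    ann_reps: int = 100
    hybrid_hidden_layers: tuple[int, ...] = (5,)
    hybrid_lags: int = 12
    hybrid_reps: int = 100
    output_dir: str = "hemoforecast_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.transform not in ("auto", "none"):
            raise ValueError("transform must be 'auto' or 'none'")
        if self.test_horizon < 1:
            raise ValueError("test_horizon must be >= 1")
        self.ann_hidden_layers = tuple(int(k) for k in self.ann_hidden_layers)
        self.hybrid_hidden_layers = tuple(int(k) for k in self.hybrid_hidden_layers)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ann_hidden_layers"] = list(self.ann_hidden_layers)
        d["hybrid_hidden_layers"] = list(self.hybrid_hidden_layers)
        return d

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def compare_config(self):
        from .ann import AnnArchitecture
        from .evaluate import CompareConfig

        return CompareConfig(
            test_horizon=self.test_horizon,
            transform=self.transform,
            p_max=self.p_max,
            q_max=self.q_max,
            P_max=self.P_max,
            Q_max=self.Q_max,
            ann_architecture=AnnArchitecture(
                self.ann_hidden_layers, self.ann_lags, self.ann_reps
            ),
            hybrid_architecture=AnnArchitecture(
                self.hybrid_hidden_layers, self.hybrid_lags, self.hybrid_reps
            ),
        )

    def load_panel(self) -> dict[str, MonthlySeries]:
        from .synthetic import PanelConfig, simulate_group_panel

        if self.input is not None:
            return read_panel(self.input)
        return simulate_group_panel(
            PanelConfig(n_months=self.n_months, seed=self.seed, start=self.start)
        )
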