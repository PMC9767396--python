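"""Monthly demand series container.

A :class:`MonthlySeries` is the currency of the whole pipeline: an ordered
vector of monthly demand values for one blood group, together with the label,
the first month (``YYYY-MM``) and the seasonal period (12 for monthly data).
Months are treated as ordered labels, not timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["MonthlySeries", "month_range"]


def month_range(start: str, n: int) -> list[str]:
    """Return ``n`` consecutive ``YYYY-MM`` labels starting at ``start``."""
    periods = pd.period_range(start=start, periods=n, freq="M")
    return [str(p) for p in periods]


@dataclass(frozen=True)
class MonthlySeries:
    """One group's ordered monthly demand values.

    Parameters
    ----------
    label : str
        Group label, e.g. ``"A+"``.
    values : ndarray
        Demand values, one per month, in temporal order.
    start : str
        First month as ``YYYY-MM``.
    period : int
        Seasonal period (12 for monthly data).
    """

    label: str
    values: np.ndarray
    start: str = "2012-01"
    period: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).copy()
        )
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.period < 1:
            raise ValueError("period must be >= 1")

    def __len__(self) -> int:
        return self.values.size

    @property
    def months(self) -> list[str]:
        return month_range(self.start, len(self))

    def with_values(self, values: np.ndarray) -> "MonthlySeries":
        """Copy of this series with ``values`` replaced (metadata kept)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def slice(self, begin: int, end: int | None = None) -> "MonthlySeries":
        """Contiguous sub-series; ``start`` is advanced accordingly."""
        months = self.months
        end = len(self) if end is None else end
        return MonthlySeries(
            label=self.label,
            values=self.values[begin:end],
            start=months[begin],
            period=self.period,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns ``month, group, demand``."""
        return pd.DataFrame(
            {"month": self.months, "group": self.label, "demand": self.values}
        )
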