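"""Fixed-interval time series with an explicit missing-value mask.

``RegularSeries`` is the common currency of the pipeline: every processing
stage consumes and produces series on a fixed time grid.  The timestamp of
each sample refers to the END of the interval it summarizes (a value stamped
12:00 at daily resolution covers the preceding day).  Missing values are
encoded as NaN and exposed through :attr:`RegularSeries.mask`; aggregation and
analysis code must never silently turn a missing value into a zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Supported fixed intervals (name -> pandas Timedelta).
INTERVALS = {
    "5min": pd.Timedelta(minutes=5),
    "10min": pd.Timedelta(minutes=10),
    "1h": pd.Timedelta(hours=1),
    "1d": pd.Timedelta(days=1),
    "1w": pd.Timedelta(weeks=1),
}


def as_interval(interval: str | pd.Timedelta) -> pd.Timedelta:
    """Normalize an interval given by name ('10min', '1h', ...) or Timedelta."""
    if isinstance(interval, pd.Timedelta):
        return interval
    key = str(interval).lower().replace(" ", "")
    aliases = {"1hr": "1h", "1hour": "1h", "1day": "1d", "1week": "1w", "7d": "1w"}
    key = aliases.get(key, key)
    if key in INTERVALS:
        return INTERVALS[key]
    return pd.Timedelta(key)


@dataclass
class RegularSeries:
    """A real-valued sequence on a fixed time grid.

    Parameters
    ----------
    start : pd.Timestamp
        End-of-interval timestamp of the first sample.
    interval : pd.Timedelta
        Fixed spacing between samples.
    values : np.ndarray
        Float array; NaN marks missing samples.
    units : str
        Unit string carried through processing (e.g. ``"mg CH4 m-2 d-1"``).
    name : str
        Variable name used in CSV headers.
    """

    start: pd.Timestamp
    interval: pd.Timedelta
    values: np.ndarray
    units: str = ""
    name: str = "value"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.interval = as_interval(self.interval)
        if self.interval <= pd.Timedelta(0):
            raise ValueError("interval must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def index(self) -> pd.DatetimeIndex:
        """End-of-interval timestamps of every sample."""
        return pd.date_range(self.start, periods=len(self), freq=self.interval)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the sample is missing."""
        return np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def copy(self, **changes) -> "RegularSeries":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    # -- pandas interop ----------------------------------------------------
    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=self.name)

    @classmethod
    def from_pandas(cls, s: pd.Series, units: str = "", name: str | None = None) -> "RegularSeries":
        """Build from a pandas Series with an equally spaced DatetimeIndex."""
        idx = pd.DatetimeIndex(s.index)
        if len(idx) < 2:
            raise ValueError("need at least two samples to infer the interval")
        steps = np.diff(idx.asi8)
        if not (steps == steps[0]).all():
            raise ValueError("index is not equally spaced")
        return cls(
            start=idx[0],
            interval=pd.Timedelta(int(steps[0]), unit="ns"),
            values=s.to_numpy(dtype=float),
            units=units,
            name=name if name is not None else (s.name or "value"),
        )

    def same_grid(self, other: "RegularSeries") -> bool:
        return (
            self.start == other.start
            and self.interval == other.interval
            and len(self) == len(other)
        )


def require_same_grid(*series: RegularSeries) -> None:
    first = series[0]
    for s in series[1:]:
        if not first.same_grid(s):
            raise ValueError(
                f"series {s.name!r} is not on the grid of {first.name!r} "
                f"(start/interval/length must match)"
            )


def bundle_to_frame(series: list[RegularSeries]) -> pd.DataFrame:
    """Stack same-grid series into a DataFrame indexed by timestamp."""
    require_same_grid(*series)
    return pd.DataFrame({s.name: s.values for s in series}, index=series[0].index)
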