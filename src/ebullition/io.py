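"""CSV input/output for the pipeline's tables.

Conventions: comma separated, UTF-8, '.' decimal, ISO-8601 timestamps in a
``timestamp`` column, one column per variable.  Units travel in a comment
line ``# units: col=unit, ...`` directly above the header so files stay
readable by any CSV tool (``pandas.read_csv(..., comment='#')``).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RegularSeries


def write_series_csv(path: str | Path, series: list[RegularSeries]) -> None:
    """Write same-grid series as a timestamped CSV table with a units line."""
    from .timeseries import bundle_to_frame

    frame = bundle_to_frame(series)
    units = ", ".join(f"{s.name}={s.units or '-'}" for s in series)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        frame.rename_axis("timestamp").to_csv(fh, lineterminator="\n")


def read_series_csv(path: str | Path) -> list[RegularSeries]:
    """Read a CSV written by :func:`write_series_csv` back into series."""
    path = Path(path)
    units: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    m = re.match(r"#\s*units:\s*(.*)", first)
    if m:
        for part in m.group(1).split(","):
            if "=" in part:
                k, v = part.split("=", 1)
                units[k.strip()] = v.strip()
    frame = pd.read_csv(path, comment="#", parse_dates=["timestamp"], index_col="timestamp")
    out = []
    for col in frame.columns:
        u = units.get(col, "")
        out.append(RegularSeries.from_pandas(frame[col], units="" if u == "-" else u, name=col))
    return out


def write_table_csv(path: str | Path, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, lineterminator="\n")


def read_irregular_csv(path: str | Path, column: str | None = None) -> pd.Series:
    """Read a possibly irregular timestamped series (for ``prep regularize``)."""
    frame = pd.read_csv(path, comment="#", parse_dates=["timestamp"], index_col="timestamp")
    col = column or frame.columns[0]
    return frame[col]
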