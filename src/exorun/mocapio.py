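"""Text readers/writers for motion-capture formats (TRC, STO/MOT) and CSV.

Internal units are SI (meters, seconds, radians); conversions (mm, degrees)
happen only at the I/O boundary, driven by each file's header. Readers
reject malformed or ambiguous headers rather than guessing; writers
round-trip with readers to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import MarkerTrial

__all__ = [
    "TimeSeriesTable",
    "ParseError",
    "read_trc",
    "write_trc",
    "read_sto_mot",
    "write_sto_mot",
]


class ParseError(ValueError):
    def __init__(self, message, line=None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class TimeSeriesTable:
    """A rectangular numeric table with a strictly increasing time column."""

    time: np.ndarray
    columns: list[str]
    data: np.ndarray             # (n, n_cols)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time column must be strictly increasing")
        if self.data.shape != (len(self.time), len(self.columns)):
            raise ValueError("data shape does not match time/columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column labels must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=pd.Index(self.time, name="time"),
                            columns=self.columns)


# ---------------------------------------------------------------------------
# STO / MOT
# ---------------------------------------------------------------------------

def read_sto_mot(path) -> TimeSeriesTable:
    """Read an STO/MOT time-series table.

    Angle columns are converted to radians when the header declares
    ``inDegrees=yes``. Raises :class:`ParseError` on malformed headers,
    missing time column, or row-count mismatch.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = {}
    i = 0
    n_rows = n_cols = None
    in_degrees = None
    for i, ln in enumerate(lines):
        s = ln.strip()
        if s.lower() == "endheader":
            break
        if "=" in s:
            k, v = s.split("=", 1)
            meta[k.strip()] = v.strip()
            kl = k.strip().lower()
            if kl == "nrows":
                n_rows = int(v)
            elif kl == "ncolumns":
                n_cols = int(v)
            elif kl == "indegrees":
                in_degrees = v.strip().lower() == "yes"
    else:
        raise ParseError("no 'endheader' line found")
    if in_degrees is None:
        raise ParseError("header missing inDegrees flag")
    header_idx = i + 1
    labels = lines[header_idx].rstrip("\n").split("\t")
    labels = [l for l in labels if l != ""]
    if not labels or labels[0] != "time":
        raise ParseError("first column must be 'time'", header_idx + 1)
    rows = []
    for j, ln in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not ln.strip():
            continue
        vals = ln.split()
        if len(vals) != len(labels):
            raise ParseError(f"expected {len(labels)} values, got {len(vals)}", j)
        rows.append([float(v) for v in vals])
    arr = np.asarray(rows, float)
    if n_rows is not None and len(arr) != n_rows:
        raise ParseError(f"header declares nRows={n_rows} but found {len(arr)}")
    if n_cols is not None and arr.shape[1] != n_cols:
        raise ParseError(f"header declares nColumns={n_cols} but found {arr.shape[1]}")
    data = arr[:, 1:]
    cols = labels[1:]
    if in_degrees:
        # convert every non-translation column; translations are identified
        # by the conventional _tx/_ty/_tz suffixes
        for k, c in enumerate(cols):
            if not c.endswith(("_tx", "_ty", "_tz")):
                data[:, k] = np.deg2rad(data[:, k])
    meta["inDegrees"] = "no"
    return TimeSeriesTable(time=arr[:, 0], columns=cols, data=data, metadata=meta)


def write_sto_mot(table: TimeSeriesTable, path):
    """Write a table as STO/MOT (always SI/radians, inDegrees=no)."""
    path = Path(path)
    n, m = table.data.shape
    lines = [path.stem, "version=1", f"nRows={n}", f"nColumns={m + 1}",
             "inDegrees=no", "endheader",
             "\t".join(["time"] + list(table.columns))]
    for i in range(n):
        lines.append("\t".join(
            [f"{table.time[i]:.12g}"] + [f"{v:.12g}" for v in table.data[i]]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path, exotendon=None, runner_id="") -> MarkerTrial:
    """Read a TRC marker file into a :class:`MarkerTrial` (positions in m)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ParseError("not a TRC file (missing PathFileType)", 1)
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr["Units"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"malformed TRC header: {exc}", 3) from None
    if units not in ("mm", "m"):
        raise ParseError(f"unsupported units {units!r}", 3)
    factor = 1e-3 if units == "mm" else 1.0
    marker_line = lines[3].split("\t")
    names = [n for n in marker_line[2:] if n.strip()]
    if len(names) != n_markers:
        raise ParseError(f"expected {n_markers} marker names, got {len(names)}", 4)
    rows = []
    for j, ln in enumerate(lines[5:], start=6):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        vals = []
        for v in parts[2:2 + 3 * n_markers]:
            vals.append(float(v) if v.strip() else np.nan)
        if len(vals) != 3 * n_markers:
            raise ParseError("wrong number of coordinate values", j)
        rows.append(vals)
    pos = np.asarray(rows, float).reshape(len(rows), n_markers, 3) * factor
    return MarkerTrial(marker_names=names, positions=pos, rate_hz=rate,
                       exotendon=exotendon, runner_id=runner_id)


def write_trc(trial: MarkerTrial, path, units="mm"):
    """Write a :class:`MarkerTrial` as TRC (default mm, per convention)."""
    path = Path(path)
    n, m, _ = trial.positions.shape
    factor = 1e3 if units == "mm" else 1.0
    rate = trial.rate_hz
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{m}\t{units}\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(trial.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m)),
    ]
    lines = head
    for i in range(n):
        vals = []
        for j in range(m):
            for c in range(3):
                v = trial.positions[i, j, c] * factor
                vals.append("" if not np.isfinite(v) else f"{v:.8g}")
        lines.append(f"{i+1}\t{i / rate:.8g}\t" + "\t".join(vals))
    path.write_text("\n".join(lines) + "\n")
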