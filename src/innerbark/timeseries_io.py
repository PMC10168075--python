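"""Quality-flagged scalar time series on a regular 10-min grid.

Dendrometer, psychrometer and climate records arrive as delimited text with
ISO-8601 timestamps at (nominally) 10-min cadence.  This module reads them,
snaps them onto an exact 600-s grid, fills short gaps by linear interpolation,
and carries a per-sample quality flag so that no downstream statistic ever
consumes a missing or discarded sample: such samples hold NaN, never a silent
zero.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DomainError,
    EmptyInputError,
    FormatError,
    OrderingError,
)

#: canonical sampling interval of the field campaign
STEP_SECONDS = 600
STEP = pd.Timedelta(seconds=STEP_SECONDS)
SAMPLES_PER_DAY = 86400 // STEP_SECONDS  # 144


class Flag(enum.IntEnum):
    """Per-sample quality code."""

    OK = 0
    INTERPOLATED = 1
    MISSING = 2
    DISCARDED = 3


_FLAG_TO_NAME = {f: f.name.lower() for f in Flag}
_NAME_TO_FLAG = {v: k for k, v in _FLAG_TO_NAME.items()}


@dataclass
class GriddedSeries:
    """A scalar time series with per-sample quality flags.

    Parameters
    ----------
    timestamps
        Strictly increasing, timezone-naive local times.
    values
        Float array; NaN wherever the flag is ``MISSING`` or ``DISCARDED``.
    flags
        Integer :class:`Flag` codes, one per sample.
    unit
        Measurement unit carried as metadata (``µm``, ``MPa``, ``°C`` ...).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    flags: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.flags = np.asarray(self.flags, dtype=np.int8).copy()
        n = len(self.timestamps)
        if len(self.values) != n or len(self.flags) != n:
            raise FormatError("timestamps, values and flags must share one length")
        if n > 1 and not (np.diff(self.timestamps.asi8) > 0).all():
            raise OrderingError("timestamps must be strictly increasing")
        # invariant: invalid samples are NaN sentinels, never silent numbers
        invalid = (self.flags == Flag.MISSING) | (self.flags == Flag.DISCARDED)
        self.values[invalid] = np.nan

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of samples usable downstream (ok or interpolated)."""
        return ((self.flags == Flag.OK) | (self.flags == Flag.INTERPOLATED)) & np.isfinite(
            self.values
        )

    @property
    def is_regular(self) -> bool:
        """True when spacing is a constant 600 s."""
        if len(self) < 2:
            return True
        d = np.diff(self.timestamps.asi8)
        return bool((d == STEP_SECONDS * 10**9).all())

    def require_grid(self) -> None:
        if not self.is_regular:
            raise AlignmentError("series is not on the regular 600 s grid")

    def same_grid(self, other: "GriddedSeries") -> bool:
        return len(self) == len(other) and bool(
            (self.timestamps.asi8 == other.timestamps.asi8).all()
        )

    def day(self, date) -> "GriddedSeries":
        """Samples within [00:00, 24:00) of ``date``."""
        d0 = pd.Timestamp(date).normalize()
        return self.between(d0, d0 + pd.Timedelta(days=1))

    def between(self, start, end) -> "GriddedSeries":
        """Samples within [start, end)."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        m = (self.timestamps >= start) & (self.timestamps < end)
        return GriddedSeries(self.timestamps[m], self.values[m], self.flags[m], self.unit)

    def dates(self) -> list[pd.Timestamp]:
        """Distinct calendar dates touched by the series."""
        return list(pd.DatetimeIndex(self.timestamps.normalize().unique()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "value": self.values,
                "flag": [_FLAG_TO_NAME[Flag(f)] for f in self.flags],
            }
        )

    # -- round-trip persistence -------------------------------------------

    def write(self, path) -> None:
        """Write as CSV with a ``# unit:`` header line; bit-exact round trip."""
        buf = io.StringIO()
        buf.write(f"# unit: {self.unit}\n")
        buf.write("timestamp,value,flag\n")
        for t, v, f in zip(self.timestamps, self.values, self.flags):
            sval = "" if not np.isfinite(v) else repr(float(v))
            buf.write(f"{t.isoformat()},{sval},{_FLAG_TO_NAME[Flag(f)]}\n")
        Path(path).write_text(buf.getvalue(), encoding="utf-8")

    @classmethod
    def read(cls, path) -> "GriddedSeries":
        """Inverse of :meth:`write`."""
        text = Path(path).read_text(encoding="utf-8").splitlines()
        unit = ""
        start = 0
        if text and text[0].startswith("#"):
            unit = text[0].split(":", 1)[1].strip()
            start = 1
        df = pd.read_csv(io.StringIO("\n".join(text[start:])), float_precision="round_trip")
        if "timestamp" not in df.columns or "flag" not in df.columns:
            raise FormatError(f"{path}: expected columns timestamp,value,flag")
        flags = np.array([_NAME_TO_FLAG[s] for s in df["flag"]], dtype=np.int8)
        return cls(pd.DatetimeIndex(pd.to_datetime(df["timestamp"])), df["value"].to_numpy(float), flags, unit)


def read_series(path, schema: dict) -> GriddedSeries:
    """Read one sensor column from a delimited text file.

    ``schema`` declares ``timestamp`` and ``value`` column names, the ``unit``,
    and optionally the delimiter (``sep``, sniffed when absent).  Rows whose
    value cell does not parse are flagged missing; rows whose timestamp does
    not parse cannot be placed on the time axis and are dropped.
    """
    sep = schema.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", comment="#")
    tcol, vcol = schema["timestamp"], schema["value"]
    if tcol not in df.columns:
        raise FormatError(f"{path}: missing timestamp column {tcol!r}")
    if vcol not in df.columns:
        raise FormatError(f"{path}: missing value column {vcol!r}")
    ts = pd.to_datetime(df[tcol], errors="coerce")
    keep = ts.notna()
    ts = pd.DatetimeIndex(ts[keep])
    if len(ts) == 0:
        raise EmptyInputError(f"{path}: no parseable rows")
    if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
        raise OrderingError(f"{path}: timestamps not strictly increasing")
    vals = pd.to_numeric(df.loc[keep, vcol], errors="coerce").to_numpy(float)
    flags = np.where(np.isfinite(vals), Flag.OK, Flag.MISSING).astype(np.int8)
    return GriddedSeries(ts, vals, flags, unit=schema.get("unit", ""))


def regularize(
    series: GriddedSeries,
    interval: int = STEP_SECONDS,
    max_gap: int = 1800,
) -> GriddedSeries:
    """Snap a series onto an exact ``interval``-second grid.

    Grid points coinciding with an input sample copy its value and flag.
    Grid points inside a gap between valid samples no longer than ``max_gap``
    seconds are filled by linear interpolation and flagged ``interpolated``;
    anything inside a longer gap, or outside the span of valid data, is
    flagged ``missing``.  Idempotent on already-gridded input.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot regularize an empty series")
    step_ns = interval * 10**9
    t = series.timestamps.asi8
    g0 = -(-t[0] // step_ns) * step_ns  # ceil to grid
    g1 = (t[-1] // step_ns) * step_ns  # floor to grid
    if g1 < g0:
        raise EmptyInputError("series spans less than one grid interval")
    grid = np.arange(g0, g1 + step_ns, step_ns)

    out_vals = np.full(len(grid), np.nan)
    out_flags = np.full(len(grid), Flag.MISSING, dtype=np.int8)

    # exact hits keep their original value and flag
    pos = np.searchsorted(t, grid)
    pos = np.clip(pos, 0, len(t) - 1)
    hit = t[pos] == grid
    out_vals[hit] = series.values[pos[hit]]
    out_flags[hit] = series.flags[pos[hit]]

    # interpolate remaining points from bracketing *valid* samples
    vmask = series.valid
    tv, vv = t[vmask], series.values[vmask]
    todo = ~hit
    if tv.size >= 2 and todo.any():
        gt = grid[todo]
        right = np.searchsorted(tv, gt)
        ok = (right > 0) & (right < tv.size)
        ridx = np.clip(right, 1, tv.size - 1)
        left = ridx - 1
        gap = tv[ridx] - tv[left]
        fill = ok & (gap <= max_gap * 10**9)
        w = np.where(gap > 0, (gt - tv[left]) / gap, 0.0)
        vals = vv[left] + w * (vv[ridx] - vv[left])
        sel = np.flatnonzero(todo)[fill]
        out_vals[sel] = vals[fill]
        out_flags[sel] = Flag.INTERPOLATED

    return GriddedSeries(
        pd.DatetimeIndex(grid.astype("datetime64[ns]")), out_vals, out_flags, series.unit
    )


def discard_interval(series: GriddedSeries, start, end, reason: str = "") -> GriddedSeries:
    """Flag samples in ``[start, end)`` as discarded (unreliable sensor data).

    The reason is returned to the caller's manifest by the pipeline; the
    series itself only carries the flag.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if not start < end:
        raise DomainError("discard interval requires start < end")
    m = (series.timestamps >= start) & (series.timestamps < end)
    flags = series.flags.copy()
    vals = series.values.copy()
    flags[m] = Flag.DISCARDED
    vals[m] = np.nan
    return GriddedSeries(series.timestamps, vals, flags, series.unit)
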