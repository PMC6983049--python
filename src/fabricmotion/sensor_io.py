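"""Read and write accelerometer CSV streams and activity-log files.

CSV dialect (one documented dialect rather than the many raw-export
variants in the wild, so round trips are bit-stable):

.. code-block:: text

    # fs=50
    # sensor_id=thigh_body
    # site=thigh
    # mount=body
    timestamp,ax,ay,az
    2019-06-01T09:00:00.000000,0,1,0
    ...

Values are in g.  Timestamps are ISO-8601; only the first row's
timestamp is trusted (it becomes ``t0``) — subsequent rows are
regenerated from ``t0 + i/fs`` on write and ignored on read, because
all analysis assumes uniform sampling.

Activity logs are one entry per line, ``label,start,end`` where the
times are either bare ``HH:MM:SS[.ffffff]`` (interpreted on
``ref_date``) or full ISO timestamps.
"""

from __future__ import annotations

import io
import os
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError
from .types import AccelSeries, ActivityEntry, ActivityLog, normalise_label

_META_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")
_TIME_RE = re.compile(r"^\d{1,2}:\d{2}:\d{2}(\.\d+)?$")

# 12 significant digits: float64 round trips exactly at this precision
# for the g-scale values these devices report.
_FLOAT_FMT = "%.12g"


def read_accel_csv(path: str | os.PathLike, fs_expected: float | None = None) -> AccelSeries:
    """Parse an accelerometer CSV into an :class:`AccelSeries`.

    Parameters
    ----------
    fs_expected:
        If given, validated against the file's ``# fs=`` header (and
        used as the rate when the header is absent).

    Raises
    ------
    ParseError
        Malformed rows (message names the 1-based line number).
    ConfigError
        Sampling rate missing or inconsistent with ``fs_expected``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    meta: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
        elif line.strip():
            body_start = i
            break
    else:
        raise ParseError(f"{path}: no data rows found")

    fs_file = float(meta["fs"]) if "fs" in meta else None
    if fs_file is None and fs_expected is None:
        raise ConfigError(f"{path}: no '# fs=' header and no fs_expected supplied")
    if fs_file is not None and fs_expected is not None:
        if abs(fs_file - fs_expected) > 1e-9 * max(fs_file, fs_expected):
            raise ConfigError(
                f"{path}: file declares fs={fs_file} Hz but fs_expected={fs_expected} Hz"
            )
    fs = fs_file if fs_file is not None else float(fs_expected)

    header = lines[body_start].strip().lower().split(",")
    if header[:4] != ["timestamp", "ax", "ay", "az"]:
        raise ParseError(
            f"{path}: line {body_start + 1}: expected header 'timestamp,ax,ay,az', "
            f"got {lines[body_start]!r}"
        )

    data_lines = lines[body_start + 1 :]
    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(data_lines)),
            header=None,
            names=["timestamp", "ax", "ay", "az"],
            dtype={"ax": np.float64, "ay": np.float64, "az": np.float64},
        )
    except (ValueError, pd.errors.ParserError):
        _locate_bad_row(path, data_lines, body_start + 1)
        raise ParseError(f"{path}: malformed numeric data")  # pragma: no cover
    if frame.empty:
        raise ParseError(f"{path}: no data rows found")
    values = frame[["ax", "ay", "az"]].to_numpy()
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise ParseError(
            f"{path}: line {body_start + 2 + row}: missing value in {data_lines[row]!r}"
        )
    try:
        t0 = pd.Timestamp(frame["timestamp"].iloc[0])
    except ValueError as exc:
        raise ParseError(f"{path}: line {body_start + 2}: bad timestamp: {exc}") from None

    return AccelSeries(
        data=values,
        fs=fs,
        t0=t0,
        sensor_id=meta.get("sensor_id", ""),
        site=meta.get("site"),
        mount=meta.get("mount"),
    )


def _locate_bad_row(path, data_lines: Sequence[str], offset: int) -> None:
    """Slow path after a bulk-parse failure: name the offending line."""
    for j, line in enumerate(data_lines):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(
                f"{path}: line {offset + 1 + j}: expected 4 fields, got "
                f"{len(parts)}: {line!r}"
            )
        for p in parts[1:]:
            try:
                float(p)
            except ValueError:
                raise ParseError(
                    f"{path}: line {offset + 1 + j}: non-numeric value {p!r}"
                ) from None


def write_accel_csv(series: AccelSeries, path: str | os.PathLike) -> str:
    """Write a series in the package CSV dialect; returns the path.

    Values are printed to 12 significant digits so that
    ``read_accel_csv(write_accel_csv(s))`` reproduces ``s`` exactly at
    that precision.
    """
    stamps = series.timestamps().strftime("%Y-%m-%dT%H:%M:%S.%f")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={_FLOAT_FMT % series.fs}\n")
        if series.sensor_id:
            fh.write(f"# sensor_id={series.sensor_id}\n")
        if series.site:
            fh.write(f"# site={series.site}\n")
        if series.mount:
            fh.write(f"# mount={series.mount}\n")
        fh.write("timestamp,ax,ay,az\n")
        for ts, (ax, ay, az) in zip(stamps, series.data):
            fh.write(
                f"{ts},{_FLOAT_FMT % ax},{_FLOAT_FMT % ay},{_FLOAT_FMT % az}\n"
            )
    return str(path)


def read_activity_log(
    path: str | os.PathLike, ref_date: pd.Timestamp | str | None = None
) -> ActivityLog:
    """Parse a ``label,start,end`` diary file.

    Bare ``HH:MM:SS`` times are interpreted on ``ref_date`` (default
    1970-01-01; use :meth:`ActivityLog.rebase` to attach the recording
    date).  Unknown labels warn and become ``"other"``; overlapping
    entries raise :class:`ValidationError`.
    """
    base = pd.Timestamp(ref_date).normalize() if ref_date is not None else pd.Timestamp(0)
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'label,start,end', got {line!r}"
                )
            label = normalise_label(parts[0])
            try:
                start = _parse_when(parts[1], base)
                end = _parse_when(parts[2], base)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            entries.append(ActivityEntry(label, start, end))
    return ActivityLog(entries)


def _parse_when(text: str, base: pd.Timestamp) -> pd.Timestamp:
    if _TIME_RE.match(text):
        h, m, s = text.split(":")
        return base + pd.Timedelta(hours=int(h), minutes=int(m), seconds=float(s))
    return pd.Timestamp(text)


def write_activity_log(log: ActivityLog, path: str | os.PathLike) -> str:
    """Write a diary file with times of day (``HH:MM:SS[.ffffff]``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in log.entries:
            fh.write(f"{e.label},{_fmt_time(e.start)},{_fmt_time(e.end)}\n")
    return str(path)


def _fmt_time(ts: pd.Timestamp) -> str:
    if ts.microsecond:
        return ts.strftime("%H:%M:%S.%f")
    return ts.strftime("%H:%M:%S")
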