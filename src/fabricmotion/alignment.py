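"""Synchronisation: marker detection and cross-correlation lag removal.

A garment-mounted sensor can trail the body-worn sensor by a fraction
of a second because fabric couples to the limb elastically.  Each pair
is first coarsely aligned on the start-of-day jump marker, then the
residual integer-sample lag is estimated as the shift maximising the
normalised (Pearson) cross-correlation between the two streams, and
removed by trimming to the overlapping region so no fabricated samples
enter downstream statistics.

The lag sign convention is positive when the clothing channel lags the
body channel.  The correlation axis defaults to y (the gravity axis),
which carries the strongest activity signal; it is configurable, as is
``max_lag`` (default 2 s of samples — generous relative to the
sub-second lags loose garments exhibit).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import MarkerNotFoundError, UndefinedCorrelationError, ValidationError
from .types import AccelSeries, SensorPair


@dataclass(frozen=True)
class LagEstimate:
    """Result of cross-correlation lag estimation.

    ``lag_samples`` is positive when the second stream (clothing) lags
    the first (body); ``peak_xcorr`` is the Pearson correlation of the
    overlapping samples at that shift.
    """

    lag_samples: int
    lag_seconds: float
    peak_xcorr: float
    search_range: int

    def __post_init__(self) -> None:
        if abs(self.lag_samples) > self.search_range:
            raise ValidationError("lag outside the declared search range")


def detect_jump_marker(
    series: AccelSeries,
    window: tuple[float, float] = (0.0, 10.0),
    floor_g: float = 2.0,
) -> int:
    """Index of the maximum acceleration magnitude within a time window.

    Raises :class:`MarkerNotFoundError` when the peak does not clear
    ``floor_g`` — a flat recording has no jump to find.
    """
    i0, i1 = _window_indices(series, window)
    mag = series.magnitude()[i0:i1]
    j = int(np.argmax(mag))
    if mag[j] < floor_g:
        raise MarkerNotFoundError(
            f"no jump marker: peak magnitude {mag[j]:.2f} g below floor {floor_g} g"
        )
    return i0 + j


def detect_taps(
    series: AccelSeries,
    n: int = 4,
    window: tuple[float, float] = (0.0, 10.0),
    min_separation_s: float = 0.2,
    floor_g: float = 2.0,
) -> list[int]:
    """Indices of the `n` largest local magnitude maxima in a window.

    Peaks must be separated by at least ``min_separation_s`` and exceed
    ``floor_g``; fewer qualifying peaks raise
    :class:`MarkerNotFoundError`.  Returned sorted by time.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    i0, i1 = _window_indices(series, window)
    mag = series.magnitude()[i0:i1]
    distance = max(1, int(round(min_separation_s * series.fs)))
    peaks, props = _signal.find_peaks(mag, distance=distance, height=floor_g)
    if len(peaks) < n:
        raise MarkerNotFoundError(
            f"found {len(peaks)} qualifying peaks above {floor_g} g, need {n}"
        )
    top = peaks[np.argsort(props["peak_heights"])[::-1][:n]]
    return sorted(int(i0 + p) for p in top)


def coarse_align(
    pair: SensorPair,
    window: tuple[float, float] = (0.0, 10.0),
    floor_g: float = 2.0,
) -> SensorPair:
    """Shift a pair so the start-jump markers coincide.

    Both streams are trimmed to their equal-length overlap.  Raises
    :class:`ValidationError` if the recordings do not overlap after the
    shift, and propagates marker-detection errors.
    """
    jb = detect_jump_marker(pair.body, window=window, floor_g=floor_g)
    jc = detect_jump_marker(pair.clothing, window=window, floor_g=floor_g)
    offset = jc - jb  # clothing marker later => clothing stream starts earlier
    return shift_pair(pair, offset)


def shift_pair(pair: SensorPair, offset: int) -> SensorPair:
    """Drop `offset` leading clothing samples (or trailing, if negative)
    and trim both streams to the common overlap."""
    nb, nc = pair.body.n, pair.clothing.n
    if offset >= nc or -offset >= nb:
        raise ValidationError("streams do not overlap at the required shift")
    body = pair.body if offset >= 0 else pair.body.slice(-offset, nb)
    clothing = pair.clothing.slice(offset, nc) if offset > 0 else pair.clothing
    n = min(body.n, clothing.n)
    return SensorPair(body.slice(0, n) if body.n > n else body,
                      clothing.slice(0, n) if clothing.n > n else clothing)


def estimate_lag_xcorr(
    a: AccelSeries | np.ndarray,
    b: AccelSeries | np.ndarray,
    axis: str = "y",
    max_lag: int = 100,
) -> LagEstimate:
    """Lag of `b` relative to `a` by normalised cross-correlation.

    For every integer shift k in ``[-max_lag, max_lag]`` the Pearson
    correlation of the overlapping samples of the selected axis is
    computed (each overlap re-centred and re-scaled, so the estimate is
    invariant to amplitude scaling between the channels); the argmax is
    the lag.  Exact ties are broken toward the smallest ``|lag|``.

    Accepts :class:`AccelSeries` (with ``axis`` in x/y/z/magnitude) or
    bare 1-D arrays.  Inputs must have equal length >= ``2 * max_lag``.
    """
    x = a.axis(axis) if isinstance(a, AccelSeries) else np.asarray(a, dtype=np.float64)
    y = b.axis(axis) if isinstance(b, AccelSeries) else np.asarray(b, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("signals must be 1-D and of equal length")
    n = x.size
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")
    if n < max(2 * max_lag, 3):
        raise ValidationError(
            f"signals of length {n} too short for max_lag={max_lag}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input; lag undefined")

    fs = a.fs if isinstance(a, AccelSeries) else None
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, -np.inf)
    for i, k in enumerate(lags):
        if k >= 0:
            u, v = x[: n - k], y[k:]
        else:
            u, v = x[-k:], y[: n + k]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            continue
        r[i] = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    if not np.any(np.isfinite(r)):
        raise UndefinedCorrelationError("correlation undefined at every shift")
    best = r.max()
    ties = lags[r == best]
    lag = int(ties[np.lexsort((ties, np.abs(ties)))[0]])
    return LagEstimate(
        lag_samples=lag,
        lag_seconds=lag / fs if fs else float("nan"),
        peak_xcorr=float(best),
        search_range=int(max_lag),
    )


def apply_lag(series: AccelSeries, lag: LagEstimate | int) -> AccelSeries:
    """Remove an estimated lag from the lagging stream by trimming.

    Positive lag: the stream trails its reference, so the first
    ``lag`` samples are dropped (the retained samples then line up with
    the reference timeline from its t0).  Negative lag: the stream
    leads, so the last ``|lag|`` samples are dropped and t0 advances.
    No samples are fabricated.
    """
    k = lag.lag_samples if isinstance(lag, LagEstimate) else int(lag)
    if abs(k) >= series.n:
        raise ValidationError(f"|lag|={abs(k)} >= series length {series.n}")
    if k == 0:
        return series
    if k > 0:
        # aligned to the reference timeline: the first retained sample
        # reflects motion at the reference t0
        return dataclasses.replace(series.slice(k, series.n), t0=series.t0)
    # stream leads: its trailing samples have no reference counterpart,
    # and the first retained sample reflects reference motion at t0+|k|/fs
    return dataclasses.replace(
        series.slice(0, series.n + k),
        t0=series.t0 + pd.to_timedelta(-k / series.fs, unit="s"),
    )


def apply_lag_pair(pair: SensorPair, lag: LagEstimate | int) -> SensorPair:
    """Align a pair at an estimated lag, trimming both to the overlap.

    After this, re-estimating the lag on the returned pair gives 0.
    """
    k = lag.lag_samples if isinstance(lag, LagEstimate) else int(lag)
    return shift_pair(pair.trimmed(), k)


def _window_indices(series: AccelSeries, window: tuple[float, float]) -> tuple[int, int]:
    lo, hi = window
    if not 0 <= lo < hi:
        raise ValidationError(f"invalid window {window}")
    i0 = int(round(lo * series.fs))
    i1 = min(series.n, int(round(hi * series.fs)))
    if i1 - i0 < 1 or i0 >= series.n:
        raise ValidationError(f"window {window} lies outside the series")
    return i0, i1
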