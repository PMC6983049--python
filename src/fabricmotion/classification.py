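"""Threshold decision-tree activity classification and pair agreement.

Two features, both from the gravity (y) axis of an aligned stream:

* the y-axis acceleration itself — near 1 g standing (thigh vertical),
  near 0 g sitting (thigh horizontal, y perpendicular to gravity);
* its moving variance over a 250 ms centred window — near zero while
  static, moderate during posture transitions, large during gait.

A fixed decision tree turns these into four classes (variance is
tested before posture, since movement masks the postural reading):

    mov_var >= var_move_min   -> walking/running
    mov_var >= var_trans_min  -> transition
    y >= y_stand_min          -> standing
    y <= y_sit_max            -> sitting
    otherwise                 -> transition (ambiguous static posture)

Agreement between the clothing-mounted and body-worn classifications is
tabulated as a confusion matrix with the body-worn labels as the
reference rows, row-normalised to percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import ValidationError
from .types import AccelSeries

CLASSES = ("walking_running", "transition", "sitting", "standing")

#: Display names for reports/CSV headers.
CLASS_DISPLAY = {
    "walking_running": "Walking/Running",
    "transition": "Transition",
    "sitting": "Sitting",
    "standing": "Standing",
}


@dataclass
class ClassifierThresholds:
    """Decision-tree parameters.

    Defaults are derived from the physics of an aligned thigh sensor
    (standing y ~ 1 g, sitting y ~ 0 g, static variance at noise floor)
    rather than tuned to any recording; all are config-overridable.
    """

    y_sit_max: float = 0.5
    y_stand_min: float = 0.7
    var_trans_min: float = 0.005
    var_move_min: float = 0.05
    window_ms: float = 250.0

    def __post_init__(self) -> None:
        if not 0 <= self.var_trans_min < self.var_move_min:
            raise ValidationError(
                "need 0 <= var_trans_min < var_move_min; got "
                f"{self.var_trans_min}, {self.var_move_min}"
            )
        if not self.y_sit_max < self.y_stand_min:
            raise ValidationError("need y_sit_max < y_stand_min")
        if not self.window_ms > 0:
            raise ValidationError("window_ms must be positive")


def window_samples(window_ms: float, fs: float) -> int:
    """Moving-variance window length in samples, round-half-up.

    250 ms at 50 Hz is 12.5 samples -> 13 (odd windows centre cleanly).
    """
    w = int(np.floor(window_ms * fs / 1000.0 + 0.5))
    return w


def moving_variance(x: np.ndarray, window_ms: float = 250.0, fs: float = 50.0) -> np.ndarray:
    """Centred sliding-window population variance, same length as input.

    Edges use the truncated available window.  Implemented with
    cumulative sums; equals a direct per-window recomputation to within
    accumulation round-off.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("input must be 1-D")
    w = window_samples(window_ms, fs)
    if w < 2:
        raise ValidationError(f"window of {window_ms} ms at {fs} Hz is {w} sample(s); need >= 2")
    n = x.size
    if n < w:
        raise ValidationError(f"sequence of {n} samples shorter than window {w}")
    half_l = (w - 1) // 2
    half_r = w // 2
    idx = np.arange(n)
    starts = np.maximum(0, idx - half_l)
    ends = np.minimum(n, idx + half_r + 1)
    # centre on the global mean: variance is shift-invariant and this
    # avoids catastrophic cancellation (constant input -> exact zeros)
    x = x - x.mean()
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cnt = ends - starts
    s1 = c1[ends] - c1[starts]
    s2 = c2[ends] - c2[starts]
    var = s2 / cnt - (s1 / cnt) ** 2
    return np.maximum(var, 0.0)


def classify_samples(
    y_accel: np.ndarray,
    mov_var: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> np.ndarray:
    """Per-sample activity labels from the fixed threshold tree."""
    th = thresholds or ClassifierThresholds()
    y = np.asarray(y_accel, dtype=np.float64)
    v = np.asarray(mov_var, dtype=np.float64)
    if y.shape != v.shape or y.ndim != 1:
        raise ValidationError("y_accel and mov_var must be 1-D and of equal length")
    return np.select(
        [
            v >= th.var_move_min,
            v >= th.var_trans_min,
            y >= th.y_stand_min,
            y <= th.y_sit_max,
        ],
        ["walking_running", "transition", "standing", "sitting"],
        default="transition",
    ).astype("U16")


def classification_features(
    series: AccelSeries, thresholds: ClassifierThresholds | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(y acceleration, y moving variance) for a gravity-aligned stream."""
    th = thresholds or ClassifierThresholds()
    y = series.axis("y")
    return y, moving_variance(y, window_ms=th.window_ms, fs=series.fs)


def classify_series(
    series: AccelSeries, thresholds: ClassifierThresholds | None = None
) -> np.ndarray:
    y, mv = classification_features(series, thresholds)
    return classify_samples(y, mv, thresholds)


def estimate_thresholds(
    y_accel: np.ndarray,
    mov_var: np.ndarray,
    fs: float = 50.0,
    method: str = "fixed_default",
) -> ClassifierThresholds:
    """Thresholds, either the documented defaults or data-driven.

    ``fixed_default`` returns the documented constants verbatim.
    ``quantile`` anchors the variance thresholds between the static
    floor and the movement plateau of the observed moving-variance
    distribution (geometric interpolation between its 50th and 90th
    percentiles, which bracket the two clusters in any day containing
    both rest and gait) and the posture thresholds between the two
    dominant modes of the low-variance y histogram.  Falls back to the
    defaults (with a warning) when the histogram is unimodal — e.g. an
    all-static recording.
    """
    if method == "fixed_default":
        return ClassifierThresholds()
    if method != "quantile":
        raise ValidationError(f"unknown threshold method {method!r}")
    y = np.asarray(y_accel, dtype=np.float64)
    v = np.asarray(mov_var, dtype=np.float64)
    if y.size < 60 * fs:
        raise ValidationError("need at least 60 s of data to estimate thresholds")

    p50, p90 = np.percentile(v, [50, 90])
    floor = 1e-8  # guards the geometric mean on noise-free synthetic input
    var_move_min = float(np.sqrt(max(p50, floor) * max(p90, floor)))
    var_trans_min = float(np.sqrt(max(p50, floor) * var_move_min))
    if not var_trans_min < var_move_min:
        warnings.warn("degenerate moving-variance distribution; using fixed defaults")
        return ClassifierThresholds()

    static_y = y[v < var_trans_min]
    if static_y.size < 20:
        warnings.warn("too few static samples; using fixed defaults")
        return ClassifierThresholds()
    counts, edges = np.histogram(static_y, bins=40)
    centres = (edges[:-1] + edges[1:]) / 2.0
    peaks, props = _signal.find_peaks(
        np.concatenate([[0], counts, [0]]), prominence=max(2.0, 0.2 * counts.max())
    )
    peaks = peaks - 1
    if peaks.size < 2:
        warnings.warn("unimodal posture histogram; using fixed defaults")
        return ClassifierThresholds()
    top2 = peaks[np.argsort(props["prominences"])[::-1][:2]]
    m_low, m_high = sorted(centres[top2])
    if m_high - m_low < 0.3:
        # seated vs upright thigh postures sit ~1 g apart on y; closer
        # modes are histogram noise, not two postures
        warnings.warn("posture modes not separable; using fixed defaults")
        return ClassifierThresholds()
    return ClassifierThresholds(
        y_sit_max=float(m_low + 0.3 * (m_high - m_low)),
        y_stand_min=float(m_low + 0.7 * (m_high - m_low)),
        var_trans_min=var_trans_min,
        var_move_min=var_move_min,
    )


@dataclass
class ConfusionMatrix:
    """Agreement table; reference (body-worn) labels index the rows."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def row_pct(self) -> np.ndarray:
        """Row-normalised percentages; empty reference rows are NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    def diagonal_pct(self) -> dict[str, float]:
        pct = self.row_pct
        return {c: float(pct[i, i]) for i, c in enumerate(self.classes)}

    def to_frame(self, pct: bool = False) -> pd.DataFrame:
        names = [CLASS_DISPLAY.get(c, c) for c in self.classes]
        values = self.row_pct if pct else self.counts
        return pd.DataFrame(values, index=names, columns=names)


def confusion(
    ref: np.ndarray, test: np.ndarray, classes: tuple[str, ...] = CLASSES
) -> ConfusionMatrix:
    """Cross-tabulate two label sequences (reference rows, test columns)."""
    ref = np.asarray(ref)
    test = np.asarray(test)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValidationError("label sequences must be 1-D and of equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for arr in (ref, test):
        unknown = set(np.unique(arr)) - set(classes)
        if unknown:
            raise ValidationError(f"labels outside the class list: {sorted(unknown)}")
    ri = np.fromiter((index[c] for c in ref), dtype=np.int64, count=ref.size)
    ti = np.fromiter((index[c] for c in test), dtype=np.int64, count=test.size)
    np.add.at(counts, (ri, ti), 1)
    return ConfusionMatrix(classes=classes, counts=counts)
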