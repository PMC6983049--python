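"""Synthetic paired body/clothing accelerometer streams.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without the
study recordings:

* gravity on the y axis while upright (standing, walking, running) and
  rotated onto the z axis while seated (thigh horizontal);
* gait oscillation with the double-peak-per-stride morphology — two
  steps per stride, stride period 0.7 s walking and 0.3 s running;
* linear 0.5 s posture-transition ramps producing the sudden
  moving-variance rise the classifier keys on;
* start/end jump spikes and four synchronisation taps 0.5 s apart;
* a clothing channel derived from the body channel by an integer
  sample delay, a fixed rotation offset, amplitude scaling, an additive
  fabric-swing sinusoid on the anterior–posterior (x) axis, and white
  Gaussian noise.

Everything is driven by a single integer seed; identical seeds give
bit-identical streams.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .orientation import RotationSpec
from .types import (
    AccelSeries,
    ActivityLog,
    GAIT_LABELS,
    SensorPair,
    make_log,
    normalise_label,
)

#: Stride (two-step) periods in seconds observed for this protocol.
STRIDE_PERIODS = {"walking": 0.7, "running": 0.3}

_UPRIGHT = np.array([0.0, 1.0, 0.0])  # gravity on +y
_SEATED = np.array([0.0, 0.0, 1.0])  # thigh horizontal: gravity on +z

_BASELINES = {
    "standing": _UPRIGHT,
    "walking": _UPRIGHT,
    "running": _UPRIGHT,
    "other": _UPRIGHT,
    "sitting": _SEATED,
    "bus_ride": _SEATED,
}

#: Default day: calibration stance first, then mixed activity bouts.
DEFAULT_SCHEDULE = (
    ("standing", 60.0),
    ("walking", 90.0),
    ("sitting", 120.0),
    ("walking", 60.0),
    ("running", 60.0),
    ("bus_ride", 90.0),
    ("walking", 60.0),
    ("standing", 60.0),
)


@dataclass
class SynthConfig:
    """Study conditions for the body-worn stream.

    Amplitudes are thigh-scale: walking oscillation ~0.6 g peak,
    running ~1.2 g peak on the gravity axis, consistent with the
    sharper, larger running peaks seen at 50 Hz.
    """

    fs: float = 50.0
    schedule: tuple = DEFAULT_SCHEDULE
    stride_period: dict = field(default_factory=lambda: dict(STRIDE_PERIODS))
    walk_amp: float = 0.6
    run_amp: float = 1.2
    noise_sd: float = 0.02
    seed: int = 0
    markers: bool = False
    transition_s: float = 0.5
    bus_vibration: float = 0.04
    bus_vibration_hz: float = 4.0
    t0: pd.Timestamp = pd.Timestamp("2019-06-01 09:00:00")

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValidationError("schedule must not be empty")
        self.schedule = tuple(
            (normalise_label(lab), float(dur)) for lab, dur in self.schedule
        )
        for lab, dur in self.schedule:
            if not dur > 0:
                raise ValidationError(f"schedule duration must be > 0; got {dur}")
        for lab, sp in self.stride_period.items():
            if not sp > 2.0 / self.fs:
                raise ValidationError(
                    f"stride period {sp} s for {lab!r} is not resolvable at {self.fs} Hz"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class ClothingChannelParams:
    """Distortions mapping a body stream to its clothing counterpart.

    clothing(t) = R @ (scale * body(t - lag)) + swing(t) * x_hat + noise

    The swing term models pendulum-like garment motion along the
    anterior–posterior axis; its parameters are free knobs, not
    calibrated to any fabric.
    """

    lag_samples: int = 38
    rotation: RotationSpec = field(
        default_factory=lambda: RotationSpec(np.array([1.0, 0.0, 0.0]), np.radians(15.0))
    )
    swing_amp: float = 0.1
    swing_freq: float = 1.2
    amp_scale: float = 1.1
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        self.lag_samples = int(self.lag_samples)
        if self.lag_samples < 0:
            raise ValidationError("lag_samples must be >= 0")
        if not self.amp_scale > 0:
            raise ValidationError("amp_scale must be > 0")
        if self.swing_amp < 0 or self.noise_sd < 0:
            raise ValidationError("swing_amp and noise_sd must be >= 0")


def generate_body_stream(config: SynthConfig) -> tuple[AccelSeries, ActivityLog]:
    """Generate the body-worn stream and the matching activity log.

    Noise-free static segments have unit magnitude exactly; walking and
    running superimpose a two-harmonic waveform whose dominant spectral
    peak sits at the step frequency ``2 / stride_period``.
    """
    fs = config.fs
    seg_samples = [int(round(dur * fs)) for _, dur in config.schedule]
    n = sum(seg_samples)
    if n == 0:
        raise ValidationError("schedule produces zero samples")

    # posture baseline as a step function, then linear transition ramps
    # via a boxcar of width transition_s (moving-averaging a step gives
    # an exact linear ramp over the window).
    baseline = np.empty((n, 3))
    pos = 0
    bounds = []
    for (label, _), m in zip(config.schedule, seg_samples):
        baseline[pos : pos + m] = _BASELINES[label]
        bounds.append((pos, pos + m, label))
        pos += m
    w = max(1, int(round(config.transition_s * fs)))
    if w > 1:
        baseline = _boxcar_smooth(baseline, w)

    t = np.arange(n) / fs
    data = baseline.copy()
    for i0, i1, label in bounds:
        if label in GAIT_LABELS:
            amp = config.walk_amp if label == "walking" else config.run_amp
            stride = config.stride_period[label]
            env = _segment_envelope(n, i0, i1, w)
            t_rel = t - t[i0]
            phase = 2.0 * np.pi * t_rel / stride  # stride phase
            wy = np.sin(2.0 * phase) + 0.35 * np.sin(phase + 0.4)
            wx = 0.35 * np.sin(2.0 * phase + 1.1)
            wz = 0.20 * np.sin(2.0 * phase + 2.0)
            data[:, 0] += env * amp * wx
            data[:, 1] += env * amp * wy
            data[:, 2] += env * amp * wz
        elif label == "bus_ride" and config.bus_vibration > 0:
            env = _segment_envelope(n, i0, i1, w)
            vib = config.bus_vibration * np.sin(
                2.0 * np.pi * config.bus_vibration_hz * t
            )
            data += (env * vib)[:, None] * np.array([0.4, 0.4, 1.0])

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    series = AccelSeries(data, fs=fs, t0=config.t0, sensor_id="synthetic_body", mount="body")
    if config.markers:
        series = inject_markers(series, at_start=True, at_end=True, taps=4)
    log = make_log(config.schedule, config.t0)
    return series, log


def _boxcar_smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving average with edge padding (constant ends unchanged)."""
    left = (w - 1) // 2
    right = w - 1 - left
    padded = np.concatenate(
        [np.repeat(x[:1], left, axis=0), x, np.repeat(x[-1:], right, axis=0)]
    )
    # summing w identical values then dividing once keeps constant
    # stretches bit-exact (no per-tap kernel rounding)
    kernel = np.ones(w)
    return np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") / w for j in range(x.shape[1])]
    )


def _segment_envelope(n: int, i0: int, i1: int, w: int) -> np.ndarray:
    """Indicator of [i0, i1) with the same transition ramps as the baseline."""
    ind = np.zeros((n, 1))
    ind[i0:i1] = 1.0
    if w > 1:
        ind = _boxcar_smooth(ind, w)
    return ind[:, 0]


def apply_clothing_transform(
    body: AccelSeries, params: ClothingChannelParams, seed: int
) -> AccelSeries:
    """Derive the clothing-mounted channel from a body channel.

    Output has the same length and rate; the delayed leading edge is
    padded by repeating the first sample (lag tests should exclude that
    edge).  With zero noise and zero swing the transform is exactly
    invertible by un-delaying and applying the inverse rotation.
    """
    lag = params.lag_samples
    if lag >= body.n:
        raise ValidationError(f"lag_samples={lag} >= series length {body.n}")
    data = body.data
    if lag > 0:
        data = np.vstack([np.repeat(data[:1], lag, axis=0), data[:-lag]])
    data = params.amp_scale * data
    data = params.rotation.apply(data)
    if params.swing_amp > 0:
        t = body.time_seconds()
        data = data.copy()
        data[:, 0] += params.swing_amp * np.sin(2.0 * np.pi * params.swing_freq * t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
    return AccelSeries(
        data,
        fs=body.fs,
        t0=body.t0,
        sensor_id="synthetic_clothing",
        site=body.site,
        mount="clothing",
    )


# -- synchronisation markers ------------------------------------------------

_JUMP_PEAK = 5.0  # g added on y; well above the 2 g detection floor
_TAP_PEAK = 3.5
_JUMP_AT_S = 0.5
_FIRST_TAP_S = 1.5
_TAP_SPACING_S = 0.5
_END_JUMP_FROM_END_S = 0.5


def marker_positions(
    n: int, fs: float, at_start: bool = True, at_end: bool = False, taps: int = 4
) -> dict:
    """Deterministic sample indices where markers are injected."""
    out: dict = {"jump_start": None, "taps": [], "jump_end": None}
    if at_start:
        out["jump_start"] = int(round(_JUMP_AT_S * fs))
    if taps > 0:
        out["taps"] = [
            int(round((_FIRST_TAP_S + k * _TAP_SPACING_S) * fs)) for k in range(taps)
        ]
    if at_end:
        out["jump_end"] = n - 1 - int(round(_END_JUMP_FROM_END_S * fs))
    return out


def inject_markers(
    series: AccelSeries,
    at_start: bool = True,
    at_end: bool = False,
    taps: int = 4,
) -> AccelSeries:
    """Superimpose jump/tap synchronisation markers on a stream.

    The start jump is a biphasic spike (>= 4 g peak) at 0.5 s; `taps`
    short spikes follow 0.5 s apart; the end jump (slightly larger, so
    it is the global maximum of its neighbourhood) sits 0.5 s before
    the end.
    """
    if taps < 0:
        raise ValidationError("taps must be >= 0")
    fs = series.fs
    need = 0.0
    if at_start or taps > 0:
        need = max(need, _FIRST_TAP_S + max(taps, 1) * _TAP_SPACING_S)
    if at_end:
        need += _END_JUMP_FROM_END_S + 1.0 / fs
    if series.duration <= need:
        raise ValidationError(
            f"series of {series.duration:.2f} s too short for requested markers"
        )
    pos = marker_positions(series.n, fs, at_start=at_start, at_end=at_end, taps=taps)
    data = series.data.copy()
    if pos["jump_start"] is not None:
        _add_biphasic(data, pos["jump_start"], _JUMP_PEAK)
    for j in pos["taps"]:
        data[j, 1] += _TAP_PEAK
    if pos["jump_end"] is not None:
        _add_biphasic(data, pos["jump_end"], _JUMP_PEAK * 1.2)
    return series.with_data(data)


def _add_biphasic(data: np.ndarray, j: int, peak: float) -> None:
    data[j, 1] += peak
    if j + 2 < data.shape[0]:
        data[j + 2, 1] -= 0.3 * peak


# -- paired generation ------------------------------------------------------

def generate_sensor_pair(
    config: SynthConfig, params: ClothingChannelParams | None = None
) -> tuple[SensorPair, ActivityLog, dict]:
    """Generate a body/clothing pair plus a ground-truth sidecar dict.

    Markers (when enabled) are injected into the body stream before the
    clothing transform so both channels carry them, delayed in the
    clothing channel exactly like the motion itself.  The clothing
    noise stream is seeded with ``config.seed + 1`` so the two channels
    have independent noise.
    """
    if params is None:
        params = ClothingChannelParams()
    body, log = generate_body_stream(config)
    clothing = apply_clothing_transform(body, params, seed=config.seed + 1)
    truth = {
        "fs": config.fs,
        "seed": config.seed,
        "lag_samples": params.lag_samples,
        "rotation_axis": params.rotation.axis.tolist(),
        "rotation_angle_deg": params.rotation.angle_deg,
        "amp_scale": params.amp_scale,
        "swing_amp": params.swing_amp,
        "swing_freq": params.swing_freq,
        "noise_sd_body": config.noise_sd,
        "noise_sd_clothing": params.noise_sd,
        "schedule": [[lab, dur] for lab, dur in config.schedule],
        "markers": (
            marker_positions(body.n, config.fs, at_start=True, at_end=True, taps=4)
            if config.markers
            else None
        ),
    }
    return SensorPair(body, clothing), log, truth


def write_truth_sidecar(truth: dict, path: str | os.PathLike) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return str(path)


def sample_labels(config: SynthConfig) -> np.ndarray:
    """Per-sample schedule label (ground truth for classifier checks)."""
    seg_samples = [int(round(dur * config.fs)) for _, dur in config.schedule]
    return np.repeat([lab for lab, _ in config.schedule], seg_samples)
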