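"""Gravity estimation and Rodrigues rotation so gravity lies on +y.

Sensors sewn into garments end up tilted relative to the body-worn
reference.  An accelerometer at rest measures the gravity reaction, so
the time-averaged direction of a quiet stretch of signal estimates the
sensor's gravity axis.  Each stream is then rotated by the minimal
rotation taking that direction onto the nominal gravity axis +y:

    R = I + sin(theta) K + (1 - cos(theta)) K^2

with K the cross-product matrix of the unit rotation axis
k = (g_hat x y_hat) / |g_hat x y_hat| and theta the angle between the
two vectors.  Rotation about gravity itself (heading) is unobservable
from an accelerometer alone and is deliberately left uncorrected; this
caps x/z-axis correlations between sensor pairs independently of any
garment effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import GravityEstimationError, ValidationError
from .types import AccelSeries

Y_AXIS = np.array([0.0, 1.0, 0.0])

_PARALLEL_EPS = 1e-12


def _skew(k: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [0.0, -k[2], k[1]],
            [k[2], 0.0, -k[0]],
            [-k[1], k[0], 0.0],
        ]
    )


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues' formula: rotation by `angle` (rad) about unit `axis`."""
    k = np.asarray(axis, dtype=np.float64)
    K = _skew(k)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class RotationSpec:
    """Axis-angle rotation with its matrix form.

    Invariants: unit axis; ``matrix`` orthonormal with determinant +1.
    """

    axis: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=np.float64)
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-8:
            raise ValidationError(f"rotation axis must be a unit vector; |axis|={norm}")
        object.__setattr__(self, "axis", axis / norm)
        object.__setattr__(self, "angle", float(self.angle))

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.axis, self.angle)

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(self.angle))

    @classmethod
    def identity(cls) -> "RotationSpec":
        return cls(np.array([1.0, 0.0, 0.0]), 0.0)

    @classmethod
    def from_matrix(cls, R: np.ndarray) -> "RotationSpec":
        """Recover axis/angle from a rotation matrix (axis arbitrary at 0)."""
        R = np.asarray(R, dtype=np.float64)
        angle = float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
        if angle < 1e-12:
            return cls.identity()
        if np.pi - angle < 1e-6:
            # near 180 deg: axis from the symmetric part, R ~ 2 kk^T - I
            M = (R + np.eye(3)) / 2.0
            k = np.sqrt(np.clip(np.diag(M), 0.0, None))
            i = int(np.argmax(k))
            k = M[:, i] / (k[i] if k[i] > 0 else 1.0)
            return cls(k / np.linalg.norm(k), angle)
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        return cls(w / np.linalg.norm(w), angle)

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate row vectors (shape (..., 3))."""
        return np.asarray(vectors) @ self.matrix.T

    def compose(self, other: "RotationSpec") -> "RotationSpec":
        """Rotation equivalent to applying `other` first, then self."""
        return RotationSpec.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RotationSpec":
        return RotationSpec(self.axis, -self.angle)


def rodrigues_from_to(v_from: np.ndarray, v_to: np.ndarray) -> RotationSpec:
    """Minimal rotation taking unit vector `v_from` onto unit vector `v_to`.

    Axis is ``v_from x v_to`` normalised; angle is
    ``atan2(|v_from x v_to|, v_from . v_to)``.  Degenerate cases:
    parallel vectors give the identity; antiparallel vectors give a
    180 deg rotation about a deterministic axis perpendicular to
    ``v_from`` (the coordinate axis least aligned with ``v_from``,
    projected onto its perpendicular plane — the x-axis whenever x is
    usable).
    """
    v_from = _unit(v_from, "v_from")
    v_to = _unit(v_to, "v_to")
    cross = np.cross(v_from, v_to)
    sin_t = np.linalg.norm(cross)
    cos_t = float(np.dot(v_from, v_to))
    if sin_t < _PARALLEL_EPS:
        if cos_t > 0:
            return RotationSpec.identity()
        # antiparallel: any axis perpendicular to v_from works; pick the
        # coordinate axis least aligned with v_from for determinism.
        i = int(np.argmin(np.abs(v_from)))
        e = np.zeros(3)
        e[i] = 1.0
        axis = e - np.dot(e, v_from) * v_from
        return RotationSpec(axis / np.linalg.norm(axis), np.pi)
    angle = float(np.arctan2(sin_t, cos_t))
    return RotationSpec(cross / sin_t, angle)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValidationError(f"{name} must be a non-zero vector")
    return v / norm


def estimate_gravity(
    series: AccelSeries,
    mode: str = "static_window",
    window: tuple[float, float] | None = None,
    static_window_s: float = 2.0,
) -> np.ndarray:
    """Estimate the unit gravity direction of a stream.

    Parameters
    ----------
    mode:
        ``"static_window"`` (default) — mean over the quietest
        (lowest total variance) ``static_window_s`` stretch; dynamic
        activity would bias the mean along the movement axis, so the
        stillest window is the best calibration surrogate.
        ``"low_pass_mean"`` — overall mean of a 0.25 Hz low-passed
        signal.
    window:
        Optional ``(start_s, end_s)`` restricting the search, e.g. a
        known calibration stance at the start of a recording.

    Raises
    ------
    GravityEstimationError
        If the candidate mean has magnitude below 0.5 g (free-fall-like
        or heavily corrupted data cannot anchor an orientation).
    """
    data = series.data
    fs = series.fs
    if window is not None:
        i0 = max(0, int(round(window[0] * fs)))
        i1 = min(series.n, int(round(window[1] * fs)))
        if i1 - i0 < 2:
            raise ValidationError(f"gravity window {window} selects <2 samples")
        data = data[i0:i1]
    if data.shape[0] < static_window_s * fs:
        raise ValidationError(
            f"need at least {static_window_s} s of data to estimate gravity"
        )

    if mode == "static_window":
        w = int(round(static_window_s * fs))
        c1 = np.vstack([np.zeros(3), np.cumsum(data, axis=0)])
        c2 = np.vstack([np.zeros(3), np.cumsum(data**2, axis=0)])
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        total_var = np.sum(s2 / w - (s1 / w) ** 2, axis=1)
        j = int(np.argmin(total_var))
        g = s1[j] / w
    elif mode == "low_pass_mean":
        nyq = fs / 2.0
        sos = signal.butter(4, min(0.25 / nyq, 0.99), btype="low", output="sos")
        g = signal.sosfiltfilt(sos, data, axis=0).mean(axis=0)
    else:
        raise ValidationError(f"unknown gravity mode {mode!r}")

    mag = np.linalg.norm(g)
    if mag < 0.5:
        raise GravityEstimationError(
            f"mean acceleration magnitude {mag:.3f} g is below 0.5 g; "
            "gravity direction unreliable"
        )
    return g / mag


def gravity_align(
    series: AccelSeries,
    mode: str = "static_window",
    window: tuple[float, float] | None = None,
) -> tuple[AccelSeries, RotationSpec]:
    """Rotate a stream so its estimated gravity direction maps to +y.

    Returns the rotated stream and the rotation applied.  Sample norms
    are preserved exactly (rotations are isometries); heading about
    gravity is untouched.
    """
    g = estimate_gravity(series, mode=mode, window=window)
    rot = rodrigues_from_to(g, Y_AXIS)
    return series.with_data(rot.apply(series.data)), rot
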