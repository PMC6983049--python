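import numpy as np
import pytest
from scipy import signal

from fabricmotion.errors import ValidationError
from fabricmotion.orientation import RotationSpec
from fabricmotion.synthetic_data import (
    ClothingChannelParams,
    SynthConfig,
    apply_clothing_transform,
    generate_body_stream,
    generate_sensor_pair,
    inject_markers,
    marker_positions,
)


def _static(label, dur=10.0, noise=0.0, seed=0):
    cfg = SynthConfig(schedule=((label, dur),), noise_sd=noise, seed=seed)
    return generate_body_stream(cfg)


class TestBodyStream:
    def test_standing_is_pure_y_gravity(self):
        series, _ = _static("standing")
        assert np.all(series.axis("y") == 1.0)
        assert np.all(series.axis("x") == 0.0)
        assert np.all(series.axis("z") == 0.0)

    def test_sitting_moves_gravity_to_z(self):
        series, _ = _static("sitting")
        assert np.all(series.axis("y") == 0.0)
        assert np.all(series.axis("z") == 1.0)

    def test_static_magnitude_exactly_one_g(self):
        for label in ("standing", "sitting"):
            series, _ = _static(label)
            np.testing.assert_allclose(series.magnitude(), 1.0, atol=1e-12)

    @pytest.mark.parametrize("label,stride", [("walking", 0.7), ("running", 0.3)])
    def test_gait_spectral_peak_at_step_frequency(self, label, stride):
        cfg = SynthConfig(schedule=((label, 30.0),), noise_sd=0.0, seed=0)
        series, _ = generate_body_stream(cfg)
        y = series.axis("y") - series.axis("y").mean()
        freqs, pxx = signal.periodogram(y, fs=series.fs)
        assert freqs[np.argmax(pxx)] == pytest.approx(2.0 / stride, abs=0.15)

    def test_log_matches_schedule(self):
        cfg = SynthConfig(
            schedule=(("standing", 10.0), ("walking", 20.0), ("sitting", 5.0)), seed=0
        )
        _, log = generate_body_stream(cfg)
        assert [e.label for e in log] == ["standing", "walking", "sitting"]
        assert [e.duration for e in log] == [10.0, 20.0, 5.0]

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(schedule=())

    def test_reproducible_and_seed_sensitive(self):
        a, _ = _static("standing", noise=0.05, seed=42)
        b, _ = _static("standing", noise=0.05, seed=42)
        c, _ = _static("standing", noise=0.05, seed=43)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


class TestClothingTransform:
    def test_identity_params_identity_output(self):
        body, _ = _static("standing", noise=0.02, seed=1)
        params = ClothingChannelParams(
            lag_samples=0,
            rotation=RotationSpec.identity(),
            swing_amp=0.0,
            amp_scale=1.0,
            noise_sd=0.0,
        )
        out = apply_clothing_transform(body, params, seed=0)
        np.testing.assert_array_equal(out.data, body.data)

    def test_injected_lag_found_by_cross_correlation(self):
        cfg = SynthConfig(
            schedule=(("standing", 10.0), ("walking", 30.0), ("standing", 10.0)),
            noise_sd=0.02,
            seed=2,
        )
        body, _ = generate_body_stream(cfg)
        params = ClothingChannelParams(lag_samples=38, swing_amp=0.0, noise_sd=0.02)
        cloth = apply_clothing_transform(body, params, seed=3)
        # independent check: numpy full cross-correlation of the centred
        # y channels, divided by the per-shift overlap length to undo
        # the triangular bias; interior slices skip the padded edge
        b = body.axis("y")[100:-100]
        c = cloth.axis("y")[100:-100]
        b = b - b.mean()
        c = c - c.mean()
        full = np.correlate(c, b, mode="full")
        n = len(b)
        overlap = n - np.abs(np.arange(-(n - 1), n))
        lags = np.arange(-(n - 1), n)
        keep = np.abs(lags) <= 100
        lag = int(lags[keep][np.argmax(full[keep] / overlap[keep])])
        assert lag == 38

    def test_rotation_of_static_gravity_closed_form(self):
        body, _ = _static("standing")
        angle = np.radians(30.0)
        params = ClothingChannelParams(
            lag_samples=0,
            rotation=RotationSpec(np.array([1.0, 0.0, 0.0]), angle),
            swing_amp=0.0,
            amp_scale=1.0,
            noise_sd=0.0,
        )
        out = apply_clothing_transform(body, params, seed=0)
        expected = np.array([0.0, np.cos(angle), np.sin(angle)])
        np.testing.assert_allclose(out.data, np.tile(expected, (body.n, 1)), atol=1e-12)

    def test_noise_free_transform_is_invertible(self):
        cfg = SynthConfig(schedule=(("walking", 20.0),), noise_sd=0.0, seed=4)
        body, _ = generate_body_stream(cfg)
        rot = RotationSpec(np.array([0.0, 0.6, 0.8]), 0.5)
        params = ClothingChannelParams(
            lag_samples=25, rotation=rot, swing_amp=0.0, amp_scale=1.3, noise_sd=0.0
        )
        cloth = apply_clothing_transform(body, params, seed=0)
        undone = rot.inverse().apply(cloth.data) / 1.3
        np.testing.assert_allclose(undone[25:], body.data[:-25], atol=1e-12)

    def test_lag_exceeding_length_rejected(self):
        body, _ = _static("standing", dur=2.0)
        with pytest.raises(ValidationError):
            apply_clothing_transform(
                body, ClothingChannelParams(lag_samples=body.n), seed=0
            )


class TestMarkers:
    def test_jump_and_four_taps_in_first_five_seconds(self):
        body, _ = _static("standing", dur=60.0)
        marked = inject_markers(body, at_start=True, at_end=False, taps=4)
        mag = marked.magnitude()[: int(5 * body.fs)]
        is_peak = (mag[1:-1] > mag[:-2]) & (mag[1:-1] > mag[2:]) & (mag[1:-1] > 3.0)
        assert int(is_peak.sum()) == 5  # one jump + four taps

    def test_no_markers_is_identity(self):
        body, _ = _static("standing", dur=60.0)
        out = inject_markers(body, at_start=False, at_end=False, taps=0)
        np.testing.assert_array_equal(out.data, body.data)

    def test_end_jump_is_global_max_of_tail(self):
        body, _ = _static("standing", dur=60.0)
        marked = inject_markers(body, at_start=False, at_end=True, taps=0)
        mag = marked.magnitude()
        assert np.argmax(mag) >= marked.n - int(2 * marked.fs)

    def test_positions_match_sidecar(self):
        body, _ = _static("standing", dur=60.0)
        marked = inject_markers(body, at_start=True, at_end=True, taps=4)
        pos = marker_positions(body.n, body.fs, at_start=True, at_end=True, taps=4)
        mag = marked.magnitude()
        assert mag[pos["jump_start"]] > 4.0
        assert mag[pos["jump_end"]] > 4.0
        for t in pos["taps"]:
            assert mag[t] > 3.0

    def test_too_short_series_rejected(self):
        body, _ = _static("standing", dur=2.0)
        with pytest.raises(ValidationError):
            inject_markers(body, at_start=True, taps=4)


def test_pair_truth_sidecar_reflects_parameters():
    cfg = SynthConfig(schedule=(("walking", 30.0),), seed=5, markers=False)
    params = ClothingChannelParams(lag_samples=12)
    pair, log, truth = generate_sensor_pair(cfg, params)
    assert truth["lag_samples"] == 12
    assert truth["rotation_angle_deg"] == pytest.approx(15.0)
    assert pair.body.n == pair.clothing.n
    assert len(log) == 1
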