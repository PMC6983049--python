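import numpy as np
import pytest
from hypothesis import given, strategies as st

from fabricmotion import alignment
from fabricmotion.errors import (
    MarkerNotFoundError,
    UndefinedCorrelationError,
    ValidationError,
)
from fabricmotion.synthetic_data import (
    SynthConfig,
    generate_body_stream,
    inject_markers,
    marker_positions,
)
from fabricmotion.types import AccelSeries, SensorPair


def _flat(n=500, fs=50.0):
    return AccelSeries(np.tile([0.0, 1.0, 0.0], (n, 1)), fs=fs)


def _spike_series(positions, heights, n=500, fs=50.0):
    data = np.tile([0.0, 1.0, 0.0], (n, 1))
    for p, h in zip(positions, heights):
        data[p, 1] += h
    return AccelSeries(data, fs=fs)


class TestMarkerDetection:
    def test_injected_jump_found(self):
        cfg = SynthConfig(schedule=(("standing", 60.0),), noise_sd=0.02, seed=1)
        series, _ = generate_body_stream(cfg)
        marked = inject_markers(series, at_start=True, taps=0)
        truth = marker_positions(series.n, series.fs, at_start=True, taps=0)
        found = alignment.detect_jump_marker(marked, window=(0.0, 5.0))
        assert abs(found - truth["jump_start"]) <= 2

    def test_flat_series_has_no_marker(self):
        with pytest.raises(MarkerNotFoundError):
            alignment.detect_jump_marker(_flat(), window=(0.0, 5.0))

    def test_argmax_picks_larger_of_two_spikes(self):
        series = _spike_series([100, 300], [3.0, 4.0])
        assert alignment.detect_jump_marker(series, window=(0.0, 10.0)) == 300

    def test_four_taps_recovered(self):
        cfg = SynthConfig(schedule=(("standing", 60.0),), noise_sd=0.02, seed=2)
        series, _ = generate_body_stream(cfg)
        marked = inject_markers(series, at_start=False, taps=4)
        truth = marker_positions(series.n, series.fs, at_start=False, taps=4)
        found = alignment.detect_taps(marked, n=4, window=(0.0, 5.0))
        assert len(found) == 4
        assert all(abs(f - t) <= 2 for f, t in zip(found, truth["taps"]))

    def test_single_spike_single_tap(self):
        series = _spike_series([250], [3.0])
        assert alignment.detect_taps(series, n=1, window=(0.0, 10.0)) == [250]

    def test_flat_series_has_no_taps(self):
        with pytest.raises(MarkerNotFoundError):
            alignment.detect_taps(_flat(), n=4, window=(0.0, 10.0))


class TestCoarseAlign:
    @pytest.fixture()
    def marked_stream(self):
        cfg = SynthConfig(schedule=(("standing", 120.0),), noise_sd=0.02, seed=3)
        series, _ = generate_body_stream(cfg)
        return inject_markers(series, at_start=True, taps=0)

    def test_known_offset_removed(self, marked_stream):
        body = marked_stream
        # clothing recording started 2 s earlier: 100 pre-roll samples
        clothing = AccelSeries(
            np.vstack([np.tile(marked_stream.data[0], (100, 1)), marked_stream.data[:-100]]),
            fs=marked_stream.fs,
        )
        aligned = alignment.coarse_align(SensorPair(body, clothing))
        jb = alignment.detect_jump_marker(aligned.body, window=(0.0, 5.0))
        jc = alignment.detect_jump_marker(aligned.clothing, window=(0.0, 5.0))
        assert jb == jc
        assert aligned.body.n == aligned.clothing.n

    def test_already_aligned_unchanged(self, marked_stream):
        pair = SensorPair(marked_stream, marked_stream)
        aligned = alignment.coarse_align(pair)
        np.testing.assert_array_equal(aligned.body.data, marked_stream.data)
        np.testing.assert_array_equal(aligned.clothing.data, marked_stream.data)

    def test_disjoint_recordings_rejected(self, marked_stream):
        with pytest.raises(ValidationError, match="overlap"):
            alignment.shift_pair(
                SensorPair(marked_stream, marked_stream), marked_stream.n
            )


def _xcorr_oracle(x, y, max_lag):
    """O(n^2) sliding product-moment oracle, ties toward smallest |lag|."""
    n = len(x)
    best = (0, -np.inf)
    for k in sorted(range(-max_lag, max_lag + 1), key=lambda q: (abs(q), q)):
        u, v = (x[: n - k], y[k:]) if k >= 0 else (x[-k:], y[: n + k])
        mu, mv = np.mean(u), np.mean(v)
        num = float(np.sum((u - mu) * (v - mv)))
        den = float(np.sqrt(np.sum((u - mu) ** 2) * np.sum((v - mv) ** 2)))
        if den == 0:
            continue
        r = num / den
        if r > best[1] + 1e-15:
            best = (k, r)
    return best


class TestLagEstimation:
    def test_canonical_38_sample_lag(self, canonical_pair):
        pair, _, truth = canonical_pair
        est = alignment.estimate_lag_xcorr(pair.body, pair.clothing, axis="y", max_lag=100)
        assert est.lag_samples == truth["lag_samples"] == 38
        assert est.lag_seconds == pytest.approx(0.76)

    def test_identical_signals_zero_lag_unit_peak(self):
        cfg = SynthConfig(schedule=(("walking", 30.0),), noise_sd=0.02, seed=4)
        series, _ = generate_body_stream(cfg)
        est = alignment.estimate_lag_xcorr(series, series, axis="y", max_lag=50)
        assert est.lag_samples == 0
        assert est.peak_xcorr == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("shift", [-23, 0, 17])
    def test_matches_bruteforce_oracle(self, shift):
        rng = np.random.default_rng(100 + shift)
        x = rng.normal(size=400)
        y = np.roll(x, shift) + 0.2 * rng.normal(size=400)
        est = alignment.estimate_lag_xcorr(x, y, max_lag=40)
        o_lag, o_r = _xcorr_oracle(x, y, 40)
        assert est.lag_samples == o_lag
        assert est.peak_xcorr == pytest.approx(o_r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            alignment.estimate_lag_xcorr(_flat(), _flat(), axis="y", max_lag=10)

    def test_tie_breaks_toward_zero_lag(self):
        # an exactly periodic integer pattern ties bit-for-bit at every
        # multiple of its period; the smallest |lag| must win
        x = np.tile([0.0, 1.0, 2.0, 1.0, 0.0, -1.0, -2.0, -1.0], 64)
        est = alignment.estimate_lag_xcorr(x, x.copy(), max_lag=20)
        assert est.lag_samples == 0

    def test_too_short_for_search_range(self):
        with pytest.raises(ValidationError):
            alignment.estimate_lag_xcorr(np.ones(50), np.ones(50), max_lag=40)

    @given(extra=st.integers(min_value=-15, max_value=15))
    def test_shift_equivariance(self, extra):
        rng = np.random.default_rng(7)
        x = rng.normal(size=600)
        base_shift = 10
        y = np.roll(x, base_shift + extra)
        est = alignment.estimate_lag_xcorr(x, y, max_lag=40)
        # rolled signals wrap, but the wrapped fraction is small enough
        # that the periodic peak structure still dominates at the true lag
        assert est.lag_samples == base_shift + extra


class TestApplyLag:
    def test_zero_lag_is_identity(self, canonical_pair):
        pair, _, _ = canonical_pair
        out = alignment.apply_lag(pair.body, 0)
        np.testing.assert_array_equal(out.data, pair.body.data)

    def test_shift_then_unshift_recovers_overlap(self, canonical_pair):
        pair, _, _ = canonical_pair
        s = pair.body
        once = alignment.apply_lag(s, 20)
        back = alignment.apply_lag(once, -20)
        np.testing.assert_array_equal(back.data, s.data[20:-20])

    def test_reestimated_lag_is_zero_after_alignment(self, canonical_pair):
        pair, _, _ = canonical_pair
        est = alignment.estimate_lag_xcorr(pair.body, pair.clothing, axis="y", max_lag=100)
        aligned = alignment.apply_lag_pair(pair, est)
        re_est = alignment.estimate_lag_xcorr(
            aligned.body, aligned.clothing, axis="y", max_lag=100
        )
        assert re_est.lag_samples == 0

    def test_lag_of_series_length_rejected(self):
        with pytest.raises(ValidationError):
            alignment.apply_lag(_flat(100), 100)
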