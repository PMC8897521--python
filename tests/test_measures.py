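"""Scalar component measures against arithmetic and oversampled oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laterp.measures import (
    fractional_area_latency,
    jackknife_latency_analysis,
    mean_amplitude,
    onset_threshold_crossing,
    signed_negative_area,
)
from laterp.synth import raised_cosine
from laterp.waveforms import DifferenceWave

from conftest import EPOCH_TIMES

TIMES = EPOCH_TIMES


def wave_from(values):
    return DifferenceWave(values=np.asarray(values, dtype=float), times=TIMES)


def smooth_random_wave(rng, scale=2.0):
    """Band-limited random wave (cumulative-summed noise, demeaned)."""
    raw = rng.normal(size=TIMES.size)
    kernel = np.hanning(31)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    return wave_from(scale * (smooth - smooth.mean()) / smooth.std())


# -- 10x-oversampled brute-force oracles (independent of the implementation) --

def _dense(values, factor=10):
    t_dense = np.linspace(TIMES[0], TIMES[-1], (TIMES.size - 1) * factor + 1)
    return t_dense, np.interp(t_dense, TIMES, values)


def oracle_negative_area(values, window):
    t, v = _dense(values)
    m = (t >= window[0]) & (t <= window[1])
    return -np.trapezoid(np.minimum(v[m], 0.0), t[m])


def oracle_fractional_latency(values, window, fraction=0.5):
    t, v = _dense(values)
    m = (t >= window[0]) & (t <= window[1])
    t, v = t[m], np.minimum(v[m], 0.0)
    seg = 0.5 * np.diff(t) * (v[:-1] + v[1:])
    total = seg.sum()
    if total >= 0:
        return None
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = np.searchsorted(-cum, -fraction * total)
    return t[k - 1] + (t[k] - t[k - 1]) * (fraction * total - cum[k - 1]) / seg[k - 1]


def oracle_onset(values, window, threshold):
    t, v = _dense(values)
    m = (t >= window[0]) & (t <= window[1])
    t, v = t[m], v[m]
    hits = np.flatnonzero(v <= threshold)
    if hits.size == 0:
        return None
    i = hits[0]
    if i == 0:
        return t[0]
    return t[i - 1] + (t[i] - t[i - 1]) * (threshold - v[i - 1]) / (v[i] - v[i - 1])


class TestMeanAmplitude:
    def test_constant_wave(self):
        assert mean_amplitude(wave_from(np.full(TIMES.size, -2.0))).value == pytest.approx(-2.0)

    def test_balanced_positive_negative_wave_near_zero(self):
        values = np.zeros(TIMES.size)
        values[(TIMES >= 200) & (TIMES <= 248)] = 1.0
        values[(TIMES >= 252) & (TIMES <= 300)] = -1.0
        assert abs(mean_amplitude(wave_from(values)).value) < 0.03

    def test_full_window_raised_cosine_mean(self):
        """A -2 uV raised cosine spanning exactly 200-300 ms has a continuous
        window mean of -1 uV (half the peak)."""
        values = raised_cosine(TIMES, 200.0, 100.0, -2.0)
        assert mean_amplitude(wave_from(values)).value == pytest.approx(-1.0, abs=0.02)

    def test_linearity(self, rng):
        a, b = smooth_random_wave(rng), smooth_random_wave(rng)
        lhs = mean_amplitude(wave_from(2.0 * a.values + b.values)).value
        rhs = 2.0 * mean_amplitude(a).value + mean_amplitude(b).value
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            mean_amplitude(wave_from(np.zeros(TIMES.size)), (400.0, 600.0))


class TestSignedNegativeArea:
    def test_nonnegative_wave_has_zero_area(self):
        assert signed_negative_area(wave_from(np.abs(np.sin(TIMES)))).value == 0.0

    def test_constant_negative_rectangle(self):
        res = signed_negative_area(wave_from(np.full(TIMES.size, -1.0)))
        assert res.value == pytest.approx(150.0)
        assert res.units == "uV*ms"

    def test_matches_oversampled_oracle_on_random_waves(self, rng):
        for _ in range(20):
            w = smooth_random_wave(rng)
            expected = oracle_negative_area(w.values, (150.0, 300.0))
            if expected < 1.0:
                continue
            assert signed_negative_area(w).value == pytest.approx(expected, rel=0.005)

    @given(c=st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_negative_shift_adds_exact_area(self, c):
        base = np.zeros(TIMES.size)
        shifted = signed_negative_area(wave_from(base - c)).value
        assert shifted == pytest.approx(c * 150.0, rel=1e-9)


class TestFractionalAreaLatency:
    def test_symmetric_pulse_bisects_at_center(self):
        values = raised_cosine(TIMES, 185.0, 80.0, -2.0)  # centered at 225 ms
        assert fractional_area_latency(wave_from(values)).value == pytest.approx(225.0, abs=0.5)

    def test_nonnegative_wave_undefined(self):
        res = fractional_area_latency(wave_from(np.ones(TIMES.size)))
        assert not res.defined
        assert np.isnan(res.value)

    def test_two_rectangle_wave_splits_at_step(self):
        values = np.zeros(TIMES.size)
        values[(TIMES >= 150) & (TIMES < 200)] = -2.0
        values[(TIMES >= 200) & (TIMES <= 300)] = -1.0
        res = fractional_area_latency(wave_from(values))
        # continuous-wave arithmetic puts the 50% point at 200 ms; sampling at
        # 2 ms shifts it by less than one sample
        assert res.value == pytest.approx(200.0, abs=1.0)
        expected = oracle_fractional_latency(values, (150.0, 300.0))
        assert res.value == pytest.approx(expected, abs=0.2)

    def test_matches_oversampled_oracle_on_random_waves(self, rng):
        checked = 0
        for _ in range(30):
            w = smooth_random_wave(rng)
            expected = oracle_fractional_latency(w.values, (150.0, 300.0))
            if expected is None:
                continue
            assert fractional_area_latency(w).value == pytest.approx(expected, abs=1.0)
            checked += 1
        assert checked > 10

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fractional_area_latency(wave_from(np.zeros(TIMES.size)), fraction=1.5)


class TestOnsetThresholdCrossing:
    def test_linear_ramp_interpolated_crossing(self):
        values = np.zeros(TIMES.size)
        m = TIMES >= 150
        values[m] = -1.5 * (TIMES[m] - 150.0) / 150.0
        res = onset_threshold_crossing(wave_from(values))
        assert res.value == pytest.approx(225.0, abs=1e-9)

    def test_threshold_never_reached_undefined(self):
        res = onset_threshold_crossing(wave_from(np.full(TIMES.size, -0.4)))
        assert not res.defined

    def test_noiseless_pulse_recovers_analytic_crossing(self):
        values = raised_cosine(TIMES, 180.0, 120.0, -3.0)
        # analytic: -3/2 (1 - cos(2 pi tau/120)) = -0.75 -> tau
        tau = 120.0 / (2 * np.pi) * np.arccos(1.0 - 2.0 * 0.75 / 3.0)
        res = onset_threshold_crossing(wave_from(values))
        assert res.value == pytest.approx(180.0 + tau, abs=2.0)

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ValueError):
            onset_threshold_crossing(wave_from(np.zeros(TIMES.size)), threshold_uv=0.5)

    def test_sustained_crossing_skips_single_sample_dips(self):
        values = np.zeros(TIMES.size)
        dip = int(np.argmin(np.abs(TIMES - 200.0)))
        values[dip] = -1.0  # one-sample dip
        values[(TIMES >= 250) & (TIMES <= 290)] = -1.0  # sustained dip
        first = onset_threshold_crossing(wave_from(values), n_sustained=1)
        sustained = onset_threshold_crossing(wave_from(values), n_sustained=3)
        assert first.value < 202.0
        assert sustained.value >= 248.0


class TestJackknifeLatencyAnalysis:
    def _waves(self, onsets, rng=None, noise=0.0):
        out = []
        for i, onset in enumerate(onsets):
            values = raised_cosine(TIMES, onset, 150.0, -3.0)
            if noise and rng is not None:
                values = values + rng.normal(scale=noise, size=TIMES.size)
            out.append(DifferenceWave(values=values, times=TIMES, participant_id=str(i)))
        return out

    def test_identical_waves_zero_variance_flagged(self):
        waves = {("patterned", "exemplar_match"): self._waves([180.0] * 4),
                 ("random", "exemplar_match"): self._waves([220.0] * 4)}
        res = jackknife_latency_analysis(waves)
        cmp_ = res.comparisons[0]
        assert np.isnan(cmp_.t_corrected)
        assert "zero variance" in cmp_.note

    def test_back_transformation_recovers_full_sample_latency(self):
        # equal-slope ramps: the crossing latency is linear in the per-wave
        # onset, so the jackknife identity mean(scores) = L_all is exact
        waves = []
        for t0 in (170.0, 180.0, 190.0):
            values = np.minimum(0.0, -0.05 * (TIMES - t0))
            waves.append(DifferenceWave(values=values, times=TIMES))
        res = jackknife_latency_analysis({("patterned", "exemplar_match"): waves})
        cond = ("patterned", "exemplar_match")
        assert np.mean(res.scores[cond]) == pytest.approx(res.full_latency[cond], abs=1e-9)

    def test_condition_failing_threshold_excluded_from_contrasts(self):
        flat = [DifferenceWave(values=np.zeros(TIMES.size), times=TIMES)
                for _ in range(4)]
        waves = {("patterned", "exemplar_match"): self._waves([170, 180, 190, 200]),
                 ("patterned", "foil"): flat}
        res = jackknife_latency_analysis(waves)
        assert not res.defined[("patterned", "foil")]
        assert res.comparisons == []

    def test_separated_onsets_detected(self, rng):
        waves = {
            ("patterned", "exemplar_match"): self._waves(
                np.linspace(155, 165, 8), rng, noise=0.05),
            ("random", "exemplar_match"): self._waves(
                np.linspace(215, 225, 8), rng, noise=0.05),
        }
        res = jackknife_latency_analysis(waves)
        cmp_ = res.comparisons[0]
        assert cmp_.mean_a_ms < cmp_.mean_b_ms
        assert cmp_.p_value < 0.01
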