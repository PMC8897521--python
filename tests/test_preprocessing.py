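"""Re-referencing, zero-phase filtering, baseline correction and rejection."""

import numpy as np
import pandas as pd
import pytest

from laterp.preprocessing import (
    FilterSpec,
    RejectionCriteria,
    baseline_correct,
    filter_epochs,
    reject_artifacts,
    rereference_to_earlobes,
    select_analysis_trials,
)
from laterp.synth import MINIMAL_CHANNELS, GroundTruth, simulate_epochs

from conftest import EPOCH_TIMES, exemplar_only_schedule, make_epochs


class TestRereference:
    CHANNELS = ("PO7", "PO8", "A1", "A2")

    def test_zero_earlobes_leave_data_unchanged(self, rng):
        data = rng.normal(size=(3, 4, 301))
        data[:, 2:, :] = 0.0
        ep = make_epochs(data, self.CHANNELS)
        out = rereference_to_earlobes(ep)
        assert out.channels == ["PO7", "PO8"]
        np.testing.assert_array_equal(out.data, data[:, :2, :])

    def test_channels_equal_to_earlobe_mean_become_zero(self):
        data = np.ones((2, 4, 301)) * 5.0
        out = rereference_to_earlobes(make_epochs(data, self.CHANNELS))
        np.testing.assert_allclose(out.data, 0.0)

    def test_matches_hand_computed_subtraction(self, rng):
        data = rng.normal(size=(2, 4, 301))
        out = rereference_to_earlobes(make_epochs(data, self.CHANNELS))
        expected = data[:, :2, :] - data[:, 2:, :].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.data, expected)

    def test_missing_earlobes_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(1, 2, 301)), ("PO7", "PO8"))
        with pytest.raises(ValueError, match="earlobe"):
            rereference_to_earlobes(ep)


class TestFilterEpochs:
    def _tone(self, freq_hz, n=301):
        t = EPOCH_TIMES[:n] / 1000.0
        return np.sin(2 * np.pi * freq_hz * t)[None, None, :]

    def test_passband_tone_preserved(self):
        ep = make_epochs(self._tone(5.0), ("Cz",))
        out = filter_epochs(ep, FilterSpec(highpass_hz=None, notch_hz=None))
        core = slice(50, 251)  # avoid edge transients
        ratio = np.abs(out.data[0, 0, core]).max() / np.abs(ep.data[0, 0, core]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_notch_attenuates_line_frequency(self):
        # long tone so the high-Q notch reaches steady state away from the edges
        n = 2001
        t = np.arange(n) / 500.0
        tone = np.sin(2 * np.pi * 60.0 * t)[None, None, :]
        ep = make_epochs(tone, ("Cz",), times=np.arange(n) * 2.0)
        out = filter_epochs(ep, FilterSpec(lowpass_hz=None, highpass_hz=None))
        core = slice(500, 1501)
        ratio = np.abs(out.data[0, 0, core]).max() / np.abs(ep.data[0, 0, core]).max()
        assert ratio < 1 / 20

    def test_zero_phase_keeps_extremum_position(self):
        data = np.zeros((1, 1, 301))
        data[0, 0, 150] = 1.0
        out = filter_epochs(make_epochs(data, ("Cz",)), FilterSpec(highpass_hz=None,
                                                                   notch_hz=None))
        assert np.argmax(out.data[0, 0]) == 150

    def test_cutoff_beyond_nyquist_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 301)), ("Cz",))
        with pytest.raises(ValueError, match="Nyquist"):
            filter_epochs(ep, FilterSpec(lowpass_hz=260.0))


class TestBaselineCorrect:
    def test_constant_trace_becomes_zero(self):
        out = baseline_correct(make_epochs(np.full((2, 1, 301), 3.0), ("Cz",)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_mean_is_zero_after_correction(self, rng):
        ep = make_epochs(rng.normal(size=(4, 2, 301)), ("PO7", "PO8"))
        out = baseline_correct(ep)
        mask = out.time_mask((-100.0, 0.0))
        np.testing.assert_allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-9)

    def test_two_segment_trace_shifts_post_segment(self):
        data = np.where(EPOCH_TIMES[None, None, :] <= 0.0, 1.0, 4.0)
        out = baseline_correct(make_epochs(data, ("Cz",)))
        post = out.data[0, 0, EPOCH_TIMES > 0]
        np.testing.assert_allclose(post, 3.0)

    def test_idempotent(self, rng):
        ep = make_epochs(rng.normal(size=(3, 2, 301)), ("PO7", "PO8"))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(1, 1, 301)), ("Cz",))
        with pytest.raises(ValueError):
            baseline_correct(ep, (-100.0, -200.0))


class TestRejectArtifacts:
    def _epochs(self, heog_value, at_ms):
        data = np.zeros((1, 4, 301))
        idx = int(np.argmin(np.abs(EPOCH_TIMES - at_ms)))
        data[0, 2, idx] = heog_value
        return make_epochs(data, ("PO7", "PO8", "HEOG", "VEOG"))

    def test_clean_data_keeps_everything(self, rng):
        ep = make_epochs(rng.normal(scale=1.0, size=(5, 4, 301)))
        report = reject_artifacts(ep)
        assert report.retained.n_trials == 5
        assert not report.rejected.any()

    def test_heog_excursion_inside_window_rejected(self):
        report = reject_artifacts(self._epochs(30.0, at_ms=100.0))
        assert report.rejected.tolist() == [True]
        assert report.counts["heog"] == 1

    def test_heog_excursion_outside_window_retained(self):
        report = reject_artifacts(self._epochs(30.0, at_ms=-50.0))
        assert report.rejected.tolist() == [False]

    def test_rejection_monotone_in_thresholds(self, rng):
        ep = make_epochs(rng.normal(scale=30.0, size=(40, 4, 301)))
        strict = reject_artifacts(ep, RejectionCriteria())
        loose = reject_artifacts(
            ep, RejectionCriteria(heog_abs_uv=50.0, veog_abs_uv=120.0, other_abs_uv=160.0)
        )
        assert np.all(loose.rejected <= strict.rejected)

    def test_rejected_set_equals_injected_set_without_noise(self):
        sch = exemplar_only_schedule(n_blocks=2, seed=8)
        truth = GroundTruth.default(noise_sd_uv=0.0, artifact_rate=0.3)
        ep = simulate_epochs(sch, truth, seed=5, channels=MINIMAL_CHANNELS)
        report = reject_artifacts(ep)
        np.testing.assert_array_equal(report.rejected,
                                      ep.trials["injected_artifact"].to_numpy())


class TestSelectAnalysisTrials:
    def test_identity_when_all_correct_lateralized(self):
        trials = pd.DataFrame({"correct": [True] * 3,
                               "trial_type": ["exemplar_match", "foil", "foil"]})
        ep = make_epochs(np.zeros((3, 1, 301)), ("Cz",), trials=trials)
        assert select_analysis_trials(ep).n_trials == 3

    def test_mixed_fixture_counts(self):
        trials = pd.DataFrame(
            {"correct": [True, True, True, False, True, True],
             "trial_type": ["exemplar_match"] * 4 + ["target_absent"] * 2}
        )
        ep = make_epochs(np.arange(6)[:, None, None] * np.ones((6, 1, 301)), ("Cz",),
                         trials=trials)
        out = select_analysis_trials(ep)
        assert out.n_trials == 3
        np.testing.assert_array_equal(out.data[:, 0, 0], [0.0, 1.0, 2.0])

    def test_all_target_absent_warns_and_empties(self):
        trials = pd.DataFrame({"correct": [True, True],
                               "trial_type": ["target_absent"] * 2})
        ep = make_epochs(np.zeros((2, 1, 301)), ("Cz",), trials=trials)
        with pytest.warns(UserWarning, match="no analyzable"):
            out = select_analysis_trials(ep)
        assert out.n_trials == 0

    def test_misaligned_metadata_rejected(self):
        ep = make_epochs(np.zeros((2, 1, 301)), ("Cz",))
        with pytest.raises(ValueError, match="aligned"):
            select_analysis_trials(ep, pd.DataFrame({"correct": [True],
                                                     "trial_type": ["foil"]}))
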