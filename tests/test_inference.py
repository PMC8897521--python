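"""Permutation, cluster and bootstrap-SME inference machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laterp.inference import (
    bootstrap_sme,
    cluster_permutation_null,
    cluster_t_mass,
    percentile_criterion,
    rms_aggregate,
    signed_area_permutation_test,
)
from laterp.synth import MINIMAL_CHANNELS, ComponentParams, GroundTruth, simulate_epochs

from conftest import EPOCH_TIMES, exemplar_only_schedule

TIMES = EPOCH_TIMES


def _participants(n_parts, amplitude=0.0, noise=8.0, seed=0, n_blocks=1,
                  onset_patterned=180.0, onset_random=180.0):
    rng = np.random.default_rng(seed)
    base = ComponentParams(amplitude_uv=amplitude, width_ms=150.0, noise_sd_uv=noise)
    truth = GroundTruth(
        conditions={
            ("patterned", "exemplar_match"): ComponentParams(
                amplitude_uv=amplitude, onset_ms=onset_patterned, width_ms=150.0,
                noise_sd_uv=noise),
            ("random", "exemplar_match"): ComponentParams(
                amplitude_uv=amplitude, onset_ms=onset_random, width_ms=150.0,
                noise_sd_uv=noise),
            ("patterned", "foil"): base, ("random", "foil"): base,
        },
        absent=ComponentParams(amplitude_uv=0.0, noise_sd_uv=noise),
    )
    out = []
    for i in range(n_parts):
        sch = exemplar_only_schedule(n_blocks=n_blocks, seed=rng,
                                     pattern_side="left" if i % 2 else "right")
        out.append(simulate_epochs(sch, truth, seed=rng, channels=MINIMAL_CHANNELS))
    return out


class TestPercentileCriterion:
    def test_observed_beyond_all_null(self, rng):
        null = rng.normal(size=500)
        significant, p = percentile_criterion(null.max() + 1.0, null)
        assert significant
        assert p == pytest.approx(1 / 501)

    def test_observed_at_median_not_significant(self, rng):
        null = rng.normal(size=501)
        significant, p = percentile_criterion(float(np.median(null)), null)
        assert not significant
        assert p == pytest.approx(0.5, abs=0.05)

    def test_nearest_rank_boundary_matches_rank_arithmetic(self, rng):
        null = rng.uniform(size=500)
        critical = np.sort(null)[int(np.ceil(0.95 * 500)) - 1]
        just_above = np.nextafter(critical, 2.0)
        assert percentile_criterion(just_above, null)[0]
        assert not percentile_criterion(critical, null)[0]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            percentile_criterion(0.0, [1.0, np.nan])


class TestSignedAreaPermutation:
    def test_extreme_observation_gives_add_one_p(self):
        # strong signal in both symbol positions, low noise: every condition's
        # observed area should exceed all permuted values
        parts = _participants(4, amplitude=-4.0, noise=1.0, seed=1)
        res = signed_area_permutation_test(parts, n_permutations=500, seed=2)
        for cond in (("patterned", "exemplar_match"), ("random", "exemplar_match")):
            assert res[cond].significant
            assert res[cond].p_value == pytest.approx(1 / 501)

    def test_equal_injection_in_both_positions_both_significant(self):
        parts = _participants(6, amplitude=-3.0, noise=2.0, seed=3)
        res = signed_area_permutation_test(parts, n_permutations=200, seed=4)
        assert res[("patterned", "exemplar_match")].significant
        assert res[("random", "exemplar_match")].significant
        a = res[("patterned", "exemplar_match")].observed
        b = res[("random", "exemplar_match")].observed
        assert abs(a - b) / max(a, b) < 0.25

    def test_determinism_and_p_grid(self):
        parts = _participants(3, amplitude=-1.0, noise=5.0, seed=5)
        r1 = signed_area_permutation_test(parts, n_permutations=150, seed=9)
        r2 = signed_area_permutation_test(parts, n_permutations=150, seed=9)
        for cond in r1:
            np.testing.assert_array_equal(r1[cond].null_distribution,
                                          r2[cond].null_distribution)
            # permutation p lives on the add-one grid
            assert (r1[cond].p_value * 151) == pytest.approx(round(r1[cond].p_value * 151))

    def test_participant_missing_label_excluded_with_warning(self):
        parts = _participants(3, amplitude=-1.0, noise=5.0, seed=6)
        bad = parts[0].select_trials(
            parts[0].trials["symbol_position"].to_numpy() == "patterned"
        )
        with pytest.warns(UserWarning, match="excluded"):
            res = signed_area_permutation_test([bad] + parts[1:], n_permutations=120,
                                               seed=0)
        assert res[("patterned", "exemplar_match")].n_permutations == 120


class TestClusterTMass:
    TIMES76 = 150.0 + 2.0 * np.arange(76)

    def test_exactly_at_chance_no_clusters(self):
        acc = np.full((6, 76), 0.5)
        with pytest.warns(UserWarning, match="zero variance"):
            res = cluster_t_mass(acc, self.TIMES76)
        assert res.clusters == []

    def test_perfect_accuracy_single_full_window_cluster(self):
        acc = np.ones((6, 76))
        with pytest.warns(UserWarning, match="zero variance"):
            res = cluster_t_mass(acc, self.TIMES76)
        assert len(res.clusters) == 1
        assert res.clusters[0].start_ms == 150.0
        assert res.clusters[0].end_ms == 300.0

    def test_two_separated_runs_with_hand_computed_masses(self):
        n = 8
        offsets = np.linspace(-0.02, 0.02, n)  # per-participant jitter, sd known
        acc = np.full((n, 76), 0.5) + offsets[:, None]
        acc[:, 10:15] += 0.2
        acc[:, 40:48] += 0.2
        res = cluster_t_mass(acc, self.TIMES76)
        assert len(res.clusters) == 2
        sd = np.std(offsets, ddof=1)
        t_expected = 0.2 / (sd / np.sqrt(n))
        np.testing.assert_allclose(res.clusters[0].t_mass, 5 * t_expected, rtol=1e-9)
        np.testing.assert_allclose(res.clusters[1].t_mass, 8 * t_expected, rtol=1e-9)
        assert (res.clusters[0].start_ms, res.clusters[0].end_ms) == (170.0, 178.0)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_t_mass(np.full((2, 76), 0.6), self.TIMES76)


class TestClusterPermutationNull:
    TIMES76 = 150.0 + 2.0 * np.arange(76)

    def test_same_seed_identical_null(self, rng):
        acc = 0.5 + rng.normal(scale=0.05, size=(8, 76))
        a = cluster_permutation_null(acc, self.TIMES76, n_permutations=150, seed=3)
        b = cluster_permutation_null(acc, self.TIMES76, n_permutations=150, seed=3)
        np.testing.assert_array_equal(a.null_t_mass, b.null_t_mass)

    def test_strong_signal_yields_wide_significant_cluster(self, rng):
        acc = 0.8 + rng.normal(scale=0.03, size=(19, 76))
        res = cluster_permutation_null(acc, self.TIMES76, n_permutations=200, seed=1)
        assert any(cl.significant for cl in res.clusters)
        widest = max(res.clusters, key=lambda c: c.end_ms - c.start_ms)
        assert (widest.end_ms - widest.start_ms) >= 0.9 * 150.0

    def test_coarse_permutation_count_warns(self, rng):
        acc = 0.5 + rng.normal(scale=0.05, size=(5, 20))
        with pytest.warns(UserWarning, match="coarse"):
            cluster_permutation_null(acc, self.TIMES76[:20], n_permutations=50, seed=0)

    def test_custom_null_sampler_used(self, rng):
        acc = 0.5 + rng.normal(scale=0.05, size=(5, 20))
        calls = []

        def sampler(r):
            calls.append(1)
            return 0.5 + r.normal(scale=0.05, size=(5, 20))

        cluster_permutation_null(acc, self.TIMES76[:20], n_permutations=120,
                                 seed=0, null_sampler=sampler)
        assert len(calls) == 120


class TestBootstrapSME:
    def test_identical_trials_zero_bsme(self):
        trials = np.tile(np.sin(TIMES / 40.0), (10, 1))
        res = bootstrap_sme(trials, TIMES, "mean_amplitude", n_bootstrap=300, seed=0)
        assert res.bsme == 0.0

    def test_mean_amplitude_bsme_close_to_analytic_se(self, rng):
        # white-noise trials: SE of the window-averaged mean is sigma/sqrt(n*m)
        sigma, n = 10.0, 60
        trials = rng.normal(scale=sigma, size=(n, TIMES.size))
        res = bootstrap_sme(trials, TIMES, "mean_amplitude", (200.0, 300.0),
                            n_bootstrap=3000, seed=1)
        m = np.sum((TIMES >= 200) & (TIMES <= 300))
        assert res.bsme == pytest.approx(sigma / np.sqrt(n * m), rel=0.10)

    def test_quadrupling_trials_halves_bsme(self, rng):
        sigma = 8.0
        trials = rng.normal(scale=sigma, size=(160, TIMES.size))
        small = bootstrap_sme(trials[:40], TIMES, "mean_amplitude",
                              n_bootstrap=2000, seed=2)
        large = bootstrap_sme(trials, TIMES, "mean_amplitude",
                              n_bootstrap=2000, seed=3)
        assert large.bsme / small.bsme == pytest.approx(0.5, abs=0.1)

    def test_undefined_latency_iterations_counted(self, rng):
        # mostly-positive trials: many bootstrap averages carry no negative area
        trials = 1.0 + rng.normal(scale=0.1, size=(10, TIMES.size))
        res = bootstrap_sme(trials, TIMES, "fractional_area_latency",
                            n_bootstrap=200, seed=4)
        assert not res.defined or res.n_undefined > 0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sme(np.zeros((1, TIMES.size)), TIMES)


class TestRMSAggregate:
    def test_equal_values_identity(self):
        assert rms_aggregate([2.5] * 19) == pytest.approx(2.5)

    def test_three_four(self):
        assert rms_aggregate([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_brute_force(self, rng):
        values = rng.uniform(0.1, 5.0, size=19)
        assert rms_aggregate(values) == pytest.approx(
            float(np.sqrt((values**2).sum() / 19)))

    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_mean_and_max(self, values):
        rms = rms_aggregate(values)
        assert rms >= np.mean(values) - 1e-9
        assert rms <= max(values) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_aggregate([])
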