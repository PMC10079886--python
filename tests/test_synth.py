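import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from accelmix import (MixtureTruth, RunConfig, SynthCohortConfig,
                      SynthMatchConfig, acceleration_index, build_match_script,
                      carrier_gain, detect_intervals, render_script,
                      sample_mixture_pool, simulate_cohort, simulate_match)
from accelmix.errors import ConfigError
from accelmix.segmentation import IN_PLAY, REST


class TestSampleMixturePool:
    def test_pure_high_component_mean(self):
        truth = MixtureTruth(w_high=1.0)
        pool, _ = sample_mixture_pool(truth, 10_000, seed_or_rng=0)
        bound = 3 * truth.sigma_high / np.sqrt(10_000)
        # truncation at zero lifts the mean slightly; allow its analytic bias
        trunc_bias = truth.sigma_high * norm.pdf(-3.0) / norm.cdf(3.0)
        assert abs(pool.mean() - truth.mu_high) < bound + trunc_bias

    def test_tail_mass_matches_analytic_cdf(self):
        truth = MixtureTruth()
        pool, _ = sample_mixture_pool(truth, 100_000, seed_or_rng=1)
        cut = 0.575
        analytic = ((1 - truth.w_high)
                    * (1 - norm.cdf(cut, truth.mu_low, truth.sigma_low))
                    + truth.w_high
                    * (1 - norm.cdf(cut, truth.mu_high, truth.sigma_high)))
        assert abs((pool > cut).mean() - analytic) < 0.01

    def test_determinism_and_nonnegativity(self):
        truth = MixtureTruth(mu_low=0.02, sigma_low=0.1)
        a, _ = sample_mixture_pool(truth, 5000, seed_or_rng=3)
        b, _ = sample_mixture_pool(truth, 5000, seed_or_rng=3)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all()

    def test_invalid_truth_rejected(self):
        with pytest.raises(ConfigError):
            MixtureTruth(sigma_low=0.0)
        with pytest.raises(ConfigError):
            MixtureTruth(w_high=1.5)


def small_match_config(**kw):
    base = dict(sample_rate_hz=100.0, duration_s=180.0, seed=0)
    base.update(kw)
    return SynthMatchConfig(**base)


class TestSimulateMatch:
    def test_truth_intervals_tile_recording(self):
        trace, iv, _ = simulate_match(small_match_config())
        assert iv.n_samples == len(trace)
        labels = {lab for lab, _, _ in iv.intervals}
        assert labels <= {IN_PLAY, REST}

    def test_seed_determinism(self):
        t1, iv1, _ = simulate_match(small_match_config(seed=9))
        t2, iv2, _ = simulate_match(small_match_config(seed=9))
        np.testing.assert_array_equal(t1.samples, t2.samples)
        assert iv1.intervals == iv2.intervals

    def test_single_rally_at_fixed_intensity_calibrates(self):
        """Noise-free 60-s rally at 0.9 G: index tracks the target level."""
        cfg = small_match_config(
            duration_s=60.0, rally_median_s=600.0, rally_min_s=600.0,
            truth=MixtureTruth(mu_low=0.89, sigma_low=1e-3, mu_high=0.9,
                               sigma_high=1e-3, w_high=1.0),
            dwell_s=600.0, taper_s=0.0, edge_high_s=0.0,
            rest_amplitude_g=0.0, noise_asd=0.0)
        trace, iv, _ = simulate_match(cfg)
        assert iv.intervals == [(IN_PLAY, 0, len(trace))]
        index = acceleration_index(trace, RunConfig())
        n = len(index)
        central = index.values[n // 4: 3 * n // 4]
        assert central.mean() == pytest.approx(0.9, rel=0.10)

    def test_rest_only_config_detected_as_all_rest(self):
        cfg = small_match_config(rally_median_s=1e-6, rally_min_s=1e-6,
                                 rest_median_s=1e4, rest_min_s=1e4)
        trace, iv, _ = simulate_match(cfg)
        found = detect_intervals(acceleration_index(trace, RunConfig()),
                                 RunConfig())
        assert [lab for lab, _, _ in found.intervals if lab == IN_PLAY] == []

    def test_rest_amplitude_above_cutoff_warns(self):
        cfg = small_match_config(rest_amplitude_g=0.35)
        with pytest.warns(UserWarning, match="unrecoverable"):
            build_match_script(cfg)

    def test_carrier_gain_near_unity_in_passband(self):
        g = carrier_gain(4.0)
        assert 0.9 < g <= 1.0


class TestRenderScript:
    def test_same_script_two_rates_align(self):
        cfg = small_match_config(seed=4)
        script = build_match_script(cfg, np.random.default_rng(4))
        t100, iv100 = render_script(script, cfg, sample_rate_hz=100.0,
                                    rng=np.random.default_rng(0))
        t500, iv500 = render_script(script, cfg, sample_rate_hz=500.0,
                                    rng=np.random.default_rng(0))
        assert len(t500) == pytest.approx(5 * len(t100), abs=5)
        assert iv100.duration_s(REST) == pytest.approx(iv500.duration_s(REST),
                                                       abs=0.05)

    def test_gravity_offset_present_in_raw(self):
        trace, _, _ = simulate_match(small_match_config())
        assert trace.samples[:, 2].mean() == pytest.approx(1.0, abs=0.05)


class TestSimulateCohort:
    def _config(self, n=2):
        groups = {
            name: dataclasses.replace(tpl, duration_s=120.0,
                                      sample_rate_hz=50.0)
            for name, tpl in
            __import__("accelmix").default_group_templates().items()
        }
        return SynthCohortConfig(groups=groups, n_per_group=n, seed=5)

    def test_shapes_and_labels(self):
        recs, table = simulate_cohort(self._config())
        assert len(recs) == 4
        assert sorted({r.group for r in recs}) == table.groups
        assert len(table) == 4
        assert set(table.data["recording_id"]) == {r.recording_id for r in recs}

    def test_determinism(self):
        r1, t1 = simulate_cohort(self._config())
        r2, t2 = simulate_cohort(self._config())
        np.testing.assert_array_equal(r1[0].trace.samples, r2[0].trace.samples)
        assert t1.data.equals(t2.data)

    def test_truth_differs_only_on_high_side(self):
        cfg = self._config()
        names = sorted(cfg.groups)
        ta, tb = (cfg.groups[n].truth for n in names)
        assert (ta.mu_low, ta.sigma_low, ta.w_high) == \
            (tb.mu_low, tb.sigma_low, tb.w_high)
        assert (ta.mu_high, ta.sigma_high) != (tb.mu_high, tb.sigma_high)

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            SynthCohortConfig(groups={"only": SynthMatchConfig()},
                              n_per_group=2)
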