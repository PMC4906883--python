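"""Generator contracts: determinism, signal model, stop rule, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbfatigue import _cci_expect
from perturbfatigue import synthetic as syn
from perturbfatigue.model import Direction, Protocol, sessions_equal
from perturbfatigue import mech
from _oracles import stop_criterion_bruteforce


class TestPreset:
    def test_published_calibration_values(self):
        cfg = syn.paper_preset()
        assert cfg.n_subjects == 24
        assert cfg.cop_targets["FAT"]["mean"][0] == pytest.approx(17.0)
        assert cfg.failure_prob["FAT"]["mean"][3] == pytest.approx(0.159)
        assert cfg.hreflex_targets["FAT"]["mean"][3] == pytest.approx(0.86)
        assert cfg.emg_targets["FAT"]["BF"]["SLR"]["mean"][3] == pytest.approx(2.13)
        assert cfg.cci_targets["FAT"]["SOL_TA"]["RP"]["mean"][3] == pytest.approx(1.64)

    def test_con_targets_flat_across_quarters(self):
        cfg = syn.paper_preset()
        for table in cfg.emg_targets["CON"].values():
            for qt in table.values():
                assert np.all(qt["mean"] == 1.0)
        assert np.ptp(cfg.cop_targets["CON"]["mean"]) == 0.0

    def test_dict_round_trip(self):
        cfg = syn.paper_preset()
        back = syn.config_from_dict(syn.config_to_dict(cfg))
        assert syn.config_to_dict(back) == syn.config_to_dict(cfg)


class TestEmgChannel:
    def test_expected_rectified_value_equals_envelope(self, rng):
        e = 0.3
        ch = syn.generate_emg_channel(np.full(1_000_000, e), 1000.0, rng)
        mean = np.abs(ch.samples).mean()
        se = e * np.sqrt(np.pi / 2 - 1) / 1000.0
        assert abs(mean - e) < 3 * se

    def test_zero_envelope_gives_silence(self, rng):
        ch = syn.generate_emg_channel(np.zeros(100), 1000.0, rng)
        assert np.all(ch.samples == 0.0)

    def test_same_stream_reproduces_samples(self):
        e = np.linspace(0, 1, 500)
        a = syn.generate_emg_channel(e, 1000.0, np.random.default_rng(7))
        b = syn.generate_emg_channel(e, 1000.0, np.random.default_rng(7))
        assert np.array_equal(a.samples, b.samples)

    def test_negative_envelope_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            syn.generate_emg_channel(np.array([-0.1, 0.2]), 1000.0, rng)


class TestStopCriterion:
    def test_immediate_double_failure_stops_at_four(self):
        assert syn.apply_stop_criterion([True, True, False, False, False]) == 4

    def test_all_successes_never_stops(self):
        assert syn.apply_stop_criterion([False] * 50) is None

    def test_spaced_failures_stop_at_second_within_window(self):
        # failures at trials 2 and 5 share the window 2..5
        seq = [False, True, False, False, True, False, True, True]
        assert syn.apply_stop_criterion(seq) == 5

    @given(st.lists(st.booleans(), min_size=0, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_equals_bruteforce_window_scan(self, flags):
        assert syn.apply_stop_criterion(flags) == stop_criterion_bruteforce(flags)


class TestTrialGeneration:
    def _noiseless_cfg(self):
        cfg = syn.paper_preset()
        cfg.cop_walk_step_mm = 0.0
        cfg.trial_cv_cop = 0.0
        cfg.cop_targets["FAT"] = syn._qt([17.0, 16.9, 14.0, 12.2], [0.0] * 4)
        return cfg

    def test_zero_failure_probability_always_succeeds(self, tiny_config, rng):
        cfg = self._noiseless_cfg()
        sub = syn.draw_subject_params(cfg, "s", np.random.default_rng(3))
        sub.failure_p["FAT"] = np.zeros(4)
        for _ in range(30):
            t = syn.generate_trial(cfg, sub, "FAT", 4, Direction.ANTERIOR, rng)
            assert not t.outcome.failed

    def test_noiseless_posterior_cop_recovers_amplitude_exactly(self, rng):
        cfg = self._noiseless_cfg()
        sub = syn.draw_subject_params(cfg, "s", np.random.default_rng(3))
        sub.cop_amp["FAT"] = np.array([17.0, 16.9, 14.0, 12.2])
        t = syn.generate_trial(cfg, sub, "FAT", 1, Direction.POSTERIOR, rng, failed=False)
        res = mech.cop_displacement(t.channels["cop_ap"], t.onset_s)
        assert res.cop_d_mm == pytest.approx(17.0, abs=1e-12)

    def test_failure_fraction_within_binomial_bound(self):
        # 1000 Bernoulli outcomes at the printed final-quarter probability
        cfg = syn.paper_preset()
        sub = syn.draw_subject_params(cfg, "s", np.random.default_rng(5))
        sub.failure_p["FAT"] = np.full(4, 0.159)
        rng = np.random.default_rng(99)
        fails = sum(
            syn.generate_trial(cfg, sub, "FAT", 4, Direction.MEDIAL, rng).outcome.failed
            for _ in range(1000)
        )
        p = 0.159
        half = 2.58 * np.sqrt(p * (1 - p) / 1000)
        assert abs(fails / 1000 - p) < half


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self, tiny_config):
        a = syn.generate_cohort(tiny_config, seed=5)
        b = syn.generate_cohort(tiny_config, seed=5)
        for (fa, ca), (fb, cb) in zip(a, b):
            assert sessions_equal(fa, fb)
            assert sessions_equal(ca, cb)

    def test_matched_direction_schedules(self, tiny_cohort):
        for fat, con in tiny_cohort:
            for tf, tc in zip(fat.trials, con.trials):
                assert tf.direction == tc.direction
            assert len(con.trials) >= len(fat.trials)

    def test_one_posterior_trial_per_set(self, tiny_cohort):
        fat, _ = tiny_cohort[0]
        for start in range(0, len(fat.trials), 8):
            block = fat.trials[start : start + 8]
            assert sum(t.is_posterior for t in block) == 1

    def test_failure_ramp_to_one_triggers_stop_before_max_sets(self):
        cfg = syn.paper_preset()
        cfg.n_subjects = 3
        cfg.min_sets = cfg.max_sets = 6
        cfg.truncate_at_stop = True
        cfg.failure_prob["FAT"] = {
            "mean": np.array([0.05, 0.5, 1.0, 1.0]),
            "sd": np.zeros(4),
        }
        cohort = syn.generate_cohort(cfg, seed=2)
        for fat, _ in cohort:
            assert len(fat.trials) < cfg.max_sets * 8
            flags = [t.outcome.failed for t in fat.trials]
            assert syn.apply_stop_criterion(flags) == len(flags)

    def test_stimulation_trials_are_posterior_and_marked(self, tiny_cohort):
        fat, _ = tiny_cohort[0]
        for i in fat.stimulation_trials:
            trial = fat.trials[i - 1]
            assert trial.is_posterior
            assert np.any(trial.channels["stim"].samples > 0)


class TestJumpTrace:
    def test_construction_recovers_peak_and_rfd(self):
        ch = syn.generate_jump_trace(2084.0, 0.1)
        res = mech.jump_measures(ch)
        assert res.peak_grf_n == pytest.approx(2084.0)
        assert res.rfd_kn_s == pytest.approx(20.84, rel=5e-3)

    def test_subthreshold_peak_rejected(self):
        with pytest.raises(ValueError, match="3 N"):
            syn.generate_jump_trace(2.0, 0.1)

    def test_noiseless_trace_peak_exact(self):
        ch = syn.generate_jump_trace(1500.0, 0.08)
        assert np.max(ch.samples) == pytest.approx(1500.0)


class TestCciExpectation:
    def test_quadrature_matches_monte_carlo(self):
        rng = np.random.default_rng(42)
        for r, rho in [(1.0, 0.0), (0.6, 0.45), (0.4, 0.9)]:
            n = 500_000
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            s = np.sqrt(np.pi / 2)
            u, v = s * np.abs(z1), s * r * np.abs(z2)
            lo, hi = np.minimum(u, v), np.maximum(u, v)
            terms = np.where(hi > 0, lo / hi * (lo + hi), 0.0)
            mc, se = terms.mean(), terms.std() / np.sqrt(n)
            quad = _cci_expect.expected_cci_unit(r, rho)
            assert abs(quad - mc) < max(4 * se, 3e-3)

    def test_calibration_inverts_expectation(self):
        hi = np.linspace(0.2, 0.5, 90)
        lo = 0.6 * hi
        target = _cci_expect.expected_cci(hi, lo, 0.62)
        assert _cci_expect.calibrate_rho(hi, lo, target) == pytest.approx(0.62, abs=5e-3)

    def test_monotone_in_correlation(self):
        hi = np.full(50, 0.4)
        lo = np.full(50, 0.3)
        vals = [_cci_expect.expected_cci(hi, lo, r) for r in (0.0, 0.3, 0.6, 0.9)]
        assert vals == sorted(vals)
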