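"""EMG measures: windows, integration, MVC normalisation, CCI, amplitudes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from perturbfatigue import emg
from perturbfatigue.model import TimeSeriesChannel


def chan(samples, rate=1000.0, label="SOL", units="mV"):
    return TimeSeriesChannel(label, np.asarray(samples, float), rate, units)


class TestRectify:
    def test_absolute_value_and_idempotence(self):
        c = chan([-1.0, 2.0, -3.0])
        r = emg.rectify(c)
        assert list(r.samples) == [1.0, 2.0, 3.0]
        assert np.array_equal(emg.rectify(r).samples, r.samples)
        assert (r.rate, r.units) == (c.rate, c.units)


class TestIntegrateWindow:
    def test_constant_over_slr_is_duration_times_level(self):
        c = chan(np.ones(1000))  # 1 mV for 1 s
        assert emg.integrate_window(c, 0.5, emg.SLR) == pytest.approx(0.030, abs=1e-15)

    def test_zero_signal_zero_integral(self):
        c = chan(np.zeros(1000))
        assert emg.integrate_window(c, 0.5, emg.MLR) == 0.0

    def test_ramp_matches_analytic_riemann_sum(self):
        rate = 1000.0
        t = np.arange(1000) / rate
        c = chan(2.5 * t)
        onset = 0.5
        # samples in [0.53, 0.56): k = 530..559
        ks = np.arange(530, 560)
        expected = np.sum(2.5 * ks / rate) / rate
        assert emg.integrate_window(c, onset, emg.SLR) == pytest.approx(expected, abs=1e-12)

    def test_window_outside_recording_raises(self):
        c = chan(np.ones(100))
        with pytest.raises(ValueError, match="outside"):
            emg.integrate_window(c, 0.09, emg.LLR)

    def test_additive_over_reflex_phases(self, rng):
        c = chan(rng.standard_normal(1000))
        onset = 0.4
        total = sum(emg.integrate_window(c, onset, w) for w in (emg.SLR, emg.MLR, emg.LLR))
        assert total == pytest.approx(emg.integrate_window(c, onset, emg.RP), rel=1e-12)


class TestPhaseIEMG:
    def test_envelope_at_mvc_gives_100_pct(self):
        c = chan(np.full(1000, 0.8))
        out = emg.phase_iemg(c, 0.5, mvc_ref_mv=0.8)
        assert set(out) == {"PRE", "SLR", "MLR", "LLR"}
        for ph in out.values():
            assert ph.pct_mvc == pytest.approx(100.0)
            assert ph.mean_mv == pytest.approx(0.8)

    def test_linearity_in_the_signal(self, rng):
        x = np.abs(rng.standard_normal(1000))
        a = emg.phase_iemg(chan(x), 0.5, 1.0)
        b = emg.phase_iemg(chan(2 * x), 0.5, 1.0)
        for ph in a:
            assert b[ph].pct_mvc == pytest.approx(2 * a[ph].pct_mvc, rel=1e-12)

    def test_nonpositive_mvc_rejected(self):
        with pytest.raises(ValueError, match="MVC"):
            emg.phase_iemg(chan(np.ones(1000)), 0.5, 0.0)


class TestMvcReference:
    def test_constant_recording(self):
        assert emg.mvc_reference(chan(np.full(2000, 2.0))) == pytest.approx(2.0)

    def test_single_spike_is_diluted_by_the_average_window(self):
        x = np.zeros(2000)
        x[1000] = 5.0
        assert emg.mvc_reference(chan(x)) == pytest.approx(5.0 / 500)

    def test_invariant_to_sign_flip(self, rng):
        x = rng.standard_normal(3000)
        assert emg.mvc_reference(chan(x)) == pytest.approx(emg.mvc_reference(chan(-x)))

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="short"):
            emg.mvc_reference(chan(np.ones(100)))


class TestCCI:
    def test_hand_worked_example(self):
        # terms: (0.2/0.4)*0.6 = 0.30 and (0.1/0.4)*0.5 = 0.125 -> mean 0.2125
        assert emg.cci([0.2, 0.4], [0.4, 0.1]) == pytest.approx(0.2125, abs=1e-15)

    def test_equal_activation_gives_sum(self):
        assert emg.cci([0.5] * 4, [0.5] * 4) == pytest.approx(1.0)

    def test_silent_antagonist_gives_zero(self):
        assert emg.cci([0.3, 0.8, 0.1], [0.0, 0.0, 0.0]) == 0.0

    def test_both_zero_sample_contributes_zero(self):
        assert emg.cci([0.0, 0.4], [0.0, 0.4]) == pytest.approx(0.4)

    def test_rejects_negative_and_mismatched(self):
        with pytest.raises(ValueError):
            emg.cci([0.1, -0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            emg.cci([0.1], [0.1, 0.2])

    @given(
        hnp.arrays(float, st.integers(1, 30),
                   elements=st.floats(0, 10, allow_nan=False)),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_homogeneity(self, a, data):
        b = data.draw(
            hnp.arrays(float, a.size, elements=st.floats(0, 10, allow_nan=False))
        )
        c = data.draw(st.floats(0.01, 50))
        assert emg.cci(a, b) == pytest.approx(emg.cci(b, a), rel=1e-12, abs=1e-12)
        assert emg.cci(c * a, c * b) == pytest.approx(c * emg.cci(a, b), rel=1e-9, abs=1e-12)

    @given(
        hnp.arrays(float, st.integers(1, 30),
                   elements=st.floats(0, 10, allow_nan=False)),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_by_summed_activation(self, a, data):
        b = data.draw(
            hnp.arrays(float, a.size, elements=st.floats(0, 10, allow_nan=False))
        )
        assert 0.0 <= emg.cci(a, b) <= np.mean(a + b) + 1e-12


class TestPeakToPeak:
    def test_full_sine_cycle_gives_twice_amplitude(self):
        t = np.arange(1000) / 1000.0
        c = chan(0.7 * np.sin(2 * np.pi * 50 * t))  # peaks hit the 1 kHz grid
        assert emg.peak_to_peak(c, 0.0, 1.0) == pytest.approx(1.4)

    def test_constant_signal_zero(self):
        assert emg.peak_to_peak(chan(np.full(100, 3.0)), 0.0, 0.1) == 0.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            emg.peak_to_peak(chan(np.ones(100)), 0.2, 0.1)


class TestSlrPeakTime:
    def test_burst_centred_at_45ms(self):
        t = np.arange(1000) / 1000.0
        onset = 0.4
        x = np.exp(-0.5 * ((t - onset - 0.045) / 0.008) ** 2)
        assert emg.slr_peak_time(chan(x), onset) == pytest.approx(onset + 0.045, abs=1e-3)

    def test_monotone_signal_peaks_at_window_end(self):
        x = np.arange(1000, dtype=float)
        assert emg.slr_peak_time(chan(x), 0.4) == pytest.approx(0.459)

    def test_tie_breaks_to_earlier_sample(self):
        x = np.zeros(1000)
        x[440] = x[450] = 1.0  # both inside [430, 460)
        assert emg.slr_peak_time(chan(x), 0.4) == pytest.approx(0.440)
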