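import numpy as np
import pytest

from abskit.dsc import (
    GAS_CONSTANT_KJ,
    Thermogram,
    fit_two_state,
    multi_transition_fit,
    subtract_baseline,
    two_state_excess_cp,
)
from abskit.simulate import gen_thermogram

_T0 = 273.15


class TestExcessCp:
    def test_peak_value_at_midpoint(self):
        # at T = Tm the equilibrium constant is 1, so Cp = s*dH^2/(4RT^2)
        tm, dh = 74.0, 400.0
        expected = dh**2 / (4 * GAS_CONSTANT_KJ * (tm + _T0) ** 2)
        assert two_state_excess_cp(tm, tm, dh) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_far_below_transition(self):
        assert two_state_excess_cp(20.0, 74.0, 400.0) < 1e-6

    def test_argmax_on_fine_grid_sits_near_tm(self):
        # peak maximum is at Tm to first order; the 1/T^2 prefactor shifts
        # it down by ~2R*Tm^2/dH * R*Tm/dH ~ 0.07 C at dH = 400 kJ/mol
        tm, dh = 74.0, 400.0
        t = np.arange(60.0, 88.0, 0.001)
        cp = two_state_excess_cp(t, tm, dh)
        assert t[np.argmax(cp)] == pytest.approx(tm, abs=0.1)

    def test_area_equals_scale_times_dh(self):
        # van't Hoff / calorimetric consistency at scale = 1 and scale = 2.5
        t = np.arange(20.0, 120.0, 0.01)
        for scale in (1.0, 2.5):
            cp = two_state_excess_cp(t, 74.0, 400.0, scale)
            area = np.trapezoid(cp, t)
            assert area == pytest.approx(scale * 400.0, rel=0.01)

    def test_nonpositive_enthalpy_rejected(self):
        with pytest.raises(ValueError):
            two_state_excess_cp(50.0, 74.0, -10.0)


class TestBaseline:
    def test_pure_cubic_subtracts_to_zero(self):
        t = np.arange(20.0, 90.0, 0.1)
        cp = 1e-5 * t**3 - 2e-3 * t**2 + 0.1 * t + 5.0
        tg = Thermogram(tuple(t), tuple(cp))
        corrected, coeffs = subtract_baseline(tg, exclude_window=(60.0, 80.0))
        assert np.max(np.abs(corrected.signal)) < 1e-9

    def test_peak_preserved_after_subtraction(self):
        # window wide enough that the peak wings (FWHM ~ 9 C at 440 kJ/mol)
        # do not leak into the baseline region
        tg = gen_thermogram([74.56], [440.0], baseline_coeffs=[1e-5, -2e-3, 0.1, 5.0])
        corrected, _ = subtract_baseline(tg, exclude_window=(60.0, 89.0))
        peak = two_state_excess_cp(corrected.t, 74.56, 440.0)
        rms = np.sqrt(np.mean((corrected.signal - peak) ** 2))
        assert rms < 0.01 * np.max(peak)

    def test_window_covering_scan_rejected(self):
        tg = gen_thermogram([74.56], [440.0])
        with pytest.raises(ValueError, match="whole scan"):
            subtract_baseline(tg, exclude_window=(0.0, 100.0))


class TestTwoStateFit:
    def test_noiseless_recovery_at_machine_precision(self):
        tg = gen_thermogram([74.56], [440.0], scales=[1.3])
        fit = fit_two_state(tg)
        assert fit.tm == pytest.approx(74.56, abs=1e-8)
        assert fit.dh == pytest.approx(440.0, rel=1e-8)
        assert fit.scale == pytest.approx(1.3, rel=1e-8)

    def test_flat_trace_has_no_peak(self, rng):
        t = np.arange(20.0, 90.0, 0.1)
        tg = Thermogram(tuple(t), tuple(rng.normal(0, 0.01, len(t))))
        with pytest.raises(ValueError, match="no discernible transition"):
            fit_two_state(tg)

    def test_free_energy_zero_at_midpoint_and_decreasing(self):
        tg = gen_thermogram([74.56], [440.0])
        fit = fit_two_state(tg)
        assert fit.dg(fit.tm) == pytest.approx(0.0, abs=1e-9)
        temps = np.linspace(fit.tm, fit.tm + 15.0, 10)
        dgs = fit.dg(temps)
        assert np.all(np.diff(dgs) < 0)
        # below Tm the folded state is favoured (positive unfolding dG)
        assert fit.dg(fit.tm - 10.0) > 0

    def test_recovery_bias_under_noise(self):
        # median Tm error < 0.1 C over 200 replicates at 1% peak-height noise
        peak = two_state_excess_cp(74.56, 74.56, 440.0)
        tms = []
        for i in range(200):
            tg = gen_thermogram([74.56], [440.0], noise_sd=0.01 * peak, rng=20_000 + i)
            tms.append(fit_two_state(tg).tm)
        assert abs(np.median(tms) - 74.56) < 0.1


class TestMultiTransition:
    def test_single_component_matches_plain_fit(self):
        tg = gen_thermogram([74.56], [440.0])
        single = fit_two_state(tg)
        fits, diag = multi_transition_fit(tg, 1)
        assert len(fits) == 1
        assert fits[0].tm == pytest.approx(single.tm, abs=1e-9)
        assert diag["k"] == 1

    def test_three_sharp_transitions_recovered(self):
        tms, dhs = [80.04, 83.39, 86.40], [1500.0, 1500.0, 1500.0]
        peak = max(two_state_excess_cp(np.arange(75, 90, 0.1), tm, dh).max()
                   for tm, dh in zip(tms, dhs))
        tg = gen_thermogram(tms, dhs, noise_sd=0.005 * peak, rng=31)
        # three local maxima visible at low noise
        from scipy.signal import find_peaks
        idx, _ = find_peaks(tg.signal, prominence=0.1 * np.max(tg.signal))
        assert len(idx) == 3
        fits, diag = multi_transition_fit(tg, 3)
        for fit, tm in zip(fits, tms):
            assert fit.tm == pytest.approx(tm, abs=0.3)
        assert diag["delta_aicc"] < 0  # 3 components beat 2

    def test_aicc_prefers_single_component_on_single_transition(self):
        peak = two_state_excess_cp(74.56, 74.56, 440.0)
        tg = gen_thermogram([74.56], [440.0], noise_sd=0.01 * peak, rng=33)
        _, diag = multi_transition_fit(tg, 2)
        assert diag["delta_aicc"] > 0  # k=2 penalised vs k=1

    def test_invalid_component_count_rejected(self):
        tg = gen_thermogram([74.56], [440.0])
        with pytest.raises(ValueError):
            multi_transition_fit(tg, 5)
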