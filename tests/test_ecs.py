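"""Three-wavelength deconvolution, flash amplitudes, stoichiometry, flow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photophys as pp
from photophys.ecs import ECSDeconvolved
from photophys.simulate import ECSTraceSet


def _traceset(a520, a554, a563, t=None, event=0.0):
    n = len(a520)
    t = np.linspace(-0.05, 0.25, n) if t is None else t
    return ECSTraceSet(t, np.asarray(a520, float), np.asarray(a554, float),
                       np.asarray(a563, float), condition="control",
                       regime="flash", event_time_s=event)


class TestDeconvolution:
    def test_printed_coefficients(self):
        ts = _traceset([1.0] * 4, [0.9] * 4, [0.5] * 4)
        dec = pp.deconvolute_wavelengths(ts)
        assert np.allclose(dec.cytc, 0.9 - 0.4 * 1.0 - 0.4 * 0.5)   # 0.3
        assert np.allclose(dec.ecslin, 1.0 - 0.25 * 0.3)            # 0.925

    def test_zero_input(self):
        dec = pp.deconvolute_wavelengths(_traceset([0] * 5, [0] * 5, [0] * 5))
        assert np.allclose(dec.cytc, 0) and np.allclose(dec.ecslin, 0)

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            ECSTraceSet(np.arange(4.0), np.zeros(4), np.zeros(3), np.zeros(4),
                        "control", "flash", 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.floats(-2, 2), st.floats(-2, 2))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(3, 8))
        y = rng.normal(size=(3, 8))
        mix = _traceset(*(a * x + b * y))
        dx = pp.deconvolute_wavelengths(_traceset(*x))
        dy = pp.deconvolute_wavelengths(_traceset(*y))
        dmix = pp.deconvolute_wavelengths(mix)
        assert np.allclose(dmix.cytc, a * dx.cytc + b * dy.cytc, atol=1e-9)
        assert np.allclose(dmix.ecslin, a * dx.ecslin + b * dy.ecslin, atol=1e-9)

    def test_pure_ecs_input_has_zero_cytc(self):
        rng = np.random.default_rng(0)
        a520 = rng.normal(size=10)
        a563 = rng.normal(size=10)
        a554 = 0.4 * (a520 + a563)
        dec = pp.deconvolute_wavelengths(_traceset(a520, a554, a563))
        assert np.allclose(dec.cytc, 0.0, atol=1e-12)
        assert np.allclose(dec.ecslin, a520, atol=1e-12)

    def test_generator_roundtrip_1e12(self, noisefree):
        ex = pp.gen_ecs_experiment(noisefree, 1, line="WT", light="ML")
        for ts in (ex.flash_control, ex.flash_inhibited, ex.light_off):
            dec = pp.deconvolute_wavelengths(ts)
            # re-mix: forward model must be the exact inverse
            re520 = dec.ecslin + 0.25 * dec.cytc
            assert np.max(np.abs(re520 - ts.a520)) < 1e-12


class TestFlashAmplitude:
    def _decon(self, t, y):
        return ECSDeconvolved(t, np.zeros_like(t), y, "dcmu_ha", "flash", 0.0)

    def test_step_without_decay(self):
        t = np.arange(-0.05, 0.25, 0.001)
        y = np.where(t >= 0, 0.01, 0.0)
        amp = pp.flash_amplitude(self._decon(t, y))
        assert amp.amplitude == pytest.approx(0.01, rel=1e-6)

    def test_flat_trace_is_zero(self):
        t = np.arange(-0.05, 0.25, 0.001)
        amp = pp.flash_amplitude(self._decon(t, np.full_like(t, 0.004)))
        assert amp.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_generator_truth_recovery(self, noisefree):
        noisefree.ecs["a1"] = 0.01
        noisefree.ecs["k_decay"] = 5.0
        ex = pp.gen_ecs_experiment(noisefree, 1, line="WT", light="LL")
        amp = pp.flash_amplitude(pp.deconvolute_wavelengths(ex.flash_inhibited))
        assert amp.amplitude == pytest.approx(0.01, rel=1e-3)
        assert amp.method == "decay_fit"

    def test_too_few_samples_error(self):
        t = np.array([-0.02, -0.01, 0.0, 0.1])
        with pytest.raises(ValueError, match="3 samples"):
            pp.flash_amplitude(self._decon(t, np.zeros(4)))


class TestStoichiometry:
    def test_arithmetic(self):
        st_ = pp.psii_psi_stoichiometry(1.0, 0.4)
        assert st_.psii_fraction == pytest.approx(0.6)
        assert st_.psii_psi_ratio == pytest.approx(1.5)

    def test_no_psii_limit(self):
        assert pp.psii_psi_stoichiometry(0.4, 0.4).psii_psi_ratio == 0.0

    def test_errors_not_clamped(self):
        with pytest.raises(ValueError, match="negative PSII"):
            pp.psii_psi_stoichiometry(0.3, 0.4)
        with pytest.raises(ValueError):
            pp.psii_psi_stoichiometry(1.0, 0.0)

    def test_recovery_from_simulated_experiment(self, scenario):
        sc = pp.SimScenario.from_dict(scenario.to_dict())
        sc.ecs["psii_psi_ratio"] = 1.2
        ratios = []
        for seed in range(20):
            ex = pp.gen_ecs_experiment(sc, seed, line="WT", light="ML")
            ac = pp.flash_amplitude(pp.deconvolute_wavelengths(ex.flash_control))
            ai = pp.flash_amplitude(pp.deconvolute_wavelengths(ex.flash_inhibited))
            ratios.append(pp.psii_psi_stoichiometry(ac.amplitude, ai.amplitude)
                          .psii_psi_ratio)
        assert abs(np.mean(ratios) - 1.2) / 1.2 < 0.05


class TestElectronFlow:
    def test_arithmetic(self):
        t = np.arange(-0.3, 0.3, 0.001)
        y = np.where(t < 0, 0.05 * t, -1.95 * t)
        dec = ECSDeconvolved(t, np.zeros_like(t), y, "control", "light_off", 0.0)
        res = pp.electron_flow_rate(dec, a_single_charge=0.01)
        assert res.flow == pytest.approx(200.0, rel=1e-9)

    def test_equal_slopes_zero_flow(self):
        t = np.arange(-0.3, 0.3, 0.001)
        dec = ECSDeconvolved(t, np.zeros_like(t), 0.03 * t, "control",
                             "light_off", 0.0)
        assert pp.electron_flow_rate(dec, a_single_charge=0.01).flow == \
            pytest.approx(0.0, abs=1e-9)

    def test_noise_free_truth(self, noisefree):
        noisefree.ecs["J"] = 150.0
        ex = pp.gen_ecs_experiment(noisefree, 1, line="WT", light="ML")
        res = pp.electron_flow_rate(pp.deconvolute_wavelengths(ex.light_off),
                                    a_single_charge=0.001)
        assert res.flow == pytest.approx(150.0, rel=1e-6)

    def test_short_window_error(self):
        t = np.arange(-0.3, 0.3, 0.001)
        dec = ECSDeconvolved(t, np.zeros_like(t), 0.03 * t, "control",
                             "light_off", 0.0)
        with pytest.raises(ValueError, match="3 samples"):
            pp.electron_flow_rate(dec, window_light_s=0.001,
                                  a_single_charge=0.01)

    def test_end_to_end_flow_ratio_recovery(self, scenario):
        """200 seeded noisy sessions: mean mutant/WT flow ratio near truth."""
        ratios = []
        for seed in range(200):
            flows = {}
            for off, ln in enumerate(("WT", "cpftsy.1-25.7")):
                ex = pp.gen_ecs_experiment(scenario, 2 * seed + off,
                                           line=ln, light="ML")
                ai = pp.flash_amplitude(
                    pp.deconvolute_wavelengths(ex.flash_inhibited))
                flows[ln] = pp.electron_flow_rate(
                    pp.deconvolute_wavelengths(ex.light_off),
                    a_single_charge=ai.amplitude).flow
            ratios.append(flows["cpftsy.1-25.7"] / flows["WT"])
        assert abs(np.mean(ratios) - 0.5) < 0.03
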