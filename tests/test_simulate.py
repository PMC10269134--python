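"""Generator contracts: determinism, validation, and closed-form truths."""

import numpy as np
import pandas as pd
import pytest

import photophys as pp
from photophys.simulate import ScenarioError


class TestScenario:
    def test_load_packaged(self, scenario):
        assert scenario.name == "cpftsy_study"
        assert scenario.wild_type == "WT"
        assert scenario.growth["mu"]["WT"]["LL"] == pytest.approx(1.42)
        assert scenario.growth["mu"]["WT"]["ML"] == pytest.approx(1.95)

    def test_unknown_name_lists_available(self):
        with pytest.raises(ScenarioError, match="cpftsy_study"):
            pp.load_scenario("no_such_scenario")

    def test_config_round_trip(self, scenario, tmp_path):
        path = tmp_path / "copy.yaml"
        scenario.save(path)
        assert pp.SimScenario.load(path) == scenario

    @pytest.mark.parametrize("section,key,bad", [
        ("fluor", "k_ind", -0.1),
        ("photoinhibition", "k_damage", -1e-6),
        ("growth", "noise_cv", 1.5),
        ("proteomics", "pi_diff", 1.2),
        ("ecs", "a1", 0.0),
    ])
    def test_validation_rejects(self, scenario, section, key, bad):
        d = scenario.to_dict()
        d[section][key] = bad
        with pytest.raises(ScenarioError):
            pp.SimScenario.from_dict(d)

    def test_e_steps_must_increase(self, scenario):
        d = scenario.to_dict()
        d["rlc"]["E_steps"] = [4, 8, 8, 16, 32]
        with pytest.raises(ScenarioError, match="increasing"):
            pp.SimScenario.from_dict(d)


class TestSeedContract:
    def test_same_seed_identical(self, scenario):
        a = pp.gen_npq_trace(scenario, 5).pulses
        b = pp.gen_npq_trace(scenario, 5).pulses
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, scenario):
        a = pp.gen_npq_trace(scenario, 5).pulses
        b = pp.gen_npq_trace(scenario, 6).pulses
        assert not np.allclose(a["Fm_prime"], b["Fm_prime"])


class TestNPQGenerator:
    def test_no_quenching_identity(self, noisefree):
        noisefree.fluor["NPQ_max"] = 0.0
        tr = pp.gen_npq_trace(noisefree, 1, line="WT")
        assert np.allclose(tr.pulses["Fm_prime"], tr.Fm)
        tc = pp.npq_timecourse(tr)
        assert np.allclose(tc.series["npq"], 0.0, atol=1e-12)

    def test_closed_form_at_end_of_induction(self, noisefree):
        # NPQ_max = 1.2, k_ind = 0.01/s -> NPQ(360 s) = 1.2 (1 - e^-3.6)
        noisefree.fluor["NPQ_max"] = 1.2
        noisefree.fluor["k_ind"] = 0.01
        tr = pp.gen_npq_trace(noisefree, 1, line="WT")
        tc = pp.npq_timecourse(tr)
        assert tc.npq_end_induction == pytest.approx(1.1672, abs=1e-4)

    def test_protocol_shape(self, scenario):
        tr = pp.gen_npq_trace(scenario, 1)
        phases = tr.pulses["phase"]
        assert set(phases) == {"dark", "induction", "relaxation"}
        ind = tr.pulses[phases == "induction"]
        assert ind["time_s"].max() == pytest.approx(360.0)
        assert np.allclose(np.diff(tr.pulses["time_s"]), 30.0)


class TestRapidLightCurve:
    def test_default_grid(self, scenario):
        df = pp.gen_rapid_light_curve(scenario, 1)
        e = df["e_umol_m2_s"].to_numpy()
        assert len(e) == 13 and e[0] == 4 and e[-1] == 1088

    def test_low_light_series_expansion(self, noisefree):
        noisefree.rlc["FvFm"] = 1.0  # remove the cap to test the Webb limit
        df = pp.gen_rapid_light_curve(noisefree, 1, line="WT")
        alpha, rmax = 0.38, 60.0
        e0 = df["e_umol_m2_s"].iloc[0]
        approx = alpha * (1 - alpha * e0 / (2 * rmax))
        assert df["phi_psii"].iloc[0] == pytest.approx(approx, rel=0.01)

    def test_invalid_steps_rejected(self, scenario):
        d = scenario.to_dict()
        d["rlc"]["E_steps"] = [-4.0, 8.0, 16.0, 32.0, 64.0]
        with pytest.raises(ScenarioError):
            pp.SimScenario.from_dict(d)


class TestECSGenerator:
    def test_zero_flux_identity(self, noisefree):
        noisefree.ecs["J"] = 0.0
        ex = pp.gen_ecs_experiment(noisefree, 1, line="WT", light="ML")
        flow = pp.electron_flow_rate(
            pp.deconvolute_wavelengths(ex.light_off), a_single_charge=0.001)
        assert flow.flow == pytest.approx(0.0, abs=1e-9)

    def test_no_psii_limit(self, noisefree):
        noisefree.ecs["psii_psi_ratio"] = 0.0
        ex = pp.gen_ecs_experiment(noisefree, 1, line="WT", light="ML")
        ac = pp.flash_amplitude(pp.deconvolute_wavelengths(ex.flash_control))
        ai = pp.flash_amplitude(pp.deconvolute_wavelengths(ex.flash_inhibited))
        assert ac.amplitude == pytest.approx(ai.amplitude, rel=1e-9)

    def test_exact_roundtrip_any_truth(self, noisefree):
        ex = pp.gen_ecs_experiment(noisefree, 1, line="cpftsy.1-25.7", light="LL")
        dec = pp.deconvolute_wavelengths(ex.flash_inhibited)
        t = ex.flash_inhibited.time_s
        e_true = np.where(t >= 0, 0.001 * np.exp(-5.0 * np.maximum(t, 0)), 0.0)
        c_true = np.where(t >= 0, 0.0003 * np.exp(-2.0 * np.maximum(t, 0)), 0.0)
        assert np.max(np.abs(dec.ecslin - e_true)) < 1e-12
        assert np.max(np.abs(dec.cytc - c_true)) < 1e-12


class TestPigmentGenerator:
    def test_noise_free_equals_means(self, noisefree):
        df = pp.gen_pigment_timecourse(noisefree, 1)
        wt0 = df[(df.line == "WT") & (df.time_h == 0.0)]
        assert np.allclose(wt0["chla_fmol_per_cell"], 0.45)

    def test_time_grid(self, scenario):
        df = pp.gen_pigment_timecourse(scenario, 1)
        assert sorted(df["time_h"].unique()) == [0.0, 0.5, 6.0, 24.0, 168.0]

    def test_des_from_configured_pool(self, noisefree):
        for tab in noisefree.pigments["means"].values():
            tab["ddx"] = [3.0] * 5
            tab["dtx"] = [1.0] * 5
        df = pp.gen_pigment_timecourse(noisefree, 1)
        des = pp.des_index(df["ddx_fmol_per_cell"], df["dtx_fmol_per_cell"])
        assert np.allclose(des, 0.25)


class TestCountSeries:
    def test_doubling_at_mu_one(self, noisefree):
        noisefree.growth["mu"] = 1.0
        df = pp.gen_count_series(noisefree, 1, line="WT")
        one_rep = df[df.replicate == 1]["cells_per_ml"].to_numpy()
        assert np.allclose(one_rep[1:] / one_rep[:-1], 2.0)

    def test_default_inoculum(self, scenario):
        df = pp.gen_count_series(scenario, 1, line="WT")
        assert scenario.growth["N0"] == pytest.approx(1e5)
        truth = df.attrs["truth"].params
        assert truth["N0"] == pytest.approx(1e5)

    def test_noise_free_inversion(self, noisefree):
        df = pp.gen_count_series(noisefree, 1, line="cpftsy.2-2.8", light="ML")
        res = pp.division_rates(df)
        assert res.mu_max == pytest.approx(0.67, abs=1e-12)


class TestHLLincGenerator:
    def test_no_damage_stays_at_100(self, noisefree):
        p = noisefree.photoinhibition
        p["k_damage"] = 0.0
        p["q_hl"] = 0.0
        p["q_res"] = 0.0
        df = pp.gen_hl_linc_timecourse(noisefree, 1, lines=["WT"])
        rel = pp.normalize_to_initial(df)
        assert np.allclose(rel["rel_pct"], 100.0)

    def test_linc_arm_closed_form(self, noisefree):
        # k_damage = -ln(0.30)/60 -> 29.99% of initial at 60 min
        df = pp.gen_hl_linc_timecourse(noisefree, 1, lines=["WT"])
        rel = pp.normalize_to_initial(df[df.arm == "HL_LINC"])
        at60 = rel[rel.time_min == 60.0]["rel_pct"]
        assert np.allclose(at60, 30.0, atol=1e-9)

    def test_packaged_wt_recovery_fraction(self, noisefree):
        df = pp.gen_hl_linc_timecourse(noisefree, 1, lines=["WT"])
        hl = pp.normalize_to_initial(df[df.arm == "HL"])
        linc = pp.normalize_to_initial(df[df.arm == "HL_LINC"])
        met = pp.repair_recovery_metrics(hl, linc)
        assert met.recovery_pct == pytest.approx(96.0, abs=1e-9)
        assert met.decline_hl_pct == pytest.approx(52.0, abs=1e-9)


class TestAbundanceGenerator:
    def test_design_shape(self, scenario):
        mat, truth = pp.gen_abundance_matrix(scenario, 1)
        assert (mat.groups.value_counts() == 5).all()
        assert mat.abundances.shape[0] == scenario.proteomics["n_prot"]

    def test_noise_free_effect_exact(self, scenario):
        d = scenario.to_dict()
        d["proteomics"].update(dict(sigma_rep=0.0, mcar_p=0.0, mnar_mid=-1e6,
                                    effect_min=1.0, effect_max=1.0,
                                    p_up=1.0, pi_diff=0.2, n_prot=200))
        sc = pp.SimScenario.from_dict(d)
        mat, truth = pp.gen_abundance_matrix(sc, 3, groups=["WT", "cpftsy.1-25.7"])
        lr = pp.log2_group_ratio(mat, "cpftsy.1-25.7", "WT")
        flagged = truth.params["is_diff"]
        eff = truth.params["true_log2_effects"]["cpftsy.1-25.7"]
        assert np.allclose(lr.to_numpy()[flagged], eff[flagged], atol=1e-9)
        assert np.allclose(lr.to_numpy()[~flagged], 0.0, atol=1e-9)

    def test_truth_record_alongside(self, scenario):
        _, truth = pp.gen_abundance_matrix(scenario, 1)
        assert truth.params["is_diff"].shape == (scenario.proteomics["n_prot"],)
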