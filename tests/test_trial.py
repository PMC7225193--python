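"""Virtual-trial generator: library, presets, sampling design, noise model."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rrtpk.core import SpecimenType
from rrtpk.trial import (
    PopulationModel,
    draw_individual,
    drug_library,
    make_scenario,
    scenario_presets,
    simulate_scenario,
    simulate_trial,
)


class TestDrugLibrary:
    def test_contract(self):
        lib = drug_library()
        assert set(lib) == {"piperacillin", "tigecycline", "colistin", "linezolid"}
        for entry in lib.values():
            assert entry.population.typical.V_cent > 0
            assert entry.regimen.interval in (8.0, 12.0)
            assert entry.regimen.amount > 0
        assert lib["piperacillin"].population.typical.CL_body == pytest.approx(3.0)
        assert lib["colistin"].population.typical.CL_body == pytest.approx(2.0)

    def test_unknown_names_rejected(self):
        with pytest.raises(KeyError):
            make_scenario("base_vancomycin")


class TestScenarioPresets:
    def test_preset_values(self):
        presets = scenario_presets()
        deg = presets["degradation_8h"]
        assert deg.param_overrides["k_deg"] == pytest.approx(0.03)
        assert deg.param_overrides["CL_RRT"] == pytest.approx(3.0)
        rev = presets["adsorption_reversible"]
        assert rev.param_overrides["F_Ads"] == pytest.approx(0.95)
        assert rev.param_overrides["k_ads_rev"] == pytest.approx(0.07)
        irr = presets["adsorption_irreversible"]
        assert irr.param_overrides["F_Ads"] == pytest.approx(0.65)
        assert "k_ads_rev" not in irr.param_overrides

    def test_base_presets_have_clean_elimination(self):
        for drug in ("piperacillin", "tigecycline", "colistin", "linezolid"):
            _, pop, _ = make_scenario(f"base_{drug}")
            assert pop.typical.F_Ads == 0.0
            assert pop.typical.k_deg == 0.0
            assert pop.typical.CL_RRT == pytest.approx(pop.typical.CL_body)

    def test_degradation_half_life_is_about_24h(self):
        _, pop, _ = make_scenario("degradation_8h")
        assert math.log(2) / pop.typical.k_deg == pytest.approx(24.0, rel=0.05)

    def test_clrrt_fraction_override(self):
        _, pop, _ = make_scenario("base_piperacillin", clrrt_frac=0.2)
        assert pop.typical.CL_RRT == pytest.approx(0.6)


class TestDrawIndividual:
    def test_zero_variability_returns_typical(self):
        _, pop, _ = make_scenario("base_piperacillin")
        pop0 = replace(pop, iiv={})
        p = draw_individual(pop0, np.random.default_rng(0))
        assert p == pop.typical

    def test_lognormal_location(self):
        """Monte-Carlo: mean log draw matches log typical within 3 SE."""
        _, pop, _ = make_scenario("base_piperacillin")
        rng = np.random.default_rng(1234)
        n = 20000
        logs = np.array([math.log(draw_individual(pop, rng).CL_body) for _ in range(n)])
        se = 0.3 / math.sqrt(n)
        assert abs(logs.mean() - math.log(3.0)) < 3 * se
        assert logs.std() == pytest.approx(0.3, rel=0.05)

    def test_flow_covariate_neutral_at_reference(self):
        _, pop, _ = make_scenario("base_piperacillin")
        pop_cov = replace(pop, iiv={}, q_effl_ref=3.0)
        assert draw_individual(pop_cov, np.random.default_rng(0), q_effl=3.0).CL_RRT \
            == pytest.approx(pop.typical.CL_RRT)
        assert draw_individual(pop_cov, np.random.default_rng(0), q_effl=3.3).CL_RRT \
            == pytest.approx(pop.typical.CL_RRT * 1.1)


class TestSimulateTrial:
    def test_record_count_matches_design_combinatorics(self):
        # 10 dialysis x (6 pre + 6 post + 6 effluent) x 2 occasions
        # + 10 x (1 cum conc + 1 cum vol) x 2 occasions
        # + 10 non-dialysis x 6 pre x 2 occasions
        expected = 10 * 18 * 2 + 10 * 2 * 2 + 10 * 6 * 2
        trial = simulate_scenario("base_piperacillin", seed=7)
        obs = trial.noisy[trial.noisy["EVID"] == 0]
        assert len(obs) == expected
        by_spec = obs.groupby("DVID").size().to_dict()
        assert by_spec == {1: 240, 2: 120, 3: 120, 4: 20, 5: 20}

    def test_non_dialysis_subjects_have_only_plasma(self):
        trial = simulate_scenario("base_piperacillin", seed=7)
        obs = trial.noisy[trial.noisy["EVID"] == 0]
        off = obs[obs["RRTON"] == 0]
        assert set(off["DVID"].unique()) == {1}
        assert (trial.subjects.loc[~trial.subjects["dialysis"], "CL_RRT"] == 0).all()

    def test_determinism(self):
        a = simulate_scenario("adsorption_irreversible", seed=42)
        b = simulate_scenario("adsorption_irreversible", seed=42)
        c = simulate_scenario("adsorption_irreversible", seed=43)
        pd.testing.assert_frame_equal(a.noisy, b.noisy)
        assert not a.noisy["DV"].equals(c.noisy["DV"])

    def test_q_dial_drawn_within_range(self):
        trial = simulate_scenario("base_piperacillin", seed=3)
        q = trial.subjects.loc[trial.subjects["dialysis"], "Q_dial"]
        assert ((q >= 3.0) & (q <= 3.3)).all()
        assert q.nunique() == 10

    def test_noise_free_effluent_satisfies_saturation_relation(self):
        """Without adsorption the effluent/plasma ratio times the effluent
        flow recovers the simulating circuit clearance exactly."""
        design, pop, _ = make_scenario("base_piperacillin", clrrt_frac=0.8)
        pop0 = replace(pop, iiv={})
        trial = simulate_trial(design, pop0, 11)
        df = trial.noise_free
        obs = df[df["EVID"] == 0]
        for sid, sub in obs[obs["RRTON"] == 1].groupby("ID"):
            pre = sub[sub["DVID"] == 1].set_index("TIME")["DV"]
            eff = sub[sub["DVID"] == 3].set_index("TIME")["DV"]
            q = sub["QD"].iloc[0]
            ratio = (eff / pre.loc[eff.index]) * q
            assert np.allclose(ratio, 0.8 * 3.0, rtol=1e-9)

    def test_degradation_depletes_the_bag_and_more_so_over_longer_collection(self):
        """The amount implied by bag concentration x volume falls short of the
        removed amount, and the deficit grows with the collection interval."""
        deficits = {}
        for name in ("degradation_8h", "degradation_12h"):
            design, pop, _ = make_scenario(name)
            pop0 = replace(pop, iiv={}, residual_cv={"conc": 0.0, "vol": 0.0})
            trial = simulate_trial(design, pop0, 5)
            df = trial.noise_free
            obs = df[(df["EVID"] == 0) & (df["RRTON"] == 1)]
            sub = obs[obs["ID"] == 1]
            t_end = design.regimen.interval
            conc = sub[(sub["DVID"] == 4) & (sub["TIME"] == t_end)]["DV"].iloc[0]
            vol = sub[(sub["DVID"] == 5) & (sub["TIME"] == t_end)]["DV"].iloc[0]
            bagged = conc * vol
            # exact mass balance: drug removed via the circuit over [0, T] is
            # the circuit's share of everything eliminated, CL_RRT / CL_total
            # of (dose - amount still in the body at T)
            pre = sub[sub["DVID"] == 1].set_index("TIME")["DV"]
            a1_end = 22.0 * pre.loc[t_end]
            removed = 0.5 * (4000.0 - a1_end)
            deficits[name] = 1.0 - bagged / removed
            assert bagged < removed
        assert deficits["degradation_12h"] > deficits["degradation_8h"]

    def test_residual_error_magnitudes(self):
        """Empirical CV of noisy/noise-free ratios matches 25% (concentrations)
        and 10% (volumes) within Monte-Carlo error."""
        ratios_c, ratios_v = [], []
        for seed in range(8):
            trial = simulate_scenario("base_piperacillin", seed=seed)
            free = trial.noise_free[trial.noise_free["EVID"] == 0]["DV"].to_numpy()
            noisy = trial.noisy[trial.noisy["EVID"] == 0]["DV"].to_numpy()
            dvid = trial.noisy[trial.noisy["EVID"] == 0]["DVID"].to_numpy()
            r = noisy / free - 1.0
            ratios_c.append(r[dvid != 5])
            ratios_v.append(r[dvid == 5])
        cv_c = np.concatenate(ratios_c).std()
        cv_v = np.concatenate(ratios_v).std()
        assert cv_c == pytest.approx(0.25, abs=0.01)
        assert cv_v == pytest.approx(0.10, abs=0.015)

    def test_population_model_validation(self):
        _, pop, _ = make_scenario("base_piperacillin")
        with pytest.raises(ValueError):
            PopulationModel(typical=pop.typical, iiv={"CL_body": -0.1})
        with pytest.raises(ValueError):
            PopulationModel(typical=pop.typical, residual_cv={"conc": -0.2})
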