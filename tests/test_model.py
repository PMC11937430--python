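"""The single-SNP parent-of-origin likelihood, its optimizer and tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_config_probs, brute_family_loglik
from triadpoo import (
    Configuration,
    FamilyUnit,
    PooParams,
    TriadPooModel,
    TriadPooResults,
    compatible_configurations,
    config_weight,
    enumerate_configurations,
    family_loglik,
    fit_maternal,
    fit_poo,
    posterior_config_weights,
)

params_strategy = st.builds(
    PooParams,
    p=st.floats(0.05, 0.95),
    rr_cm=st.floats(0.2, 5.0),
    rr_cf=st.floats(0.2, 5.0),
    rr_star=st.floats(0.5, 2.0),
)


class TestConfigurations:
    def test_sixteen_distinct(self):
        configs = enumerate_configurations()
        assert len(configs) == len(set(configs)) == 16

    def test_child_genotype_two_count(self):
        assert sum(c.child == 2 for c in enumerate_configurations()) == 4

    def test_unique_configuration_for_201(self):
        matches = [c for c in enumerate_configurations() if (c.mother, c.father, c.child) == (2, 0, 1)]
        assert matches == [Configuration(1, 1, 0, 0)]


class TestConfigWeight:
    def test_uniform_case(self):
        p = PooParams(0.5)
        weights = [config_weight(c, p) for c in enumerate_configurations()]
        assert np.allclose(weights, 0.0625)

    def test_single_maternal_factor(self):
        assert config_weight(Configuration(0, 1, 1, 0), PooParams(0.5, 2.0, 1.0)) == pytest.approx(0.125)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params_strategy)
    def test_normalised_probabilities_sum_to_one(self, params):
        total = sum(config_weight(c, params) for c in enumerate_configurations())
        probs = brute_config_probs(params.p, params.rr_cm, params.rr_cf, params.rr_star)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        norm = [config_weight(c, params) / total for c in enumerate_configurations()]
        assert sum(norm) == pytest.approx(1.0, abs=1e-12)


class TestCompatibility:
    def test_double_heterozygote_ambiguity(self):
        configs = compatible_configurations(FamilyUnit("f", 1, 1, 1))
        assert set(configs) == {Configuration(0, 1, 1, 0), Configuration(1, 0, 0, 1)}

    def test_forced_configuration(self):
        assert compatible_configurations(FamilyUnit("f", 1, 2, 0)) == [Configuration(1, 1, 0, 0)]

    def test_mother_dyad_frees_paternal_slots(self):
        configs = compatible_configurations(FamilyUnit("f", 2, 1, None))
        assert set(configs) == {Configuration(0, 1, 0, 1), Configuration(0, 1, 1, 1)}


class TestFamilyLoglik:
    def test_unique_configuration_uniform_cells(self):
        ll = family_loglik(FamilyUnit("f", 2, 2, 2), PooParams(0.5))
        assert ll == pytest.approx(math.log(1 / 16))

    def test_double_het_matches_direct_sum(self):
        params = PooParams(0.5, 2.0, 1.0)
        ll = family_loglik(FamilyUnit("f", 1, 1, 1), params)
        z = sum(config_weight(c, params) for c in enumerate_configurations())
        assert ll == pytest.approx(math.log((2 + 1) * 0.0625 / z), abs=1e-12)

    def test_dyad_marginalises_over_fathers(self):
        params = PooParams(0.3, 1.5, 0.8)
        dyad_ll = family_loglik(FamilyUnit("f", 1, 1, None), params)
        total = sum(
            math.exp(brute_family_loglik(1, father, 1, params.p, params.rr_cm, params.rr_cf))
            for father in (0, 1, 2)
        )
        assert dyad_ll == pytest.approx(math.log(total), abs=1e-12)

    def test_matches_enumeration_oracle_on_random_draws(self, rng):
        for _ in range(200):
            params = PooParams(rng.uniform(0.05, 0.95), *np.exp(rng.normal(0, 0.5, 3)))
            m, f = int(rng.integers(3)), int(rng.integers(3))
            child_options = [mt + ft for mt in ((0,) if m == 0 else (1,) if m == 2 else (0, 1))
                             for ft in ((0,) if f == 0 else (1,) if f == 2 else (0, 1))]
            c = int(rng.choice(child_options))
            kind = rng.integers(3)
            mm, ff = (m, f) if kind == 0 else (m, None) if kind == 1 else (None, f)
            unit = FamilyUnit("f", c, mm, ff)
            expected = brute_family_loglik(mm, ff, c, params.p, params.rr_cm, params.rr_cf, params.rr_star)
            assert family_loglik(unit, params) == pytest.approx(expected, abs=1e-10)


class TestPosterior:
    def test_symmetric_risks_split_evenly(self):
        _, post = posterior_config_weights(FamilyUnit("f", 1, 1, 1), PooParams(0.4, 1.3, 1.3))
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_weights_follow_risk_ratio(self):
        configs, post = posterior_config_weights(FamilyUnit("f", 1, 1, 1), PooParams(0.5, 2.0, 1.0))
        maternal = configs.index(Configuration(0, 1, 1, 0))
        assert post[maternal] == pytest.approx(2 / 3)

    def test_unambiguous_family_is_degenerate(self):
        _, post = posterior_config_weights(FamilyUnit("f", 0, 0, 0), PooParams(0.2, 3.0, 0.5))
        np.testing.assert_allclose(post, [1.0])


class TestFit:
    def test_parent_swap_symmetric_data_equates_risks(self):
        units = []
        for i, (m, f, c) in enumerate([(1, 1, 1), (2, 0, 1), (0, 2, 1), (1, 2, 2), (2, 1, 2)]):
            units.append(FamilyUnit(f"a{i}", c, m, f))
            units.append(FamilyUnit(f"b{i}", c, f, m))  # mirrored partner
        res = fit_poo(units)
        assert res.params.rr_cm == pytest.approx(res.params.rr_cf, rel=1e-6)

    def test_grid_oracle_small(self, toy_units):
        res = fit_poo(toy_units)
        model = TriadPooModel(toy_units)
        best = -np.inf
        for p in np.linspace(0.1, 0.9, 21):
            for rcm in np.exp(np.linspace(np.log(0.25), np.log(4), 21)):
                for rcf in np.exp(np.linspace(np.log(0.25), np.log(4), 21)):
                    best = max(best, model.loglike(PooParams(p, rcm, rcf)))
        assert res.llf >= best - 1e-9

    def test_empty_units_error(self):
        with pytest.raises(ValueError):
            TriadPooModel([])

    def test_recovery_from_simulation(self, sim_units_5000):
        units, cfg = sim_units_5000
        res = fit_poo(units)
        ci = dict(zip(res.param_names, res.bse))
        from scipy.special import logit

        assert abs(logit(res.params.p) - logit(cfg.p)) < 3 * ci["p"]
        assert abs(np.log(res.params.rr_cm / cfg.rr_cm)) < 3 * ci["rr_cm"]
        assert abs(np.log(res.params.rr_cf / cfg.rr_cf)) < 3 * ci["rr_cf"]

    def test_summary_mentions_ratio(self, sim_units_5000):
        res = fit_poo(sim_units_5000[0])
        assert "RRcm/RRcf" in res.summary()


class TestRatioTest:
    def _results_with(self, theta_cm, theta_cf, var, cov):
        units = [FamilyUnit("f", 1, 1, 1), FamilyUnit("g", 0, 0, 0), FamilyUnit("h", 2, 2, 2)]
        model = TriadPooModel(units)
        theta = np.array([0.0, theta_cm, theta_cf])
        C = np.eye(3) * var
        C[1, 2] = C[2, 1] = cov
        return TriadPooResults(model, theta, C, llf=-1.0, converged=True, n_iter=1)

    def test_equal_risks_give_p_one(self):
        r = self._results_with(0.3, 0.3, 0.01, 0.0)
        assert r.ratio_test().ratio == pytest.approx(1.0)
        assert r.ratio_test().p_value == pytest.approx(1.0)

    def test_closed_form_interval(self):
        r = self._results_with(0.2, 0.0, 0.01, 0.0).ratio_test()
        se = math.sqrt(0.02)
        z975 = 1.959963984540054
        assert r.ratio == pytest.approx(math.exp(0.2))
        assert r.ci_low == pytest.approx(math.exp(0.2 - z975 * se))
        assert r.ci_high == pytest.approx(math.exp(0.2 + z975 * se))

    def test_nonconverged_fit_refused(self):
        res = self._results_with(0.2, 0.0, 0.01, 0.0)
        res.converged = False
        with pytest.raises(RuntimeError):
            res.ratio_test()


class TestMaternalModel:
    def test_fixed_rr_m_reproduces_base_loglik(self, toy_units):
        base = fit_poo(toy_units)
        fixed = fit_maternal(toy_units, fix_rr_m=True)
        assert fixed.llf == base.llf
        assert "rr_m" not in fixed.param_names

    def test_free_rr_m_never_decreases_loglik(self, toy_units):
        base = fit_poo(toy_units)
        mat = fit_maternal(toy_units)
        assert mat.llf >= base.llf - 1e-9

    def test_maternal_effect_recovered_without_poo_artifact(self):
        from triadpoo import SimConfig, simulate_case_families

        cfg = SimConfig(p=0.4, rr_m=1.5, n_case_families=4000, seed=11)
        units, _ = simulate_case_families(cfg)
        res = fit_maternal(units)
        j = res.param_names.index("rr_m")
        assert abs(np.log(res.params.rr_m / 1.5)) < 3 * res.bse[j]
        # no spurious parent-of-origin signal
        assert res.ratio_test().p_value > 0.01

    def test_null_rr_m_recovered(self, sim_units_5000):
        res = fit_maternal(sim_units_5000[0])
        j = res.param_names.index("rr_m")
        assert abs(np.log(res.params.rr_m)) < 3 * res.bse[j]


class TestNesting:
    def test_free_rr_star_never_decreases_loglik(self, sim_units_5000):
        units, _ = sim_units_5000
        fixed = fit_poo(units)
        free = fit_poo(units, fix_rr_star=False)
        assert free.llf >= fixed.llf - 1e-9
        # truth has rr_star = 1: the improvement behaves like a null LRT
        assert 2 * (free.llf - fixed.llf) < 10.83  # chi2(1) at p=0.001
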