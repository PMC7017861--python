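import numpy as np
import pytest

import wetstate as ws
from wetstate.data_io import MISSING
from wetstate.simulate import SyntheticConfig, simulate_study
from conftest import interior_config


class TestAicc:
    def test_small_sample_correction(self):
        assert ws.compute_aicc(6692.67, 67, 2910) == pytest.approx(6829.88, abs=0.01)
        assert ws.compute_aicc(5673.87, 55, 2910) == pytest.approx(5786.03, abs=0.01)

    def test_large_n_limit_is_aic(self):
        assert ws.compute_aicc(100.0, 5, 10**9) == pytest.approx(110.0, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="n_eff"):
            ws.compute_aicc(100.0, 5, 6)


class TestWeights:
    def test_published_delta_column(self):
        w = ws.akaike_weights([0, 0.94, 2.76, 3.15, 4.81])
        assert np.allclose(w, [0.4600, 0.2875, 0.1157, 0.0952, 0.0415], atol=5e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_equal_aicc_split_evenly(self):
        assert np.allclose(ws.akaike_weights([3.0, 3.0]), [0.5, 0.5])

    def test_single_model(self):
        assert np.allclose(ws.akaike_weights([42.0]), [1.0])

    def test_invariance_to_constant_shift(self, rng):
        d = rng.random(6) * 10
        assert np.allclose(ws.akaike_weights(d), ws.akaike_weights(d + 123.4))

    def test_largest_remainder_rounding_sums_to_one(self, rng):
        for _ in range(20):
            w = rng.dirichlet(np.ones(5))
            r = ws.round_weights_to_sum(w)
            assert r.sum() == pytest.approx(1.0)
            assert np.abs(r - w).max() <= 0.01 + 1e-12


class FakeFit:
    def __init__(self, name, aicc, k, deviance=0.0, n_eff=2910, converged=True):
        self.name, self.aicc, self.k = name, aicc, k
        self.deviance, self.n_eff, self.converged = deviance, n_eff, converged


class TestRanking:
    def test_table_sorted_with_zero_top_delta(self):
        fits = [FakeFit("b", 102.0, 5), FakeFit("a", 100.0, 4), FakeFit("c", 110.0, 6)]
        table = ws.rank_models(fits)
        assert table.top_model == "a"
        assert table.frame["dAICc"].iloc[0] == 0.0
        assert table.frame["weight"].sum() == pytest.approx(1.0)
        assert (table.frame["weight"].diff().dropna() <= 1e-12).all()

    def test_tie_broken_by_smaller_k(self):
        fits = [FakeFit("big", 100.0, 9), FakeFit("small", 100.0, 4)]
        assert ws.rank_models(fits).top_model == "small"

    def test_mixed_n_eff_rejected(self):
        fits = [FakeFit("a", 100.0, 4), FakeFit("b", 101.0, 4, n_eff=500)]
        with pytest.raises(ValueError, match="n_eff"):
            ws.rank_models(fits)

    def test_averaging_trigger(self):
        strong = ws.rank_models([FakeFit("a", 100.0, 4), FakeFit("b", 120.0, 4)])
        weak = ws.rank_models([FakeFit("a", 100.0, 4), FakeFit("b", 100.4, 4)])
        assert not strong.averaging_triggered      # top weight > 0.90
        assert weak.averaging_triggered


class TestModelAverage:
    def test_single_model_identity(self):
        fit = FakeFit("a", 100.0, 4)
        est, se, used = ws.model_average([fit], lambda f: (0.37, 0.01**2))
        assert est == pytest.approx(0.37) and se == pytest.approx(0.01)

    def test_two_equal_models_formula(self):
        fits = [FakeFit("a", 100.0, 4), FakeFit("b", 100.0, 4)]
        targets = {"a": 0.4, "b": 0.6}
        est, se, _ = ws.model_average(fits, lambda f: (targets[f.name], 0.0))
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.1)   # pure between-model spread

    def test_nonconverged_excluded(self):
        fits = [FakeFit("a", 100.0, 4), FakeFit("b", 100.0, 4, converged=False)]
        targets = {"a": 0.4, "b": 0.6}
        est, _, used = ws.model_average(fits, lambda f: (targets[f.name], 0.0))
        assert est == pytest.approx(0.4) and len(used) == 1


class TestFitModel:
    def test_perfect_detection_mles_equal_empirical_frequencies(self):
        # with delta = 1 the states are fully observed, so the transition MLEs
        # are the empirical transition frequencies (closed-form oracle)
        beta = dict(interior_config().beta)
        beta["delta:int"] = 30.0       # delta = 1 to numerical precision
        cfg = SyntheticConfig(n_sites=700, n_years=6, missing_rate=0.0,
                              structure="psi[m](.) R[m](.) delta(.)", beta=beta)
        truth = simulate_study(cfg, seed=17)
        fit = ws.fit_model(cfg.structure, truth.data, n_starts=1, seed=0,
                           compute_vcov=False)
        states = truth.latent_states
        prev, nxt = states[:, :-1].ravel(), states[:, 1:].ravel()
        from scipy.special import expit
        labels = fit.design.labels
        for m in range(3):
            sel = prev == m
            emp_psi = (nxt[sel] > 0).mean()
            est_psi = expit(fit.beta_hat[labels.index(f"psi:int[m{m}]")])
            assert est_psi == pytest.approx(emp_psi, abs=1e-3)
            wet = sel & (nxt > 0)
            emp_r = (nxt[wet] == 2).mean()
            est_r = expit(fit.beta_hat[labels.index(f"R:int[m{m}]")])
            assert est_r == pytest.approx(emp_r, abs=1e-3)
        # initial-year parameters likewise
        emp_psi0 = (states[:, 0] > 0).mean()
        est_psi0 = expit(fit.beta_hat[labels.index("init:logit_psi")])
        assert est_psi0 == pytest.approx(emp_psi0, abs=1e-3)

    def test_all_dry_dataset_hits_boundary(self, small_truth):
        d = small_truth.data.subset(np.arange(20))
        d.obs[:] = 0
        fit = ws.fit_model("psi[m](.) R[m](.) delta(.)", d, n_starts=1, seed=0,
                           compute_vcov=False)
        assert fit.boundary_flags[fit.design.labels.index("init:logit_psi")]

    def test_site_order_invariance(self, interior_truth):
        data = interior_truth.data.subset(np.arange(150))
        perm = np.random.default_rng(3).permutation(150)
        f1 = ws.fit_model("psi[m](.) R[m](.) delta(.)", data,
                          n_starts=1, seed=0, compute_vcov=False)
        f2 = ws.fit_model("psi[m](.) R[m](.) delta(.)", data.subset(perm),
                          n_starts=1, seed=0, compute_vcov=False)
        assert f1.deviance == pytest.approx(f2.deviance, abs=1e-5)

    def test_deviance_invariant_to_covariate_rescaling(self, small_truth):
        data = small_truth.data
        f1 = ws.fit_model("psi[m](.) R[m](evap) delta(.)", data,
                          n_starts=1, seed=0, compute_vcov=False)
        rescaled = data.subset(np.arange(data.n_sites))
        rescaled.site_year = dict(rescaled.site_year)
        rescaled.site_year["evap"] = data.site_year["evap"] * 12.0 - 999.0
        f2 = ws.fit_model("psi[m](.) R[m](evap) delta(.)", rescaled,
                          n_starts=1, seed=0, compute_vcov=False)
        assert f1.deviance == pytest.approx(f2.deviance, abs=1e-4)

    def test_aicc_uses_site_visit_count(self, interior_fit, interior_truth):
        n_eff = interior_truth.data.n_site_visits
        assert interior_fit.n_eff == n_eff
        assert interior_fit.aicc == pytest.approx(
            ws.compute_aicc(interior_fit.deviance, interior_fit.k, n_eff))


class TestStepwiseWorkflow:
    def test_single_candidate_per_stage(self, small_truth):
        res = ws.stepwise_workflow(
            small_truth.data, ["delta(.)"], ["psi[m](.)"], ["R[m](.)"],
            n_starts=1, seed=0, compute_vcov=False)
        assert set(res.stage_tables) == {"detection", "wetland", "breeding"}
        for table in res.stage_tables.values():
            assert len(table.frame) == 1
            assert table.frame["weight"].iloc[0] == pytest.approx(1.0)
        assert res.final_structure.name == "psi[m](.) R[m](.) delta(.)"

    def test_empty_candidate_list_rejected(self, small_truth):
        with pytest.raises(ValueError, match="empty"):
            ws.stepwise_workflow(small_truth.data, [], ["psi[m](.)"], ["R[m](.)"])

    def test_stage_winners_propagate(self, interior_truth):
        data = interior_truth.data.subset(np.arange(250))
        res = ws.stepwise_workflow(
            data, ["delta(.)", "delta(veg)"], ["psi[m](.)", "psi[1=2](.)"],
            ["R[m](.)", "R[0=1](.)"], base_psi="psi[m](.)", base_r="R[m](.)",
            n_starts=1, seed=0, compute_vcov=False)
        best_delta = ws.parse_model_structure(
            res.stage_tables["detection"].top_model).delta.canonical()
        for model in res.stage_tables["wetland"].frame["Model"]:
            assert best_delta in model
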