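import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import tlcausal as tl
from tlcausal.tmle import PositivityError, saturated_nuisances


class TestFitNuisances:
    def test_randomized_design_recovers_half(self, small_run_config):
        rng = np.random.default_rng(0)
        n = 4000
        w = pd.DataFrame({"x": rng.normal(size=n)})
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, expit(-1 + a + 0.5 * w.x))
        cohort = tl.Cohort(y=y, a=a, w=w)
        nuis = tl.fit_nuisances(cohort, small_run_config)
        assert nuis.g.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n) + 0.01)

    def test_truncation_clips_exactly(self):
        nuis = tl.NuisanceFits(
            qbar_aw=np.full(3, 0.3), qbar1=np.full(3, 0.4), qbar0=np.full(3, 0.2),
            g_raw=np.array([0.01, 0.5, 0.99]), g=np.array([0.01, 0.5, 0.99]),
            bound=0.06,
        )
        np.testing.assert_allclose(nuis.g, [0.06, 0.5, 0.94])

    def test_null_outcome_model_flat_predictions(self, small_run_config):
        rng = np.random.default_rng(1)
        n = 3000
        w = pd.DataFrame({"x": rng.normal(size=n)})
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, 0.3, n)
        nuis = tl.fit_nuisances(tl.Cohort(y=y, a=a, w=w), small_run_config)
        assert np.abs(nuis.qbar1 - nuis.qbar0).mean() < 0.05
        assert nuis.qbar_aw.mean() == pytest.approx(y.mean(), abs=0.03)


class TestFluctuate:
    def test_saturated_fit_gives_zero_epsilon(self, discrete_toy):
        nuis = saturated_nuisances(discrete_toy)
        _, eps = tl.fluctuate(nuis, discrete_toy)
        assert abs(eps) < 1e-6

    def test_epsilon_shrinks_when_nuisances_are_true(self):
        """When Qbar is the true conditional mean, the fluctuation is pure
        noise and shrinks with n."""
        eps_by_n = {}
        for n in (2000, 50_000):
            rng = np.random.default_rng(21)
            w = rng.normal(size=n)
            g = expit(0.4 * w)
            a = rng.binomial(1, g)
            q = expit(-1 + 0.9 * a + 0.5 * w)
            y = rng.binomial(1, q)
            cohort = tl.Cohort(y=y, a=a, w=pd.DataFrame({"w": w}))
            nuis = tl.NuisanceFits(
                qbar_aw=q, qbar1=expit(-1 + 0.9 + 0.5 * w),
                qbar0=expit(-1 + 0.5 * w), g_raw=g, g=g, bound=1e-3,
            )
            _, eps_by_n[n] = tl.fluctuate(nuis, cohort)
        assert abs(eps_by_n[2000]) < 0.2
        assert abs(eps_by_n[50_000]) < 0.05

    def test_rescaled_g_changes_epsilon_not_eif_mean(self, discrete_toy):
        cfg = tl.RunConfig(ps_bound=0.01)
        nuis = saturated_nuisances(discrete_toy)
        # perturb Qbar so the score is not already solved
        nuis = dataclasses.replace(
            nuis,
            qbar_aw=np.clip(nuis.qbar_aw * 0.8 + 0.05, 0.01, 0.99),
            qbar1=np.clip(nuis.qbar1 * 0.8 + 0.05, 0.01, 0.99),
            qbar0=np.clip(nuis.qbar0 * 0.8 + 0.05, 0.01, 0.99),
        )
        res1 = tl.TMLE(discrete_toy, cfg, nuisances=nuis).fit()
        nuis2 = dataclasses.replace(nuis, g_raw=nuis.g_raw**2, g=nuis.g**2)
        res2 = tl.TMLE(discrete_toy, cfg, nuisances=nuis2).fit()
        assert res1.epsilon != pytest.approx(res2.epsilon, abs=1e-6)
        assert abs(res1.ic.mean()) <= 1e-8
        assert abs(res2.ic.mean()) <= 1e-8


class TestWaldCI:
    def test_reported_interval_reconstruction(self):
        lo, hi = tl.wald_ci(0.21, 0.062, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.09, 0.33)
        assert lo == pytest.approx(0.0885, abs=2e-4)
        assert hi == pytest.approx(0.3315, abs=2e-4)

    def test_standard_normal_quantile(self):
        lo, hi = tl.wald_ci(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_half_level_quantile(self):
        lo, hi = tl.wald_ci(0.0, 1.0, 0.5)
        assert hi == pytest.approx(0.67449, abs=1e-4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            tl.wald_ci(0.2, 0.0)


class TestGcompOracle:
    def test_single_stratum_is_crude_rd(self):
        y = np.array([0, 1, 1, 0, 1, 1])
        a = np.array([0, 0, 0, 1, 1, 1])
        cohort = tl.Cohort(y=y, a=a, w=pd.DataFrame({"w": np.ones(6)}))
        crude = y[a == 1].mean() - y[a == 0].mean()
        assert tl.gcomp_oracle(cohort) == pytest.approx(crude, abs=1e-12)

    def test_hand_computed_strata(self, hand_toy):
        # stratum diffs 0, 2/3, 1/3 with equal weights 1/3 -> RD = 1/3
        assert tl.gcomp_oracle(hand_toy) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_empty_cell_names_stratum(self):
        y = np.array([0, 1, 0, 1])
        a = np.array([0, 0, 1, 1])
        w = pd.DataFrame({"w": [0, 0, 1, 1]})
        with pytest.raises(PositivityError, match="stratum"):
            tl.gcomp_oracle(tl.Cohort(y=y, a=a, w=w))


class TestTmleEstimate:
    def test_saturated_equals_gcomp(self, discrete_toy, hand_toy):
        for cohort in (discrete_toy, hand_toy):
            nuis = saturated_nuisances(cohort)
            res = tl.TMLE(cohort, tl.RunConfig(ps_bound=1e-6), nuisances=nuis).fit()
            assert res.rd == pytest.approx(tl.gcomp_oracle(cohort), abs=1e-6)

    def test_recovers_true_effect_unconfounded(self, small_run_config):
        cfg = tl.default_sim_config(n=5000, seed=17)
        cohort, truth = tl.generate_cohort(cfg, mc_size=100_000)
        res = tl.TMLE(cohort, small_run_config).fit()
        assert res.rd == pytest.approx(truth.rd, abs=3 * res.se_rd)

    def test_all_treated_rejected(self):
        y = np.array([0, 1, 1])
        a = np.array([1, 1, 1])
        cohort = tl.Cohort(y=y, a=a, w=pd.DataFrame({"w": [1.0, 2.0, 3.0]}))
        with pytest.raises(PositivityError):
            tl.TMLE(cohort, tl.RunConfig(v_folds=2)).fit()

    def test_relabeling_negates_rd_and_inverts_ratios(self, discrete_toy):
        cfg = tl.RunConfig(ps_bound=1e-6)
        nuis = saturated_nuisances(discrete_toy)
        res = tl.TMLE(discrete_toy, cfg, nuisances=nuis).fit()
        flipped = tl.Cohort(
            y=discrete_toy.y, a=1 - discrete_toy.a, w=discrete_toy.w
        )
        nuis_f = saturated_nuisances(flipped)
        res_f = tl.TMLE(flipped, cfg, nuisances=nuis_f).fit()
        assert res_f.rd == pytest.approx(-res.rd, abs=1e-12)
        rr = res.effects_table().loc["RR", "estimate"]
        rr_f = res_f.effects_table().loc["RR", "estimate"]
        assert rr_f == pytest.approx(1.0 / rr, abs=1e-10)

    def test_truncation_noop_when_g_interior(self, discrete_toy):
        nuis = saturated_nuisances(discrete_toy, bound=0.06)
        assert nuis.g_raw.min() > 0.06 and nuis.g_raw.max() < 0.94
        res_tight = tl.TMLE(
            discrete_toy, tl.RunConfig(ps_bound=0.06), nuisances=nuis
        ).fit()
        nuis2 = saturated_nuisances(discrete_toy, bound=1e-6)
        res_loose = tl.TMLE(
            discrete_toy, tl.RunConfig(ps_bound=1e-6), nuisances=nuis2
        ).fit()
        assert res_tight.rd == pytest.approx(res_loose.rd, abs=1e-12)

    def test_summary_contains_key_numbers(self, discrete_toy):
        nuis = saturated_nuisances(discrete_toy)
        res = tl.TMLE(discrete_toy, tl.RunConfig(), nuisances=nuis).fit()
        text = res.summary()
        assert f"{res.rd:.4f}" in text
        assert "95% CI" in text


class TestEffectOnScale:
    def _toy_result(self):
        n = 50
        ic1 = np.random.default_rng(3).normal(0, 0.1, n)
        ic0 = np.random.default_rng(4).normal(0, 0.1, n)
        return ic1 - ic1.mean(), ic0 - ic0.mean()

    def test_null_gives_unit_ratios(self):
        ic1, ic0 = self._toy_result()
        rr, _, _ = tl.effect_on_scale(0.3, 0.3, ic1, ic0, "RR")
        orr, _, _ = tl.effect_on_scale(0.3, 0.3, ic1, ic0, "OR")
        assert rr == pytest.approx(1.0, abs=1e-12)
        assert orr == pytest.approx(1.0, abs=1e-12)

    def test_ratio_arithmetic(self):
        ic1, ic0 = self._toy_result()
        rr, _, _ = tl.effect_on_scale(0.5, 0.25, ic1, ic0, "RR")
        orr, _, _ = tl.effect_on_scale(0.5, 0.25, ic1, ic0, "OR")
        assert rr == pytest.approx(2.0, abs=1e-12)
        assert orr == pytest.approx(3.0, abs=1e-12)

    def test_degenerate_arm_mean_rejected(self):
        ic1, ic0 = self._toy_result()
        with pytest.raises(ValueError):
            tl.effect_on_scale(0.5, 0.0, ic1, ic0, "RR")

    def test_log_rr_se_matches_bootstrap(self, discrete_toy):
        """Delta-method SE for log RR agrees with a nonparametric bootstrap
        of the saturated TMLE on a discrete toy."""
        nuis = saturated_nuisances(discrete_toy)
        res = tl.TMLE(discrete_toy, tl.RunConfig(scale="RR", ps_bound=1e-6),
                      nuisances=nuis).fit()
        _, se_delta, _ = tl.effect_on_scale(
            res.psi1, res.psi0, res.ic1, res.ic0, "RR"
        )
        rng = np.random.default_rng(6)
        boot = []
        df = discrete_toy.to_dataframe()
        for _ in range(400):
            idx = rng.integers(0, len(df), len(df))
            d = df.iloc[idx]
            try:
                c = tl.Cohort(y=d.y.to_numpy(), a=d.a.to_numpy(),
                              w=d[["w1", "w2"]].reset_index(drop=True))
                r = tl.TMLE(c, tl.RunConfig(scale="RR", ps_bound=1e-6),
                            nuisances=saturated_nuisances(c)).fit()
                boot.append(np.log(r.psi1 / r.psi0))
            except PositivityError:
                continue
        assert se_delta == pytest.approx(np.std(boot), rel=0.25)
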