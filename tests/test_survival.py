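import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from gipni import datagen, io as gio, survival

from _oracles import harrell_c_pairs, td_auc_weighted_pairs


def _surv(time, event, **cov):
    df = pd.DataFrame({"time": time, "event": event, **cov},
                      index=[f"p{i}" for i in range(len(time))])
    return gio.SurvivalTable(df)


class TestUnivariateScreen:
    def test_matches_lifelines_exactly(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        em, sv = ems["PROG1"], svs["PROG1"]
        screen = survival.univariate_cox_screen(em, sv)
        for g in list(betas.index[:3]) + ["G0020", "G0045"]:
            df = pd.DataFrame(
                {"x": em.values.loc[g], "time": sv.time, "event": sv.event}
            )
            cph = CoxPHFitter().fit(df, "time", "event")
            # lifelines stops at a looser step tolerance, so agreement is
            # to its convergence precision, not machine precision
            assert screen.loc[g, "coef"] == pytest.approx(
                cph.params_["x"], rel=1e-4, abs=5e-5
            )
            assert screen.loc[g, "p"] == pytest.approx(
                cph.summary["p"]["x"], rel=1e-3, abs=1e-6
            )

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(23)
        n, n_genes = 150, 1000
        vals = pd.DataFrame(
            rng.normal(size=(n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n)],
        )
        em = gio.ExpressionMatrix(values=vals)
        time = rng.exponential(10, n)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        sv = gio.SurvivalTable(
            pd.DataFrame({"time": time, "event": event}, index=vals.columns)
        )
        screen = survival.univariate_cox_screen(em, sv)
        ks = stats.kstest(screen["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_gene_detected(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        screen = survival.univariate_cox_screen(ems["PROG1"], svs["PROG1"])
        assert (screen.loc[betas.index, "p"] < 0.01).all()

    def test_sign_convention(self):
        # high expression with early events => positive coefficient
        time = np.r_[np.linspace(1, 5, 20), np.linspace(20, 30, 20)]
        x = np.r_[np.full(20, 2.0), np.full(20, -2.0)] + np.linspace(0, 0.1, 40)
        vals = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(40)])
        em = gio.ExpressionMatrix(values=vals)
        sv = _surv(time, [1] * 40)
        sv.data.index = vals.columns
        screen = survival.univariate_cox_screen(em, gio.SurvivalTable(sv.data))
        assert screen.loc["g", "coef"] > 0
        assert screen.loc["g", "direction"] == 1


class TestMetaP:
    def _screen(self, p, direction):
        return pd.DataFrame({"p": p, "direction": direction, "coef": direction},
                            index=[f"g{i}" for i in range(len(p))])

    def test_fisher_combination_value(self):
        # X = -2(ln 0.5 + ln 0.5) = 2.7726; chi2(4) sf = 0.5966
        out = survival.meta_p(
            {"a": self._screen([0.5], [1]), "b": self._screen([0.5], [1])}
        )
        assert out.loc["g0", "meta_p"] == pytest.approx(
            stats.chi2.sf(-2 * 2 * np.log(0.5), 4)
        )
        assert out.loc["g0", "meta_p"] == pytest.approx(0.5966, abs=1e-3)

    def test_unit_p_values_stay_unit(self):
        out = survival.meta_p(
            {"a": self._screen([1.0], [1]), "b": self._screen([1.0], [1])}
        )
        assert out.loc["g0", "meta_p"] == pytest.approx(1.0)

    def test_discordant_directions_not_kept(self):
        out = survival.meta_p(
            {"a": self._screen([1e-8], [1]), "b": self._screen([1e-8], [-1])}
        )
        assert not out.loc["g0", "kept"]
        assert out.loc["g0", "meta_p"] < 0.05

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = survival.meta_p(
                {"a": self._screen([0.0], [1]), "b": self._screen([0.5], [1])}
            )
        assert out.loc["g0", "meta_p"] > 0


class TestHarrellC:
    def test_perfect_and_null_ranking(self):
        time = np.arange(1.0, 21.0)
        sv = _surv(time, [1] * 20)
        assert survival.harrell_c(-time, sv) == 1.0
        rng = np.random.default_rng(0)
        sv_big = _surv(np.arange(1.0, 2001.0), [1] * 2000)
        c = survival.harrell_c(rng.normal(size=2000), sv_big)
        assert abs(c - 0.5) < 0.03

    def test_matches_pair_enumeration_oracle(self):
        time = [2.0, 4.0, 4.0, 6.0, 7.0, 9.0, 12.0, 15.0]
        event = [1, 1, 0, 1, 0, 1, 0, 1]
        scores = [5.0, 3.0, 3.0, 4.0, 1.0, 2.0, 0.5, 0.1]
        sv = _surv(time, event)
        mine = survival.harrell_c(np.array(scores), sv)
        oracle = harrell_c_pairs(scores, time, event)
        assert mine == oracle

    def test_no_usable_pairs_rejected(self):
        sv = _surv([5.0, 5.0], [1, 1])
        with pytest.raises(ValueError):
            survival.harrell_c(np.array([1.0, 2.0]), sv)


class TestTdAuc:
    def test_perfect_ordering_no_censoring(self):
        time = np.arange(1.0, 11.0)
        sv = _surv(time, [1] * 10)
        auc = survival.td_auc(-time, sv, [5.5])
        assert auc[5.5] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        time = np.arange(1.0, 501.0)
        sv = _surv(time, [1] * 500)
        auc = survival.td_auc(rng.normal(size=500), sv, [250.0])
        assert abs(auc[250.0] - 0.5) < 0.06

    def test_matches_weighted_pair_oracle(self):
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 12.0]
        event = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]
        scores = [9.0, 3.0, 8.0, 2.0, 5.0, 6.0, 1.0, 7.0, 4.0, 0.0]
        sv = _surv(time, event)
        for tau in (4.5, 7.5):
            mine = survival.td_auc(np.array(scores), sv, [tau])[tau]
            oracle = td_auc_weighted_pairs(scores, time, event, tau)
            assert mine == pytest.approx(oracle, rel=1e-12)

    def test_agrees_with_sksurv_when_uncensored(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(2)
        time = rng.exponential(10, 80) + 0.1
        scores = -time + rng.normal(0, 3, 80)
        sv = _surv(time, [1] * 80)
        y = Surv.from_arrays(np.ones(80, dtype=bool), time)
        taus = [np.quantile(time, 0.3), np.quantile(time, 0.6)]
        theirs = cumulative_dynamic_auc(y, y, scores, taus)[0]
        mine = survival.td_auc(scores, sv, taus)
        assert np.allclose(mine.to_numpy(), theirs, atol=1e-10)

    def test_horizon_without_events_missing(self):
        sv = _surv([5.0, 6.0, 7.0, 9.0], [0, 0, 1, 1])
        auc = survival.td_auc(np.array([1.0, 2.0, 3.0, 4.0]), sv, [5.5])
        assert np.isnan(auc[5.5])


class TestSignature:
    def test_packaged_gene_list(self):
        genes = survival.packaged_signature_genes()
        assert len(genes) == 11

    def test_zero_coefficients_score_zero(self, prognostic_sim):
        ems, _svs, betas = prognostic_sim
        sig = gio.SignatureModel(
            gene_ids=list(betas.index), coefficients=np.zeros(len(betas))
        )
        scores = survival.score_samples(sig, ems["PROG1"])
        assert (scores == 0).all()

    def test_score_linearity_in_coefficients(self, prognostic_sim):
        ems, _svs, betas = prognostic_sim
        em = ems["PROG1"]
        base = gio.SignatureModel(
            gene_ids=list(betas.index), coefficients=np.ones(len(betas))
        )
        doubled = gio.SignatureModel(
            gene_ids=list(betas.index),
            coefficients=np.r_[2.0, np.ones(len(betas) - 1)],
        )
        delta = survival.score_samples(doubled, em) - survival.score_samples(base, em)
        pd.testing.assert_series_equal(
            delta, em.values.loc[betas.index[0]], check_names=False
        )

    def test_missing_gene_tolerance(self, prognostic_sim):
        ems, _svs, _betas = prognostic_sim
        em = ems["PROG1"]
        sig = gio.SignatureModel(
            gene_ids=[*em.gene_ids[:9], "ABSENT"], coefficients=np.ones(10)
        )
        with pytest.warns(UserWarning, match="dropping"):
            survival.score_samples(sig, em)
        sig_bad = gio.SignatureModel(
            gene_ids=["NO1", "NO2", "NO3", *em.gene_ids[:2]],
            coefficients=np.ones(5),
        )
        with pytest.raises(ValueError, match="missing"):
            survival.score_samples(sig_bad, em)

    def test_coefficient_recovery_across_seeds(self):
        for seed in (1, 2, 3):
            cohorts, surv, betas = datagen.simulate_prognostic(seed=seed)
            em = gio.zscore(cohorts[0])
            sv = surv.subset(em.sample_ids)
            sig = survival.fit_signature(em, sv, list(betas.index), learner="cox")
            fitted = pd.Series(sig.coefficients, index=sig.gene_ids)
            corr = np.corrcoef(fitted.loc[betas.index], betas)[0, 1]
            assert corr > 0.8

    def test_cross_cohort_generalization(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        sig = survival.fit_signature(
            ems["PROG1"], svs["PROG1"], list(betas.index), learner="cox"
        )
        scores = survival.score_samples(sig, ems["PROG2"])
        assert survival.harrell_c(scores, svs["PROG2"]) > 0.65


class TestStepwise:
    def test_recovers_signal_genes(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        em, sv = ems["PROG1"], svs["PROG1"]
        candidates = list(betas.index) + list(em.gene_ids[10:16])
        df = em.values.loc[candidates].T.copy()
        df["time"] = sv.data["time"]
        df["event"] = sv.data["event"]
        kept = survival.stepwise_cox(df, candidates)
        assert set(betas.index) <= set(kept)
        assert len(kept) <= len(betas) + 3


class TestLogrankCutoff:
    def test_bimodal_gap_found(self):
        time = np.r_[np.linspace(1, 5, 15), np.linspace(50, 60, 15)]
        scores = pd.Series(
            np.r_[np.full(15, 10.0) + np.linspace(0, 1, 15),
                  np.full(15, 0.0) + np.linspace(0, 1, 15)],
            index=[f"p{i}" for i in range(30)],
        )
        sv = _surv(time, [1] * 30)
        strat = survival.logrank_cutoff(scores, sv)
        # the chosen threshold separates exactly at the score gap
        assert 1.0 <= strat.cutoff < 10.0
        assert (strat.groups == "high").sum() == 15
        assert set(strat.groups.iloc[:15]) == {"high"}
        assert strat.logrank_p < 1e-6

    def test_high_group_has_worse_survival_on_simulated_cohort(self):
        cohorts, surv, betas = datagen.simulate_prognostic(
            n_samples=200, seed=17
        )
        em = gio.zscore(cohorts[0])
        sv = surv.subset(em.sample_ids)
        sig = survival.fit_signature(em, sv, list(betas.index), learner="cox")
        scores = survival.score_samples(sig, em)
        strat = survival.logrank_cutoff(scores, sv)
        assert strat.logrank_p < 0.001
        high = strat.groups == "high"
        med_high = sv.data.loc[high[high].index, "time"].median()
        med_low = sv.data.loc[high[~high].index, "time"].median()
        assert med_high < med_low

    def test_constant_scores_rejected(self):
        sv = _surv(np.arange(1.0, 13.0), [1] * 12)
        scores = pd.Series(np.ones(12), index=sv.sample_ids)
        with pytest.raises(ValueError, match="identical"):
            survival.logrank_cutoff(scores, sv)


class TestMultivariateCox:
    def test_duplicated_covariate_is_rank_deficient(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        sv = _surv(rng.exponential(10, n) + 0.1, [1] * n, age=x, age2=x)
        scores = pd.Series(rng.normal(size=n), index=sv.sample_ids)
        with pytest.raises(ValueError, match="rank deficient"):
            survival.multivariate_cox(sv, scores, covariates=["age", "age2"])

    def test_covariate_free_call_matches_univariate(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        em, sv = ems["PROG1"], svs["PROG1"]
        sig = survival.fit_signature(em, sv, list(betas.index), learner="cox")
        scores = survival.score_samples(sig, em)
        bare = gio.SurvivalTable(sv.data[["time", "event"]])
        out = survival.multivariate_cox(bare, scores)
        df = pd.DataFrame({"x": scores, "time": sv.time, "event": sv.event})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert out.loc["score", "coef"] == pytest.approx(cph.params_["x"], rel=1e-6)

    def test_independent_covariates_leave_hr_stable(self):
        cohorts, surv, betas = datagen.simulate_prognostic(seed=17)
        em = gio.zscore(cohorts[0])
        sv = surv.subset(em.sample_ids)
        rng = np.random.default_rng(17)
        data = sv.data.copy()
        data["age"] = rng.normal(60, 8, len(data))
        sv2 = gio.SurvivalTable(data.drop(columns="cohort"))
        sig = survival.fit_signature(em, sv, list(betas.index), learner="cox")
        scores = survival.score_samples(sig, em)
        uni = survival.multivariate_cox(
            gio.SurvivalTable(data[["time", "event"]]), scores
        )
        multi = survival.multivariate_cox(sv2, scores, covariates=["age"])
        assert (
            multi.loc["score", "ci_low"]
            <= uni.loc["score", "hr"]
            <= multi.loc["score", "ci_high"]
        )


class TestBenchmark:
    def test_single_pair_registry(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        genes = list(betas.index) + list(ems["PROG1"].gene_ids[10:20])
        table = survival.run_benchmark(
            ems, svs, genes, training_cohort="PROG1",
            registry={"selectors": ["StepCox"], "learners": ["StepCox"]},
            seed=17,
        )
        assert len(table) == 1
        assert table.loc[0, "c_PROG1"] > 0.7

    def test_strong_signal_beats_chance_for_every_learner(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        genes = list(betas.index) + list(ems["PROG1"].gene_ids[10:20])
        table = survival.run_benchmark(
            ems, svs, genes, training_cohort="PROG1",
            registry={"selectors": ["Lasso"],
                      "learners": ["Ridge", "GBM", "SuperPC", "plsRcox"]},
            seed=17,
        )
        assert (table["c_PROG1"] > 0.7).all()

    def test_permuted_survival_is_null(self, prognostic_sim):
        ems, svs, _betas = prognostic_sim
        rng = np.random.default_rng(17)
        sv = svs["PROG1"]
        permuted_data = sv.data.copy()
        permuted_data[["time", "event"]] = (
            sv.data[["time", "event"]].sample(frac=1, random_state=17).to_numpy()
        )
        svs_null = {"PROG1": gio.SurvivalTable(permuted_data)}
        ems_null = {"PROG1": ems["PROG1"]}
        genes = list(ems["PROG1"].gene_ids[:15])
        table = survival.run_benchmark(
            ems_null, svs_null, genes, training_cohort="PROG1",
            registry={"selectors": ["CoxBoost"], "learners": ["Ridge"]},
            seed=17,
        )
        # in-sample fit on permuted outcomes keeps the held-in C-index
        # near chance for a penalized linear learner
        assert 0.4 <= table.loc[0, "c_PROG1"] <= 0.72

    def test_ranking_invariant_to_registry_order(self, prognostic_sim):
        ems, svs, betas = prognostic_sim
        genes = list(betas.index) + list(ems["PROG1"].gene_ids[10:18])
        a = survival.run_benchmark(
            ems, svs, genes, training_cohort="PROG1",
            registry={"selectors": ["StepCox", "Lasso"], "learners": ["Ridge", "StepCox"]},
            seed=17,
        )
        b = survival.run_benchmark(
            ems, svs, genes, training_cohort="PROG1",
            registry={"selectors": ["Lasso", "StepCox"], "learners": ["StepCox", "Ridge"]},
            seed=17,
        )
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_screened_genes_rejected(self, prognostic_sim):
        ems, svs, _betas = prognostic_sim
        with pytest.raises(ValueError, match="at least 5"):
            survival.run_benchmark(
                ems, svs, list(ems["PROG1"].gene_ids[:3]),
                training_cohort="PROG1",
            )
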