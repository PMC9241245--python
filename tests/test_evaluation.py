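"""Performance metrics: logistic ORs, AUCs, liability R², tails, PPV/NPV,
decile calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prs_transcal import (EvaluationInput, auc, auc_suite,
                          calibration_by_decile, liability_factor,
                          liability_r2, logistic_fit, metrics_report,
                          or_per_sd, ppv_npv, tail_metrics)


def two_by_two_layout():
    """8 exposed cases, 12 exposed controls, 92 unexposed cases, 888
    unexposed controls: cross-product OR = (8*888)/(12*92) = 6.43."""
    status = np.r_[np.ones(8), np.zeros(12), np.ones(92), np.zeros(888)]
    exposed = np.r_[np.ones(20), np.zeros(980)]
    return status, exposed


def logistic_sim(n, or_per_sd_true, prevalence=0.2, seed=0):
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    intercept = np.log(prevalence / (1 - prevalence))
    p = 1 / (1 + np.exp(-(intercept + np.log(or_per_sd_true) * score)))
    return (rng.random(n) < p).astype(int), score


class TestLogisticFit:
    def test_two_by_two_matches_cross_product_oracle(self):
        status, exposed = two_by_two_layout()
        fit = logistic_fit(status, exposed[:, None])
        assert np.exp(fit.params[1]) == pytest.approx(6.4348, abs=0.01)

    def test_null_predictor(self):
        rng = np.random.default_rng(1)
        status = rng.integers(0, 2, 10_000)
        x = rng.standard_normal(10_000)
        fit = logistic_fit(status, x[:, None])
        assert 0.9 < np.exp(fit.params[1]) < 1.1

    def test_generative_or_recovery(self):
        status, score = logistic_sim(20_000, 2.0, seed=2)
        fit = logistic_fit(status, score[:, None])
        assert 1.85 < np.exp(fit.params[1]) < 2.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            logistic_fit(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))

    def test_separation_flagged(self):
        status = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), -np.ones(20)]
        fit = logistic_fit(status, x[:, None])
        assert fit.separation_flag


class TestOrPerSd:
    def test_scale_invariance(self):
        status, score = logistic_sim(2000, 1.8, seed=3)
        inp1 = EvaluationInput(status, score)
        inp2 = EvaluationInput(status, 37.5 * score)
        o1, _ = or_per_sd(inp1)
        o2, _ = or_per_sd(inp2)
        assert o1 == pytest.approx(o2, abs=1e-8)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            or_per_sd(EvaluationInput(np.r_[np.ones(5), np.zeros(5)],
                                      np.ones(10)))


class TestAuc:
    def test_four_point_exhaustive_pair_count(self):
        # cases {2, 3}, controls {1, 2.5}: 3 of 4 pairs concordant
        assert auc([1, 0, 1, 0], [2, 1, 3, 2.5]) == 0.75

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [1, 2, 3, 4]) == 1.0

    def test_all_ties(self):
        assert auc([0, 1, 0, 1], [5, 5, 5, 5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.1, 0.2])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        status = rng.integers(0, 2, 500)
        score = rng.standard_normal(500)
        a = auc(status, score)
        assert auc(status, np.exp(score)) == pytest.approx(a, abs=1e-12)
        assert auc(status, 3 * score - 7) == pytest.approx(a, abs=1e-12)

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        status = rng.integers(0, 2, 300)
        score = rng.normal(size=300).round(1)  # force ties
        assert auc(status, score) == pytest.approx(
            roc_auc_score(status, score), abs=1e-12)


class TestAucSuite:
    def test_null_score_with_informative_covariates(self):
        rng = np.random.default_rng(6)
        n = 10_000
        age = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + age)))
        status = (rng.random(n) < p).astype(int)
        score = rng.standard_normal(n)  # independent of everything
        inp = EvaluationInput(status, score, pd.DataFrame({"age": age}))
        res = auc_suite(inp)
        cov_auc = res["auc_covariates_only"]
        assert cov_auc > 0.6
        assert res["auc_prs_only"] == pytest.approx(0.5, abs=0.02)
        assert res["auc_prs_covariate_adjusted"] == pytest.approx(0.5, abs=0.02)
        assert res["auc_combined"] == pytest.approx(cov_auc, abs=0.02)

    def test_constant_covariates_residualization_noop(self):
        status, score = logistic_sim(1000, 2.0, seed=7)
        inp = EvaluationInput(status, score,
                              pd.DataFrame({"c": np.ones(1000)}))
        res = auc_suite(inp)
        assert res["auc_prs_covariate_adjusted"] == res["auc_prs_only"]

    def test_combined_not_below_covariates_only(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 2000
            age = rng.normal(size=n)
            status, score = logistic_sim(n, 1.5, seed=seed + 100)
            inp = EvaluationInput(status, score, pd.DataFrame({"age": age}))
            res = auc_suite(inp)
            assert res["auc_combined"] >= res["auc_covariates_only"] - 0.01


class TestLiabilityR2:
    def test_zero_observed_r2_maps_to_zero(self):
        rng = np.random.default_rng(8)
        status = rng.integers(0, 2, 200)
        inp = EvaluationInput(status, np.zeros(200) + 1e-12, prevalence=0.1)
        assert liability_r2(inp) == pytest.approx(0.0, abs=1e-6)

    def test_balanced_design_factor_is_half_pi(self):
        # K = P = 0.5: z = 1/sqrt(2*pi), C = pi/2
        assert liability_factor(0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-10)

    def test_population_sample_reduction(self):
        # K = P: C reduces to K(1-K)/z^2
        for k in (0.1, 0.25, 0.4):
            z = stats.norm.pdf(stats.norm.isf(k))
            assert liability_factor(k, k) == pytest.approx(
                k * (1 - k) / z ** 2, rel=1e-12)

    def test_ascertained_generative_recovery(self):
        """A score explaining 9% of liability variance, K=0.10, case-
        control sampled to P=0.5, recovers 0.09 on the liability scale."""
        rng = np.random.default_rng(9)
        n_pool, h2, k = 400_000, 0.09, 0.10
        g = rng.standard_normal(n_pool) * np.sqrt(h2)
        liab = g + rng.standard_normal(n_pool) * np.sqrt(1 - h2)
        case = liab > stats.norm.isf(k)
        cases = np.flatnonzero(case)[:10_000]
        controls = np.flatnonzero(~case)[:10_000]
        idx = np.r_[cases, controls]
        inp = EvaluationInput(case[idx].astype(int), g[idx], prevalence=k)
        assert liability_r2(inp) == pytest.approx(0.09, abs=0.015)

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            EvaluationInput(np.r_[1, 0], np.r_[0.0, 1.0], prevalence=0.0)
        with pytest.raises(ValueError, match="case fraction"):
            liability_r2(EvaluationInput(np.r_[1, 1], np.r_[0.0, 1.0],
                                         prevalence=0.1))


class TestPpvNpv:
    def test_printed_european_row(self):
        # sens 0.05, spec 0.99, prev 0.10 -> NPV 0.90 at two decimals
        _, npv = ppv_npv(0.05, 0.99, 0.10)
        assert round(npv, 2) == 0.90

    def test_perfect_classifier(self):
        assert ppv_npv(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_direct_formula_arithmetic(self):
        ppv, _ = ppv_npv(0.07, 0.98, 0.137)
        assert ppv == pytest.approx(0.357, abs=5e-4)

    def test_monotone_in_prevalence(self):
        prevs = np.linspace(0.01, 0.99, 25)
        vals = [ppv_npv(0.3, 0.9, p) for p in prevs]
        ppvs, npvs = zip(*vals)
        assert np.all(np.diff(ppvs) > 0)
        assert np.all(np.diff(npvs) < 0)

    def test_zero_denominator_is_defined_error(self):
        with pytest.raises(ZeroDivisionError):
            ppv_npv(0.0, 1.0, 0.0)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            ppv_npv(1.2, 0.9, 0.1)


class TestTailMetrics:
    def test_null_tail_or_near_one(self):
        rng = np.random.default_rng(10)
        n = 50_000
        status = rng.integers(0, 2, n)
        score = rng.standard_normal(n)
        tm = tail_metrics(EvaluationInput(status, score, prevalence=0.1), 10)
        assert 0.85 < tm.or_estimate < 1.15

    def test_two_by_two_layout_as_two_percent_tail(self):
        status, exposed = two_by_two_layout()
        score = np.where(exposed == 1, 2.0, 1.0)
        tm = tail_metrics(EvaluationInput(status, score, prevalence=0.1), 2)
        assert tm.n_top == 20
        assert tm.or_estimate == pytest.approx(6.4348, abs=0.01)
        assert tm.sensitivity == pytest.approx(0.08, abs=1e-12)
        assert tm.specificity == pytest.approx(888 / 900, abs=1e-12)

    def test_or_grows_toward_extreme_cutoffs(self):
        """With real signal, mean OR over replicates is ordered
        top 2% >= top 5% >= top 10%."""
        ors = {2: [], 5: [], 10: []}
        for seed in range(20):
            status, score = logistic_sim(4000, 2.0, seed=200 + seed)
            inp = EvaluationInput(status, score, prevalence=0.2)
            for c in ors:
                ors[c].append(tail_metrics(inp, c).or_estimate)
        m = {c: np.mean(v) for c, v in ors.items()}
        assert m[2] >= m[5] >= m[10] > 1.0

    def test_cutoff_validation(self):
        status, score = logistic_sim(100, 1.0, seed=11)
        with pytest.raises(ValueError):
            tail_metrics(EvaluationInput(status, score), 60)


class TestCalibration:
    def test_true_probabilities_are_calibrated(self):
        rng = np.random.default_rng(12)
        n = 20_000
        p = 1 / (1 + np.exp(-rng.normal(-1.5, 1.0, n)))
        status = (rng.random(n) < p).astype(int)
        tab = calibration_by_decile(status, p)
        assert np.max(np.abs(tab["predicted_risk"] - tab["observed_risk"])) < 0.03

    def test_equal_group_sizes(self):
        rng = np.random.default_rng(13)
        tab = calibration_by_decile(rng.integers(0, 2, 100), rng.random(100))
        assert tab["n"].tolist() == [10] * 10

    def test_miscalibration_direction(self):
        rng = np.random.default_rng(14)
        n = 20_000
        p = 1 / (1 + np.exp(-rng.normal(-0.5, 1.0, n)))
        status = (rng.random(n) < p).astype(int)
        tab = calibration_by_decile(status, p ** 2, score=p)
        top = tab.iloc[-1]
        assert top["observed_risk"] > top["predicted_risk"]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            calibration_by_decile(np.r_[1, 0, 1], np.r_[0.5, 0.5, 0.5])


class TestMetricsReport:
    def test_full_report_on_signal_cohort(self):
        rng = np.random.default_rng(15)
        n = 8000
        age = rng.normal(size=n)
        score = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-2.0 + 0.7 * score + 0.3 * age)))
        status = (rng.random(n) < p).astype(int)
        inp = EvaluationInput(status, score, pd.DataFrame({"age": age}),
                              prevalence=0.1)
        rep = metrics_report(inp)
        assert rep.n_samples == n
        assert 0 < rep.liability_r2 < 1
        assert rep.auc_prs_only > 0.6
        assert rep.or_per_sd_ci[0] < rep.or_per_sd < rep.or_per_sd_ci[1]
        assert [t.cutoff_percent for t in rep.tail] == [2.0, 5.0, 10.0]
        assert len(rep.calibration) == 10
        # qualitative ordering of tail ORs vs OR/SD on a strong score
        assert rep.tail[0].or_estimate > rep.or_per_sd
        d = rep.to_dict()
        assert set(d["calibration"]) == {"decile", "n", "predicted_risk",
                                         "observed_risk"}
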