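"""Cox fitting (Breslow ties), KM estimation, scans and the binomial death test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import mpascore as mp
from mpascore.survival import _fit_arrays


def _clin(time, event, **covs):
    return mp.ClinicalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(time))],
        "time": time, "event": event, **covs,
    }))


def _null_cohort(seed, n=200, beta=0.0):
    r = np.random.default_rng(seed)
    score = r.normal(0, 1, n)
    st = mp.ScoreTable(tuple(f"s{i}" for i in range(n)), score, "MPAS", 10)
    cfg = mp.CohortConfig(n_samples=n, beta_survival=beta)
    return mp.generate_clinical(cfg, st, r), score


class TestKM:
    def test_no_events_flat_curve(self):
        est = mp.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (est.survival == 1.0).all()
        assert est.median is None

    def test_product_limit_by_hand(self):
        est = mp.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(
            [est.at(1.0), est.at(2.0), est.at(3.0)], [2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert est.median == 2.0

    def test_matches_direct_product_limit_with_censoring(self, rng):
        time = rng.exponential(5, 60).round(1) + 0.1
        event = rng.integers(0, 2, 60)
        est = mp.km_estimate(time, event)
        # direct product-limit recomputation
        s = 1.0
        for t in np.unique(time):
            at_risk = np.sum(time >= t)
            d = np.sum((time == t) & (event == 1))
            s *= 1.0 - d / at_risk
            assert est.at(t) == pytest.approx(s, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mp.km_estimate([], [])


class TestCoxFit:
    def test_four_record_hand_case_vs_numeric_partial_likelihood(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = mp.cox_fit(_clin(time, event, x=x), ["x"])

        def neg_pl(beta):  # independent hand-written partial likelihood
            ll = 0.0
            for i in range(4):
                if event[i]:
                    risk = time >= time[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        res = optimize.minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_duplicating_records_leaves_beta_unchanged(self, rng):
        n = 50
        time = rng.exponential(5, n)
        event = rng.integers(0, 2, n)
        event[:5] = 1
        x = rng.normal(0, 1, n)
        f1 = _fit_arrays(time, event, x[:, None], ["x"])
        f2 = _fit_arrays(np.tile(time, 2), np.tile(event, 2), np.tile(x, 2)[:, None], ["x"])
        assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-8)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        df = pd.DataFrame({
            "time": rng.exponential(1, n),  # continuous -> tie-free
            "event": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
            "w": rng.normal(size=n),
        })
        cph = CoxPHFitter().fit(df, "time", "event")
        ours = _fit_arrays(df["time"].values, df["event"].values,
                           df[["x", "w"]].values, ["x", "w"])
        np.testing.assert_allclose(ours.beta, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(ours.se, cph.standard_errors_.values, atol=1e-5)

    def test_hr_and_ci_consistency(self):
        clin, score = _null_cohort(3, n=150, beta=np.log(2.0))
        fit = mp.cox_fit(clin, ["score"])
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]), rel=1e-12)
        lo, hi = fit.ci95[0]
        assert lo <= fit.hr[0] <= hi

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            clin, score = _null_cohort(seed, n=300, beta=0.0)
            fit = mp.cox_fit(clin, ["score"])
            lo, hi = fit.ci95[0]
            covered += lo <= 1.0 <= hi
        assert covered >= 17  # ~95% nominal coverage

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            mp.cox_fit(_clin([1, 2, 3, 4], [1, 1, 1, 0], x=[1.0] * 4), ["x"])

    def test_perfect_separation_flagged(self):
        # covariate perfectly orders survival: monotone likelihood
        n = 30
        time = np.arange(1, n + 1, dtype=float)
        event = np.ones(n, dtype=int)
        x = -time  # higher x -> earlier death, perfectly
        fit = _fit_arrays(time, event, x[:, None], ["x"])
        assert not fit.converged

    def test_logrank_reported_for_binary_terms(self):
        clin, _ = _null_cohort(5, n=120)
        grp = (np.arange(120) % 2).astype(float)
        clin2 = _clin(clin.time, clin.event, grp=grp)
        fit = mp.cox_fit(clin2, ["grp"])
        assert "grp" in fit.logrank_p
        assert 0.0 <= fit.logrank_p["grp"] <= 1.0


class TestDichotomizeAndScans:
    def test_median_dichotomize_examples(self):
        assert mp.median_dichotomize([-1.0, 0.0, 1.0, 2.0]).tolist() == [False, False, True, True]
        assert mp.median_dichotomize([1.0, 2.0, 3.0]).tolist() == [False, False, True]

    def test_distinct_scores_split_floor_half(self, rng):
        scores = rng.normal(size=25)
        assert mp.median_dichotomize(scores).sum() == 12

    def test_threshold_scan_at_median_matches_dichotomization(self):
        clin, score = _null_cohort(9, n=120, beta=np.log(1.5))
        scan = mp.km_threshold_scan(clin, score, lo_pct=50, hi_pct=50, step_pct=10)
        row = scan.table.iloc[0]
        labels = mp.median_dichotomize(score)
        fit = _fit_arrays(clin.time, clin.event, labels.astype(float)[:, None], ["g"])
        assert row["hr"] == pytest.approx(np.exp(fit.beta[0]), rel=1e-10)
        assert row["n_high"] == labels.sum()

    def test_threshold_scan_grid_and_nulls(self):
        clin, score = _null_cohort(2, n=60)
        scan = mp.km_threshold_scan(clin, score, lo_pct=10, hi_pct=90, step_pct=10)
        assert scan.table["position_pct"].tolist() == [10, 20, 30, 40, 50, 60, 70, 80, 90]
        assert (scan.table["n_high"] + scan.table["n_low"] == 60).all()

    def test_hazardous_score_gives_hr_above_one(self):
        clin, score = _null_cohort(4, n=400, beta=np.log(2.0))
        scan = mp.km_threshold_scan(clin, score)
        assert (scan.table["hr"].dropna() > 1.0).all()

    def test_window_positions_cover_15_to_85(self):
        clin, score = _null_cohort(6, n=300)
        scan = mp.sliding_window_scan(clin, score, window_pct=30, step_pct=2)
        pos = scan.table["position_pct"]
        assert pos.iloc[0] == 15.0 and pos.iloc[-1] == 85.0
        np.testing.assert_allclose(np.diff(pos), 2.0)
        assert scan.table["window_lo_pct"].iloc[0] == 0.0
        assert scan.table["window_hi_pct"].iloc[-1] == 100.0

    def test_protective_score_window_hr_declines(self):
        wins = 0
        for seed in range(10):
            clin, score = _null_cohort(100 + seed, n=300, beta=-np.log(2.0))
            scan = mp.sliding_window_scan(clin, score)
            tbl = scan.table.set_index("position_pct")
            if tbl.loc[85.0, "hr"] < tbl.loc[15.0, "hr"]:
                wins += 1
        assert wins >= 9

    def test_remainder_vs_population_reference(self):
        clin, score = _null_cohort(8, n=300, beta=np.log(1.5))
        pop = mp.sliding_window_scan(clin, score, comparator="population").table
        rem = mp.sliding_window_scan(clin, score, comparator="remainder").table
        f = pop["n_in"] / 300.0
        conv = rem["hr"] / (f * rem["hr"] + (1 - f))
        np.testing.assert_allclose(pop["hr"], conv, rtol=1e-10)

    def test_oversized_window_errors(self):
        clin, score = _null_cohort(1, n=50)
        with pytest.raises(ValueError):
            mp.sliding_window_scan(clin, score, window_pct=99.5, step_pct=2)


class TestBinomialDeathTest:
    def test_proportional_split_is_null(self):
        # 4 of 8 deaths in a half-sized group -> maximally null
        time = np.ones(16)
        event = np.array([1] * 8 + [0] * 8)
        groups = np.array([True, False] * 8)
        p = mp.binomial_death_test(_clin(time, event), groups)
        assert p == pytest.approx(1.0)

    def test_extreme_enrichment(self):
        # all 10 deaths in a half-sized high group: p = 2 * 0.5^10
        time = np.ones(20)
        event = np.array([1] * 10 + [0] * 10)
        groups = np.array([True] * 10 + [False] * 10)
        p = mp.binomial_death_test(_clin(time, event), groups)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    @pytest.mark.parametrize("k,K,n_high,n", [(3, 7, 10, 30), (5, 12, 12, 36), (0, 9, 15, 45)])
    def test_matches_exhaustive_pmf_enumeration(self, k, K, n_high, n):
        time = np.ones(n)
        event = np.zeros(n, dtype=int)
        groups = np.zeros(n, dtype=bool)
        groups[:n_high] = True
        # place k deaths in the high group, K-k in the low group
        event[:k] = 1
        event[n_high:n_high + K - k] = 1
        p = mp.binomial_death_test(_clin(time, event), groups)
        p0 = n_high / n
        pmf = np.array([stats.binom.pmf(i, K, p0) for i in range(K + 1)])
        expected = float(pmf[pmf <= pmf[k] * (1 + 1e-10)].sum())
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_deaths_errors(self):
        with pytest.raises(ValueError, match="no deaths"):
            mp.binomial_death_test(_clin([1, 2], [0, 0]), np.array([True, False]))


class TestMultivariate:
    def test_single_term_equals_univariate(self):
        clin, score = _null_cohort(12, n=150, beta=np.log(1.5))
        joint = mp.multivariate_survival_report(clin, ["score"])
        uni = mp.cox_fit(clin, ["score"])
        assert joint.beta[0] == pytest.approx(uni.beta[0], abs=1e-10)

    def test_constant_shifted_copy_raises_collinearity(self):
        clin, score = _null_cohort(13, n=100)
        df = clin.data.copy()
        df["score2"] = df["score"] + 3.0
        clin2 = mp.ClinicalTable(df)
        with pytest.raises(ValueError, match="collinear"):
            mp.multivariate_survival_report(clin2, ["score", "score2"])

    def test_categorical_covariate_expanded(self):
        clin, score = _null_cohort(14, n=120)
        df = clin.data.copy()
        df["arm"] = np.where(np.arange(120) % 2 == 0, "FOLFOX", "XELOX")
        fit = mp.multivariate_survival_report(mp.ClinicalTable(df), ["score", "arm"])
        assert any(t.startswith("arm_") for t in fit.terms)

    def test_joint_recovery_of_score_effect_with_null_subtype(self):
        hits_score, hits_subtype = 0, 0
        for seed in range(15):
            r = np.random.default_rng(3000 + seed)
            n = 300
            score = r.normal(0, 1, n)
            st = mp.ScoreTable(tuple(f"s{i}" for i in range(n)), score, "MPAS", 10)
            cfg = mp.CohortConfig(n_samples=n, beta_survival=np.log(1.6))
            clin = mp.generate_clinical(cfg, st, r)
            fit = mp.multivariate_survival_report(clin, ["score", "subtype"])
            terms = dict(zip(fit.terms, range(len(fit.terms))))
            lo, hi = fit.ci95[terms["score"]]
            hits_score += not (lo <= 1.0 <= hi)  # effect detected
            lo, hi = fit.ci95[terms["subtype"]]
            hits_subtype += lo <= 1.0 <= hi      # null covered
        assert hits_score >= 12
        assert hits_subtype >= 12
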