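import numpy as np
import pandas as pd
import pytest

from gliorad.evaluation import (
    CutoffScanResult,
    EvaluationError,
    PrfThresholds,
    cox_multivariate_backward,
    cox_univariate,
    kaplan_meier_by_group,
    log_rank,
    prf_cutoff_scan,
    prf_three_group,
    time_dependent_auc,
)

from oracles import cumulative_dynamic_auc_brute


def surv_df(times, events, **cols):
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "os_months": times,
            "event": events,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return df


def simulate_cohort(rng, n, beta=0.0, covariate=None, rate=1 / 12):
    x = rng.integers(0, 2, n) if covariate is None else np.asarray(covariate)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    c = rng.uniform(0, 80, n)
    return surv_df(np.minimum(t, c), (t <= c).astype(int), x=x), x


class TestKaplanMeier:
    def test_curve_drops_1_over_n_without_censoring(self):
        df = surv_df([1, 2, 3, 4], [1, 1, 1, 1])
        km = kaplan_meier_by_group(df, ["g"] * 4)["g"]
        sf = km["curve"].iloc[:, 0]
        assert np.allclose(sf.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0])
        assert km["median"] == 2.0

    def test_identical_groups_identical_curves(self, rng):
        t = rng.exponential(10, 40)
        df = surv_df(np.concatenate([t, t]), [1] * 80)
        km = kaplan_meier_by_group(df, ["a"] * 40 + ["b"] * 40)
        pd.testing.assert_frame_equal(
            km["a"]["curve"].rename(columns={"a": "s"}),
            km["b"]["curve"].rename(columns={"b": "s"}),
        )

    def test_curve_starts_at_one_and_is_nonincreasing(self, rng):
        t = rng.exponential(10, 60)
        c = rng.integers(0, 2, 60)
        km = kaplan_meier_by_group(surv_df(t, c), ["g"] * 60)["g"]
        sf = km["curve"].iloc[:, 0].to_numpy()
        assert sf[0] <= 1.0 + 1e-12
        assert (np.diff(sf) <= 1e-12).all()

    def test_empty_group_is_error(self):
        df = surv_df([1, 2], [1, 1])
        with pytest.raises(EvaluationError):
            kaplan_meier_by_group(df.iloc[:0], np.array([]))


class TestLogRank:
    def test_type_i_error_near_nominal(self, rng):
        # both groups from the same exponential: ~5% rejections
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            t = rng.exponential(10, 100)
            g = np.array(["a"] * 50 + ["b"] * 50)
            _, p = log_rank(surv_df(t, [1] * 100), g)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_power_against_hazard_ratio_3(self, rng):
        hits = 0
        for _ in range(40):
            g = np.array([0] * 50 + [1] * 50)
            t = rng.exponential(1.0 / (0.1 * np.exp(np.log(3) * g)))
            _, p = log_rank(surv_df(t, [1] * 100), g.astype(str))
            hits += p < 0.05
        assert hits >= 38

    def test_matches_permutation_null_on_small_fixture(self, rng):
        # the observed statistic should be an unexceptional draw from its
        # permutation distribution under exchangeable labels
        t = rng.exponential(10, 20)
        e = np.ones(20, dtype=int)
        df = surv_df(t, e)
        g0 = np.array(["a"] * 10 + ["b"] * 10)
        stat0, _ = log_rank(df, g0)
        perm_stats = []
        for _ in range(300):
            perm_stats.append(log_rank(df, rng.permutation(g0))[0])
        p_perm = np.mean(np.asarray(perm_stats) >= stat0)
        # chi2(1) tail of stat0 should roughly match the permutation tail
        from scipy.stats import chi2

        p_chi2 = chi2.sf(stat0, 1)
        assert abs(p_perm - p_chi2) < 0.12

    def test_requires_two_groups_and_an_event(self):
        df = surv_df([1, 2], [1, 1])
        with pytest.raises(EvaluationError):
            log_rank(df, ["a", "a"])
        with pytest.raises(EvaluationError):
            log_rank(surv_df([1, 2], [0, 0]), ["a", "b"])


class TestCoxUnivariate:
    def test_null_covariate_hr_near_one(self, rng):
        df, _ = simulate_cohort(rng, 500, beta=0.0)
        r = cox_univariate(df, "x")
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_recovers_true_hazard_ratio_2(self, rng):
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            df, _ = simulate_cohort(rng, 1000, beta=np.log(2.0))
            r = cox_univariate(df, "x")
            covered += r.ci_low <= 2.0 <= r.ci_high
        assert covered / n_rep >= 0.88  # ~95% nominal coverage

    def test_reference_flip_inverts_hr(self, rng):
        df, x = simulate_cohort(rng, 300, beta=0.8)
        r1 = cox_univariate(df, "x")
        df2 = df.copy()
        df2["x"] = 1 - df2["x"]
        r2 = cox_univariate(df2, "x")
        assert r2.hr == pytest.approx(1.0 / r1.hr, rel=1e-6)

    def test_degenerate_variable_is_error(self):
        df = surv_df([1, 2, 3], [1, 1, 1], x=[1, 1, 1])
        with pytest.raises(EvaluationError):
            cox_univariate(df, "x")


class TestBackwardElimination:
    def test_true_covariate_survives_noise(self, rng):
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            x = rng.integers(0, 2, 500)
            noise = {f"n{i}": rng.integers(0, 2, 500) for i in range(4)}
            t = rng.exponential(1.0 / (0.08 * np.exp(1.0 * x)))
            df = surv_df(t, [1] * 500, x=x, **noise)
            res = cox_multivariate_backward(df, ["x", "n0", "n1", "n2", "n3"])
            hits += "x" in res.variables
        assert hits >= 18

    def test_all_noise_mostly_eliminated(self, rng):
        empty = 0
        n_rep = 20
        for _ in range(n_rep):
            noise = {f"n{i}": rng.integers(0, 2, 200) for i in range(4)}
            df = surv_df(rng.exponential(10, 200), [1] * 200, **noise)
            res = cox_multivariate_backward(df, list(noise))
            empty += len(res.variables) == 0
        assert empty >= n_rep // 2 + 1

    def test_single_significant_candidate_retained(self, rng):
        x = rng.integers(0, 2, 400)
        t = rng.exponential(1.0 / (0.1 * np.exp(1.2 * x)))
        df = surv_df(t, [1] * 400, x=x)
        res = cox_multivariate_backward(df, ["x"])
        assert res.variables == ["x"]
        assert res.final[0].p < 0.05

    def test_elimination_trace_records_removals(self, rng):
        noise = {f"n{i}": rng.integers(0, 2, 150) for i in range(3)}
        df = surv_df(rng.exponential(10, 150), [1] * 150, **noise)
        res = cox_multivariate_backward(df, list(noise))
        assert len(res.trace) == 3 - len(res.variables)


class TestTimeDependentAuc:
    def test_null_score_auc_near_half(self, rng):
        t = rng.exponential(12, 1000)
        df = surv_df(t, [1] * 1000)
        score = rng.standard_normal(1000)
        res = time_dependent_auc(df, score, grid=[6, 12, 18])
        assert np.nanmax(np.abs(res.auc - 0.5)) < 0.05

    def test_equals_brute_force_pairs_without_censoring(self, rng):
        t = rng.exponential(12, 50)
        z = rng.standard_normal(50)
        lam = 0.08 * np.exp(0.8 * z)
        t = rng.exponential(1.0 / lam)
        df = surv_df(t, [1] * 50)
        res = time_dependent_auc(df, z, grid=[6, 12])
        for k, tt in enumerate([6, 12]):
            ref = cumulative_dynamic_auc_brute(t, [1] * 50, z, tt)
            assert res.auc[k] == pytest.approx(ref, abs=1e-10)
            assert res.auc[k] > 0.5

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(12, 80)
        z = rng.standard_normal(80)
        df = surv_df(t, [1] * 80)
        a = time_dependent_auc(df, z, grid=[6, 12])
        b = time_dependent_auc(df, np.exp(3 * z), grid=[6, 12])
        assert np.allclose(a.auc, b.auc, equal_nan=True)

    def test_out_of_range_grid_point_is_nan(self, rng):
        t = rng.uniform(1, 20, 40)
        df = surv_df(t, [1] * 40)
        res = time_dependent_auc(df, rng.standard_normal(40), grid=[6, 500])
        assert np.isnan(res.auc[1])


class TestPrfCutoffScan:
    def _threshold_cohort(self, rng, n, cstar=0.016):
        f = rng.uniform(0.005, 0.03, n)
        rate = np.where(f >= cstar, 0.18, 0.05)  # planted threshold effect
        t = rng.exponential(1.0 / rate)
        return surv_df(t, [1] * n, prf=f)

    def test_planted_threshold_recovered(self, rng):
        cohorts = {f"D{k}": self._threshold_cohort(rng, 120) for k in (1, 2, 3)}
        res = prf_cutoff_scan(cohorts, "prf")
        lo, hi = res.common_significant_interval
        assert lo <= 0.016 <= hi

    def test_null_feature_interval_usually_empty(self, rng):
        empties = 0
        n_rep = 10
        for _ in range(n_rep):
            cohorts = {
                f"D{k}": surv_df(rng.exponential(10, 60), [1] * 60,
                                 prf=rng.uniform(0.005, 0.03, 60))
                for k in (1, 2)
            }
            res = prf_cutoff_scan(cohorts, "prf")
            empties += res.common_significant_interval is None
        assert empties >= 8

    def test_single_cohort_reduces_to_own_range(self, rng):
        c = self._threshold_cohort(rng, 150)
        res = prf_cutoff_scan({"D1": c}, "prf")
        assert isinstance(res, CutoffScanResult)
        assert res.common_significant_interval is not None

    def test_invariant_to_cohort_ordering(self, rng):
        a = self._threshold_cohort(rng, 100)
        b = self._threshold_cohort(rng, 100)
        r1 = prf_cutoff_scan({"D1": a, "D2": b}, "prf")
        r2 = prf_cutoff_scan({"D2": b, "D1": a}, "prf")
        assert r1.common_significant_interval == r2.common_significant_interval

    def test_out_of_range_cutoffs_non_evaluable(self, rng):
        c = self._threshold_cohort(rng, 50)
        res = prf_cutoff_scan({"D1": c}, "prf", grid=np.array([0.5, 0.9]))
        assert res.p_values.isna().all().all()
        assert res.common_significant_interval is None


class TestPrfThreeGroup:
    def test_published_thresholds_assign_bands(self):
        df = surv_df([5, 10, 15], [1, 1, 1], prf=[0.010, 0.016, 0.020])
        res = prf_three_group(df, "prf")
        assert list(res.labels) == ["Low", "Mid", "High"]

    def test_single_band_degrades_with_no_test(self, rng):
        df = surv_df(rng.exponential(10, 20), [1] * 20, prf=np.full(20, 0.01))
        res = prf_three_group(df, "prf")
        assert res.overall_p is None
        assert res.pairwise_p == {}

    def test_low_vs_high_smallest_pairwise_p_under_monotone_effect(self, rng):
        wins = 0
        n_rep = 10
        for _ in range(n_rep):
            f = rng.uniform(0.005, 0.03, 150)
            rate = 0.03 * np.exp(120 * (f - 0.005))
            t = rng.exponential(1.0 / rate)
            df = surv_df(t, [1] * 150, prf=f)
            res = prf_three_group(df, "prf")
            if res.pairwise_p and min(res.pairwise_p, key=res.pairwise_p.get) == "Low_vs_High":
                wins += 1
        assert wins >= 8

    def test_pairwise_bonferroni_capped_at_one(self, rng):
        df = surv_df(rng.exponential(10, 90), [1] * 90,
                     prf=rng.uniform(0.005, 0.03, 90))
        res = prf_three_group(df, "prf")
        assert all(0 <= p <= 1 for p in res.pairwise_p.values())

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(EvaluationError):
            PrfThresholds(low_cut=0.02, high_cut=0.01)
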