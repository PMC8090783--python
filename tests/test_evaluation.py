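"""Metrics, stratified folds, nested C search, repeated CV and corrected tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import brainage as ba
from brainage.cohort import ParameterError
from brainage.evaluation import (
    compare_all,
    mae,
    nested_select_C,
    pearson_r,
    rmse,
)


class TestMetrics:
    def test_brainage_sign_convention(self):
        assert ba.brainage(np.array([65.0]), np.array([60.0]))[0] == 5.0
        assert ba.brainage(np.array([60.0]), np.array([60.0]))[0] == 0.0

    def test_mean_absolute_brainage_is_mae(self, rng):
        y = rng.uniform(47, 73, 50)
        pred = y + rng.normal(0, 3, 50)
        assert np.mean(np.abs(ba.brainage(pred, y))) == pytest.approx(mae(y, pred))

    def test_weighted_mae(self):
        assert ba.weighted_mae(0.0, 47, 73) == 0.0
        assert ba.weighted_mae(5.2, 47, 73) == pytest.approx(0.2)
        with pytest.raises(ParameterError):
            ba.weighted_mae(1.0, 73, 47)

    def test_prediction_r2_anchors(self, rng):
        y = rng.uniform(47, 73, 40)
        assert ba.prediction_r2(y, y) == 1.0
        assert ba.prediction_r2(y, np.full(40, y.mean())) == pytest.approx(0.0)
        bad = y.mean() + rng.normal(0, 2 * y.std(), 40)
        assert ba.prediction_r2(y, bad) < 0.0

    def test_rmse_at_least_mae(self, rng):
        y = rng.uniform(47, 73, 30)
        pred = y + rng.normal(0, 2, 30)
        assert rmse(y, pred) >= mae(y, pred)

    def test_age_bias_extremes(self):
        age = np.array([50.0, 55.0, 60.0, 65.0])
        gap = np.array([4.0, 2.0, 1.0, -3.0])  # strictly decreasing in age
        assert ba.age_bias(age, gap) == -1.0

    def test_age_bias_constant_predictions_not_available(self):
        age = np.array([50.0, 55.0, 60.0])
        assert np.isnan(ba.age_bias(age, np.zeros(3)))
        assert np.isnan(pearson_r(age, np.full(3, 61.0)))

    def test_age_bias_matches_rank_oracle(self, rng):
        # brute force: average ranks (ties included), then Pearson on the ranks
        age = rng.integers(47, 74, 60).astype(float)  # integer ages force ties
        gap = rng.normal(0, 3, 60)

        def avg_rank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(v.size)
            i = 0
            sv = v[order]
            while i < v.size:
                j = i
                while j + 1 < v.size and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return ranks

        expected = stats.pearsonr(avg_rank(age), avg_rank(gap))[0]
        assert ba.age_bias(age, gap) == pytest.approx(expected, abs=1e-12)


class TestStratifiedFolds:
    def test_uniform_cohort_perfectly_balanced(self):
        ages = np.repeat(np.arange(50, 60), 10)
        folds = ba.stratified_folds(ages, k=10, seed=0)
        for a in range(50, 60):
            per_fold = np.bincount(folds[ages == a], minlength=10)
            assert np.all(per_fold == 1)

    def test_partition_properties(self, rng):
        # every age has >= 7 members so no stratum merging occurs at k=5
        ages = np.concatenate([np.repeat(np.arange(47, 74), 7), rng.integers(47, 74, 28)])
        folds = ba.stratified_folds(ages, k=5, seed=3)
        assert folds.size == ages.size
        assert set(np.unique(folds)) == set(range(5))
        # every subject in exactly one fold is implied by the label vector;
        # per-age counts across folds differ by at most one
        for a in np.unique(ages):
            counts = np.bincount(folds[ages == a], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self, rng):
        ages = rng.integers(47, 74, 100)
        assert np.array_equal(
            ba.stratified_folds(ages, 5, seed=9), ba.stratified_folds(ages, 5, seed=9)
        )

    def test_more_balanced_than_random_assignment(self):
        wins = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            ages = g.choice(np.arange(47, 74), 300, p=np.linspace(1, 3, 27) / np.sum(np.linspace(1, 3, 27)))
            strat = ba.stratified_folds(ages, 5, seed=seed)
            rand = g.permutation(np.arange(300) % 5)

            def chi2(assign):
                tbl = pd.crosstab(ages, assign).to_numpy()
                return stats.chi2_contingency(tbl)[0]

            wins += chi2(strat) <= chi2(rand)
        assert wins >= 95

    def test_small_strata_merged(self):
        ages = np.array([47] * 2 + [48] * 30 + [73] * 30)  # age 47 has < k members
        folds = ba.stratified_folds(ages, k=5, seed=1)
        assert set(np.unique(folds)) == set(range(5))


class TestNestedSelectC:
    def test_single_value_grid(self, rng):
        x = rng.normal(size=(60, 3))
        y = x @ np.ones(3) + 60
        plan = ba.CVPlan(k=3, repetitions=1, nested_k=3, c_grid=(0.5,))
        ages = np.clip(np.round(y), 47, 73).astype(int)
        assert nested_select_C(x, y, ages, plan, seed=0) == 0.5

    def test_duplicate_entries_tie_to_smaller(self, rng):
        x = rng.normal(size=(60, 3))
        y = x @ np.ones(3) + 60
        ages = np.clip(np.round(y), 47, 73).astype(int)
        plan = ba.CVPlan(k=3, repetitions=1, nested_k=3, c_grid=(4.0, 4.0))
        assert nested_select_C(x, y, ages, plan, seed=0) == 4.0

    def test_underfitting_small_c_rejected(self, rng):
        age = rng.integers(47, 74, 120).astype(float)
        x = np.outer(age - 60, np.ones(4)) + rng.normal(0, 0.5, (120, 4))
        plan = ba.CVPlan(k=3, repetitions=1, nested_k=3, c_grid=(2.0**-7, 1.0))
        chosen = nested_select_C(x, age, age.astype(int), plan, seed=0)
        assert chosen > 2.0**-7

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            ba.CVPlan(c_grid=())


class TestCorrectedTTest:
    def test_identical_scores(self):
        s = np.array([3.0, 4.0, 5.0])
        assert ba.corrected_paired_ttest(s, s, 90, 10) == (0.0, 1.0)

    def test_reduces_to_classical_when_ratio_vanishes(self, rng):
        a = rng.normal(4, 0.5, 20)
        b = rng.normal(4.2, 0.5, 20)
        t_corr, p_corr = ba.corrected_paired_ttest(a, b, n_train=1e12, n_test=1)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t_corr == pytest.approx(t_ref, rel=1e-6)
        assert p_corr == pytest.approx(p_ref, rel=1e-6)

    def test_correction_shrinks_statistic(self, rng):
        a = rng.normal(4, 0.5, 20)
        b = a + rng.normal(0.2, 0.1, 20)
        t_corr, _ = ba.corrected_paired_ttest(a, b, n_train=90, n_test=10)
        t_ref, _ = stats.ttest_rel(a, b)
        assert abs(t_corr) < abs(t_ref)

    def test_mismatched_lengths(self):
        with pytest.raises(ParameterError):
            ba.corrected_paired_ttest(np.ones(3), np.ones(4), 9, 1)


class TestCompareAll:
    @staticmethod
    def _fake_scores(n_models=8, k=10, r=10, seed=0):
        g = np.random.default_rng(seed)
        rows = []
        for m in range(n_models):
            for rep in range(r):
                for f in range(k):
                    rows.append(
                        {
                            "model": f"m{m}",
                            "repetition": rep,
                            "fold": f,
                            "n_train": 900,
                            "n_test": 100,
                            "mae": 4.0 + 0.1 * m + g.normal(0, 0.2),
                        }
                    )
        return pd.DataFrame(rows)

    def test_antisymmetry(self):
        cm = compare_all(self._fake_scores(n_models=3))
        for a in cm.models:
            for b in cm.models:
                assert cm.t.loc[a, b] == pytest.approx(-cm.t.loc[b, a])
                assert cm.p.loc[a, b] == cm.p.loc[b, a]

    def test_pair_count_and_threshold(self):
        cm = compare_all(self._fake_scores(n_models=8))
        assert cm.n_pairs == 28
        assert cm.bonferroni_alpha == pytest.approx(0.05 / 28)

    def test_unpaired_design_rejected(self):
        scores = self._fake_scores(n_models=2)
        scores = scores.drop(scores[(scores["model"] == "m1") & (scores["fold"] == 0)].index[:1])
        with pytest.raises(ParameterError):
            compare_all(scores)


class TestRepeatedCV:
    def test_record_count_and_pairing(self, benchmark_results, cv_plan):
        scores = benchmark_results.scores
        for m in scores["model"].unique():
            assert len(scores[scores["model"] == m]) == cv_plan.n_scores
        # paired design: identical fold sizes per (repetition, fold) across models
        pivot = scores.pivot_table(
            index=["repetition", "fold"], columns="model", values="n_test"
        )
        assert pivot.nunique(axis=1).max() == 1

    def test_metric_identities_per_fold(self, benchmark_results):
        s = benchmark_results.scores
        assert (s["rmse"] >= s["mae"] - 1e-12).all()
        assert (s["mae"] >= 0).all()
        ok = s["pearson_r"].dropna()
        assert ok.between(-1, 1).all()

    def test_no_leakage_audit(self, benchmark_results):
        benchmark_results.check_no_leakage()

    def test_leakage_audit_detects_contamination(self, benchmark_results):
        import copy

        tampered = copy.deepcopy(benchmark_results.cv)
        entry = tampered.audit[0]
        key = next(iter(entry["fit_seen_ids"]))
        entry["fit_seen_ids"][key] = np.concatenate(
            [entry["fit_seen_ids"][key], entry["val_ids"][:1]]
        )
        with pytest.raises(AssertionError):
            ba.assert_no_leakage(tampered)

    def test_same_seed_reproduces_scores(self, two_site_cohorts, cv_plan):
        site1, _ = two_site_cohorts
        models = [ba.ModelSpec("rvr_region", "rvr", "region")]
        r1 = ba.run_repeated_cv({"region": site1["region"]}, models, cv_plan)
        r2 = ba.run_repeated_cv({"region": site1["region"]}, models, cv_plan)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)

    def test_null_cohort_scores_at_chance(self):
        # permutation null: shuffled ages leave nothing to learn, so the mean
        # MAE approaches the mean absolute deviation of the age distribution
        maes, mads = [], []
        for seed in range(6):
            spec = ba.CohortSpec(n_subjects=150, seed=seed)
            cohort = ba.generate_region_cohort(spec)
            g = np.random.default_rng(seed)
            shuffled = cohort.subjects.copy()
            shuffled["age"] = g.permutation(shuffled["age"].to_numpy())
            null = ba.Cohort(
                subjects=shuffled, features=cohort.features, feature_kind="region"
            )
            plan = ba.CVPlan(k=4, repetitions=1, seed=seed)
            res = ba.run_repeated_cv(
                {"region": null}, [ba.ModelSpec("rvr_region", "rvr", "region")], plan
            )
            maes.append(res.scores["mae"].mean())
            ages = null.ages.astype(float)
            mads.append(np.mean(np.abs(ages - ages.mean())))
        assert abs(np.mean(maes) - np.mean(mads)) < 1.0

    def test_global_pca_scope_runs_and_audit_flags_it(self, two_site_cohorts):
        # the cheaper fit-once PCA variant works, but its basis has seen the
        # validation rows, which the structural audit flags by design
        site1, _ = two_site_cohorts
        plan = ba.CVPlan(k=3, repetitions=1, seed=2)
        res = ba.run_repeated_cv(
            {"voxel": site1["voxel"]},
            [ba.ModelSpec("rvr_voxel_pca", "rvr", "voxel_pca")],
            plan,
            pca_config=ba.PCAConfig(n_components=20, batch_size=60, scope="global"),
        )
        assert len(res.scores) == 3
        with pytest.raises(AssertionError):
            ba.assert_no_leakage(res)

    def test_underfit_tracking_columns_present(self, benchmark_results):
        s = benchmark_results.scores
        rvr = s[s["model"].str.startswith("rvr")]
        assert rvr["n_relevance_vectors"].notna().all()
        svr = s[s["model"].str.startswith("svr")]
        assert svr["chosen_C"].notna().all()
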