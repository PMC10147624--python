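"""Save-all, fixed-capacity, prioritize operating points and CV wrappers."""

import numpy as np
import pytest
from scipy import stats

from histotriage import (CohortConfig, GeneSpec, generate_cohort,
                         cross_validated_strategy, fixed_capacity,
                         prevalence_dependence, prioritize, save_all,
                         site_aware_kfold)
from histotriage.strategies import (DegenerateCapacityError, StrategyResult,
                                    fold_summary)


def _random_instance(seed, max_n=30):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n + 1))
    labels = np.zeros(n, dtype=int)
    labels[:int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = rng.choice(np.linspace(0, 1, 7), size=n)  # with ties
    return scores, labels


class TestSaveAll:
    def test_worked_example_avoids_80_percent(self):
        scores = np.array([0.95, 0.85, 0.75, 0.65, 0.55, 0.45, 0.35, 0.25,
                           0.15, 0.05])
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        op = save_all(scores, labels, 0.95)  # required TP = ceil(1.9) = 2
        assert op.dl_negative_fraction == pytest.approx(0.80)
        assert op.sensitivity == 1.0
        assert op.feasible

    def test_perfect_separation(self):
        scores = np.r_[np.full(2, 0.9), np.full(8, 0.1)]
        labels = np.r_[np.ones(2, int), np.zeros(8, int)]
        op = save_all(scores, labels, 0.95)
        assert op.dl_negative_fraction == pytest.approx(0.80)

    def test_identical_scores_infeasible(self):
        op = save_all([0.5] * 10, [1, 1] + [0] * 8, 0.95)
        assert op.dl_negative_fraction == 0.0
        assert not op.feasible
        assert op.sensitivity == 1.0

    def test_constraint_always_satisfied(self):
        for seed in range(200):
            scores, labels = _random_instance(seed)
            op = save_all(scores, labels, 0.95)
            assert op.sensitivity >= 0.95 - 1e-9 or \
                op.tp == labels.sum()  # ceil rule may force all positives

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            save_all([0.1, 0.9], [0, 1], 0.0)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            save_all([0.1, 0.9], [1, 1])


class TestFixedCapacity:
    def test_worked_example(self):
        # 10 slides, 4 positives, 3 of them in the top 5 by score
        scores = np.array([0.95, 0.9, 0.85, 0.8, 0.75,
                           0.4, 0.3, 0.2, 0.1, 0.05])
        labels = np.array([1, 1, 0, 1, 0, 1, 0, 0, 0, 0])
        op = fixed_capacity(scores, labels, 0.5)
        assert op.sensitivity == pytest.approx(0.75)
        assert op.dl_positive_fraction == pytest.approx(0.5)

    def test_full_capacity_sensitivity_one(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert fixed_capacity(scores, labels, 1.0).sensitivity == 1.0

    def test_degenerate_capacity(self):
        with pytest.raises(DegenerateCapacityError):
            fixed_capacity([0.1, 0.9, 0.3], [0, 1, 0], 0.05)

    def test_monotone_in_capacity(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        sens = [fixed_capacity(scores, labels, c).sensitivity
                for c in (0.1, 0.3, 0.5, 0.7, 1.0)]
        assert all(b >= a for a, b in zip(sens, sens[1:]))

    def test_budget_never_exceeded_under_ties(self):
        scores = np.array([0.5] * 10)
        labels = np.array([1] * 3 + [0] * 7)
        ids = np.array([f"s{i}" for i in range(10)])
        op = fixed_capacity(scores, labels, 0.3, slide_ids=ids)
        assert op.tp + op.fp == 3

    def test_binormal_closed_form_recovery(self):
        # oracle: numeric integration of the binormal tail at the capacity
        # threshold (prevalence 0.35, AUC 0.79 -> mu = 1.1404)
        from scipy.optimize import brentq
        prev, auc, cap = 0.35, 0.79, 0.5
        mu = np.sqrt(2) * stats.norm.ppf(auc)
        c = brentq(lambda t: prev * stats.norm.sf(t - mu)
                   + (1 - prev) * stats.norm.sf(t) - cap, -5, 8)
        expected = stats.norm.sf(c - mu)
        cfg = CohortConfig(n_sites=10, slides_per_site=200,
                           genes=[GeneSpec("G", prev, auc)], seed=17)
        cohort = generate_cohort(cfg)
        op = fixed_capacity(cohort.scores("G"), cohort.labels("G"), cap)
        assert op.sensitivity == pytest.approx(expected, abs=0.05)
        assert op.sensitivity > cap  # informative score beats random gate


class TestPrioritize:
    def test_perfect_top_fraction(self):
        scores = np.linspace(1, 0, 20)
        labels = np.r_[np.ones(5, int), np.zeros(15, int)]  # prevalence 0.25
        res = prioritize(scores, labels, 0.10)  # top 2 slides, both mutated
        assert res.ppv == 1.0
        assert res.relative_risk == pytest.approx(4.0)

    def test_odds_ratio_cross_product(self):
        # top 2 of 20: 1 mutated; remaining 18: 4 mutated
        scores = np.linspace(1, 0, 20)
        labels = np.zeros(20, int)
        labels[[0, 3, 6, 9, 12]] = 1
        res = prioritize(scores, labels, 0.10)
        assert res.ppv == pytest.approx(0.5)
        assert res.odds_ratio == pytest.approx((1 * 14) / (1 * 4))
        assert not res.continuity_corrected

    def test_zero_cell_continuity_correction(self):
        scores = np.linspace(1, 0, 20)
        labels = np.r_[np.ones(2, int), np.zeros(18, int)]
        res = prioritize(scores, labels, 0.10)  # b = 0 and c = 0
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)

    def test_zero_prevalence_error(self):
        with pytest.raises(ValueError):
            prioritize([0.2, 0.8], [0, 0], 0.5)

    def test_rr_times_prevalence_is_ppv(self):
        for seed in range(100):
            scores, labels = _random_instance(seed)
            res = prioritize(scores, labels, 0.3)
            assert res.relative_risk * res.prevalence == pytest.approx(
                res.ppv, abs=1e-12)

    def test_uninformative_scores_ppv_near_prevalence(self):
        prev, reps = 0.3, 400
        rng = np.random.default_rng(5)
        ppvs = []
        for _ in range(reps):
            labels = (rng.random(100) < prev).astype(int)
            if labels.min() == labels.max() or labels.sum() == 0:
                continue
            ppvs.append(prioritize(rng.random(100), labels, 0.10).ppv)
        se = np.std(ppvs, ddof=1) / np.sqrt(len(ppvs))
        assert abs(np.mean(ppvs) - prev) < 3 * se + 0.005


class TestRankInvariance:
    @pytest.mark.parametrize("transform", [
        np.exp,
        lambda s: s ** 3,
        lambda s: 2 * s + 1,
        stats.logistic.cdf,
    ])
    def test_strategies_depend_only_on_ranks(self, transform):
        scores, labels = _random_instance(123, max_n=25)
        # break ties first: monotone maps preserve strict order only
        scores = scores + np.linspace(0, 1e-6, len(scores))
        t = transform(scores)
        a, b = save_all(scores, labels, 0.9), save_all(t, labels, 0.9)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)
        a, b = (fixed_capacity(s, labels, 0.4) for s in (scores, t))
        assert (a.tp, a.fp) == (b.tp, b.fp)
        a, b = (prioritize(s, labels, 0.2) for s in (scores, t))
        assert (a.ppv, a.odds_ratio) == (b.ppv, b.odds_ratio)


class TestCrossValidated:
    def test_fold_summary_worked_example(self):
        mean, sem = fold_summary([0.6, 0.62, 0.58, 0.61, 0.59])
        assert mean == pytest.approx(0.60)
        assert sem == pytest.approx(0.00707, abs=1e-5)

    def test_identical_folds_zero_dispersion(self):
        mean, sem = fold_summary([0.5, 0.5, 0.5])
        assert (mean, sem) == (0.5, 0.0)

    def test_cv_runs_on_precomputed_scores(self, scored_cohort):
        plan = site_aware_kfold(scored_cohort, "TP53", 5, seed=3)
        res = cross_validated_strategy(scored_cohort, "TP53",
                                       "fixed_capacity", 0.5, plan)
        assert len(res.fold_values) == 5
        assert res.mean == pytest.approx(np.mean(res.fold_values))
        expected_sem = np.std(res.fold_values, ddof=1) / np.sqrt(5)
        assert res.dispersion == pytest.approx(expected_sem)
        assert res.mean > 0.5  # informative scores beat the random gate

    def test_degenerate_fold_skipped_with_warning(self):
        cfg = CohortConfig(n_sites=5, slides_per_site=30,
                           genes=[GeneSpec("G", 0.3, 0.7)], seed=21)
        cohort = generate_cohort(cfg)
        # empty one site's positives so its fold lacks a class
        site0 = cohort.slides["site_id"] == "S00"
        cohort.slides.loc[site0, "label_G"] = 0
        plan = site_aware_kfold(cohort, "G", 5, seed=22)
        with pytest.warns(UserWarning, match="skipped"):
            res = cross_validated_strategy(cohort, "G", "fixed_capacity",
                                           0.5, plan)
        assert res.extras["n_folds_used"] == 4
        assert len(res.fold_values) == 4

    def test_unknown_strategy(self, scored_cohort):
        plan = site_aware_kfold(scored_cohort, "TP53", 5, seed=3)
        with pytest.raises(ValueError):
            cross_validated_strategy(scored_cohort, "TP53", "triage", 0.5,
                                     plan)


class TestPrevalenceDependence:
    @staticmethod
    def _results(means, ors=None):
        return [StrategyResult(gene=f"G{i}", strategy="prioritize",
                               parameter=0.1, fold_values=[m], mean=m,
                               dispersion=0.0,
                               extras={"odds_ratio": (ors or means)[i]})
                for i, m in enumerate(means)]

    @pytest.mark.parametrize("y, expected", [
        ([2, 4, 6], 1.0),
        ([6, 4, 2], -1.0),
        ([1, 3, 2], 0.5),
    ])
    def test_worked_examples(self, y, expected):
        r, p = prevalence_dependence(self._results(y), [1, 2, 3])
        assert r == pytest.approx(expected)
        assert 0 <= p <= 1

    def test_odds_ratio_channel(self):
        res = self._results([1, 2, 3], ors=[5, 5, 6])
        r, _ = prevalence_dependence(res, [1, 2, 3], use_odds_ratio=True)
        assert r == pytest.approx(stats.pearsonr([1, 2, 3], [5, 5, 6])[0])

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            prevalence_dependence(self._results([2, 2, 2]), [1, 2, 3])

    def test_needs_three_genes(self):
        with pytest.raises(ValueError):
            prevalence_dependence(self._results([1, 2]), [1, 2])
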