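"""Nested 5-fold test protocol, metrics, Friedman oracle, Fisher projection."""

import itertools

import numpy as np
import pytest

from mrcpdetect.evaluate import (METHODS, LdaDetector, confusion_metrics,
                                 evaluate_subject, fisher_projection,
                                 five_fold_test, friedman_compare, run_study)


class TestConfusionMetrics:
    def test_all_correct(self):
        r = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (r.error, r.sensitivity, r.specificity) == (0.0, 1.0, 1.0)

    def test_all_positive_predictions(self):
        r = confusion_metrics([1, 1, 1, 1], [1, 1, 0, 0])
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_hand_computed_counts(self):
        y = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        r = confusion_metrics(pred, y)
        assert (r.tp, r.fn, r.tn, r.fp) == (9, 1, 8, 2)
        assert r.error == pytest.approx(0.15)
        assert r.sensitivity == pytest.approx(0.9)
        assert r.specificity == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class SpyDetector:
    """Records which items each fit/predict call saw, for leakage checks."""

    def __init__(self):
        self.fit_items: list[set] = []
        self.predicted: list[set] = []

    def fit(self, items, labels):
        ids = set(np.asarray(items)[:, 0].astype(int))
        self.fit_items.append(ids)
        return ids

    def predict(self, model, items):
        self.predicted.append((frozenset(model),
                               set(np.asarray(items)[:, 0].astype(int))))
        return np.ones(len(items), dtype=int)


class TestFiveFoldTest:
    @staticmethod
    def clouds(n=100, gap=20.0, seed=0):
        r = np.random.default_rng(seed)
        X = np.vstack([r.standard_normal((n, 2)),
                       r.standard_normal((n, 2)) + gap])
        y = np.repeat([0, 1], n)
        return X, y

    def test_separable_clouds_perfect(self):
        X, y = self.clouds()
        res = five_fold_test(X, y, LdaDetector(), seed=1)
        assert res.mean_error == 0.0
        assert res.mean_sensitivity == 1.0 and res.mean_specificity == 1.0
        assert len(res.folds) == 5

    def test_stratified_part_sizes(self):
        X, y = self.clouds(n=100)
        res = five_fold_test(X, y, LdaDetector(), seed=1)
        for f in res.folds:
            assert f.tp + f.fn == 20 and f.tn + f.fp == 20

    def test_permuted_labels_at_chance(self):
        r = np.random.default_rng(5)
        X, _ = self.clouds(n=100)
        y = r.permutation(np.repeat([0, 1], 100))
        res = five_fold_test(X, y, LdaDetector(), seed=2)
        assert 0.4 <= res.mean_error <= 0.6

    def test_mean_equals_fold_mean_exactly(self):
        X, y = self.clouds(gap=2.0, seed=3)
        res = five_fold_test(X, y, LdaDetector(), seed=3)
        assert res.mean_error == np.mean([f.error for f in res.folds])

    def test_no_test_epoch_reaches_training_or_validation(self):
        # instrument with item identities: X[:, 0] is a unique id
        n = 100
        ids = np.arange(2 * n, dtype=float)
        X = np.column_stack([ids, np.zeros(2 * n)])
        y = np.repeat([0, 1], n)
        spy = SpyDetector()
        five_fold_test(X, y, spy, seed=7)
        # 5 rotations x 4 validation fits
        assert len(spy.fit_items) == 20
        fits = iter(spy.fit_items)
        preds = iter(spy.predicted)
        for rotation in range(5):
            val_sets = []
            for _ in range(4):
                train = next(fits)
                model, val = next(preds)
                assert model == train
                assert not (train & val)         # validation unseen in training
                val_sets.append(train | val)
            chosen_model, test = next(preds)
            rotation_pool = set().union(*val_sets)
            assert rotation_pool == val_sets[0]  # same 4 parts throughout
            assert not (test & rotation_pool)    # test never seen before
        assert next(preds, None) is None

    def test_too_few_epochs_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            five_fold_test(X, y, LdaDetector(), seed=0)


def friedman_exact_permutation_p(scores):
    """Exact permutation null: permute method labels within each subject."""
    scores = np.asarray(scores, float)
    n, k = scores.shape
    observed, _ = friedman_compare(scores)
    stats = []
    for perms in itertools.product(itertools.permutations(range(k)), repeat=n):
        table = np.vstack([scores[i, list(p)] for i, p in enumerate(perms)])
        s, _ = friedman_compare(table)
        stats.append(s)
    stats = np.asarray(stats)
    return np.mean(stats >= observed - 1e-12)


class TestFriedman:
    def test_identical_columns_all_ties(self):
        stat, p = friedman_compare(np.ones((5, 3)))
        assert stat == 0.0 and p == 1.0

    def test_two_methods_maximum_statistic(self):
        # method A strictly better for all 6 subjects: chi2 = 6, the maximum
        scores = np.column_stack([np.arange(6) + 1.0, np.arange(6) + 2.0])
        stat, _ = friedman_compare(scores)
        assert stat == pytest.approx(6.0)

    def test_hand_computed_rank_algebra_4x3(self):
        scores = np.array([[1.0, 2.0, 3.0],
                           [2.0, 1.0, 3.0],
                           [1.0, 2.0, 3.0],
                           [1.0, 3.0, 2.0]])
        # rank sums: (5, 8, 11); chi2 = 12/(4*3*4) * sum((Rj-8)^2) = 4.5
        stat, _ = friedman_compare(scores)
        assert stat == pytest.approx(4.5)

    def test_p_close_to_exact_enumeration(self):
        scores = np.array([[1.0, 3.0, 2.0],
                           [2.0, 5.0, 4.0],
                           [1.0, 2.0, 6.0],
                           [3.0, 5.0, 4.0]])
        _, p_chi2 = friedman_compare(scores)
        p_exact = friedman_exact_permutation_p(scores)
        assert p_chi2 == pytest.approx(p_exact, abs=0.02)

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import friedmanchisquare
        scores = rng.standard_normal((10, 4))
        stat, p = friedman_compare(scores)
        ref = friedmanchisquare(*scores.T)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_monotone_invariance(self, rng):
        scores = rng.uniform(0, 1, (8, 3))
        s1, p1 = friedman_compare(scores)
        s2, p2 = friedman_compare(np.exp(5 * scores))  # monotone transform
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_missing_cells_rejected(self):
        scores = np.ones((4, 3))
        scores[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_compare(scores)


class TestFisherProjection:
    def test_separated_clusters_stay_separated(self, rng):
        centers = np.array([[0, 0, 0], [50, 0, 0], [0, 50, 0]], float)
        X = np.vstack([rng.standard_normal((100, 3)) + c for c in centers])
        labels = np.repeat(["f60", "s20", "noise"], 100)
        Z = fisher_projection(X, labels)
        means = {c: Z[labels == c].mean(axis=0) for c in set(labels)}
        spread = max(Z[labels == c].std(axis=0).max() for c in set(labels))
        for a, b in itertools.combinations(means, 2):
            assert np.linalg.norm(means[a] - means[b]) > 5 * spread

    def test_output_range_exactly_unit(self, rng):
        X = rng.standard_normal((90, 4))
        labels = np.repeat([0, 1, 2], 30)
        Z = fisher_projection(X, labels)
        np.testing.assert_allclose(Z.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(Z.max(axis=0), 1.0, atol=1e-12)

    def test_shuffled_labels_still_defined(self, rng):
        X = rng.standard_normal((90, 4))
        labels = rng.permutation(np.repeat([0, 1, 2], 30))
        Z = fisher_projection(X, labels)
        assert Z.shape == (90, 2) and np.all(np.isfinite(Z))

    def test_out_dim_limited_by_classes(self, rng):
        X = rng.standard_normal((40, 4))
        with pytest.raises(ValueError):
            fisher_projection(X, np.repeat([0, 1], 20), out_dim=2)


class TestStudy:
    def test_subject_records_shape(self, real_recording):
        records = evaluate_subject(real_recording, seed=0)
        assert len(records) == 2 * len(METHODS)      # two tasks, three methods
        for r in records:
            assert 0.0 <= r["error"] <= 1.0
            assert len(r["folds"]) == 5
            assert r["error"] == pytest.approx(
                np.mean([f["error"] for f in r["folds"]]))

    def test_run_study_aggregation(self, small_cfg):
        from mrcpdetect import generate_recording
        recs = [generate_recording(small_cfg.replace(seed=s), "real", f"S{s}")
                for s in (1, 2, 3)]
        report = run_study(recs, seed=0)
        agg = report.aggregate["real"]
        for metric in ("error", "sensitivity", "specificity"):
            for m in METHODS:
                assert np.isfinite(agg[metric][m]["mean"])
        # SE = sd/sqrt(n) over subjects, recomputed independently
        per_subj = {}
        for r in report.per_subject:
            if r["method"] == "lda_spectral":
                per_subj.setdefault(r["subject"], []).append(r["error"])
        scores = np.array([np.mean(v) for v in per_subj.values()])
        assert agg["error"]["lda_spectral"]["se"] == pytest.approx(
            scores.std(ddof=1) / np.sqrt(len(scores)))
        assert "temporal_vs_spectral" in report.friedman["real"]
        assert "best_vs_template" in report.friedman["real"]

    def test_imaginary_group_runs_with_imagery_features(self,
                                                       imaginary_recording):
        records = evaluate_subject(imaginary_recording, seed=4)
        # cue-aligned epochs still contain the MRCP: far better than chance
        errs = [r["error"] for r in records if r["method"] == "lda_temporal"]
        assert np.mean(errs) < 0.25

    def test_template_degraded_by_onset_jitter(self, real_recording):
        clean = evaluate_subject(real_recording, seed=6, methods=("template",))
        jittered = evaluate_subject(real_recording, seed=6,
                                    methods=("template",),
                                    template_onset_jitter_sd=0.4)
        assert np.mean([r["error"] for r in jittered]) > \
            np.mean([r["error"] for r in clean])
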