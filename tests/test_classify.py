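"""Metrics, Youden threshold, downsampling and differential regions."""

import numpy as np
import pandas as pd
import pytest

from cfrefrag.classify import (
    ConfusionCounts,
    classification_metrics,
    confusion_at_threshold,
    differential_regions,
    downsample,
    feature_table,
    assemble_matrix,
    youden_threshold,
)
from cfrefrag.fragments import Fragment


def youden_oracle(scores, labels):
    """Exhaustive sweep over all candidate cuts."""
    best_t, best_j = min(scores), -1e9
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t


class TestMetrics:
    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(TP=9, TN=8, FP=2, FN=1))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_missing_denominator(self):
        m = classification_metrics(ConfusionCounts(TP=0, TN=7, FP=0, FN=0))
        assert m["sensitivity"] is None
        assert m["specificity"] == 1.0

    def test_identities_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 40, 4))
            cc = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
            m = classification_metrics(cc)
            if m["ppv"] is not None:
                assert m["ppv"] * (tp + fp) == pytest.approx(tp)
            if m["accuracy"] is not None:
                assert m["accuracy"] * cc.total == pytest.approx(tp + tn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


class TestYouden:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t = youden_threshold(scores, labels)
        assert t == 0.8
        cc = confusion_at_threshold(scores, labels, t)
        m = classification_metrics(cc)
        assert m["sensitivity"] + m["specificity"] - 1 == pytest.approx(1.0)

    def test_all_equal_scores(self):
        t = youden_threshold([0.5] * 6, [0, 1] * 3)
        cc = confusion_at_threshold([0.5] * 6, [0, 1] * 3, t)
        m = classification_metrics(cc)
        assert m["sensitivity"] + m["specificity"] - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 3).tolist()
            labels = rng.integers(0, 2, n).tolist()
            if len(set(labels)) < 2:
                continue
            assert youden_threshold(scores, labels) == youden_oracle(scores, labels)


class TestDownsample:
    @staticmethod
    def _frags(n):
        return [Fragment("chr1", i * 10, i * 10 + 100, name=f"f{i}") for i in range(n)]

    def test_identity_at_full_fraction(self):
        frags = self._frags(50)
        assert downsample(frags, 1.0, seed=1) == frags

    def test_seed_reproducibility(self):
        frags = self._frags(500)
        assert downsample(frags, 0.3, seed=7) == downsample(frags, 0.3, seed=7)

    def test_kept_count_within_binomial_bounds(self):
        frags = self._frags(10_000)
        kept = len(downsample(frags, 0.5, seed=11))
        assert abs(kept - 5000) <= 3 * np.sqrt(10_000 * 0.25)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            downsample(self._frags(5), fraction)


class TestAssembleMatrix:
    def test_standardization_contract(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(rng.normal(5, 2, size=(20, 3)),
                             index=[f"S{i}" for i in range(20)],
                             columns=["Alu:FR", "Alu:FD", "FE"])
        feats.iloc[0, 1] = np.nan
        labels = {f"S{i}": ("cancer" if i % 2 else "healthy") for i in range(20)}
        X, y = assemble_matrix(feats, labels)
        assert not X.isna().any().any()
        assert np.allclose(X.mean(), 0.0, atol=1e-9)
        assert np.allclose(X.std(ddof=0), 1.0, atol=1e-9)
        assert y.sum() == 10

    def test_missing_sample_raises(self):
        feats = pd.DataFrame([[1.0]], index=["S0"], columns=["FE"])
        with pytest.raises(KeyError):
            assemble_matrix(feats, {})

    def test_identical_samples_identical_rows(self, cohort_features):
        import dataclasses

        first = next(iter(cohort_features.sample_features.values()))
        twin = dataclasses.replace(first, sample_id="twin")
        fe = dict(cohort_features.fe_scores)
        fe["twin"] = fe[first.sample_id]
        tab = feature_table([first, twin], fe)
        assert tab.loc[first.sample_id].equals(tab.loc["twin"])


class TestEnsemble:
    def test_all_algorithms_separate_planted_cohort(self, cohort_features):
        from cfrefrag.classify import ALGORITHMS, train_ensemble

        best, aucs = train_ensemble(cohort_features.X, cohort_features.y,
                                    folds=5, seed=1)
        assert set(aucs) == set(ALGORITHMS)
        assert "random-forest" in aucs
        assert all(a > 0.8 for a in aucs.values())  # far above any null
        assert best.auc == max(aucs.values())

    def test_winner_is_order_independent(self, cohort_features):
        from cfrefrag.classify import train_ensemble

        subset = ("naive-bayes", "lda", "knn")
        a, _ = train_ensemble(cohort_features.X, cohort_features.y,
                              algorithms=subset, folds=5, seed=1)
        b, _ = train_ensemble(cohort_features.X, cohort_features.y,
                              algorithms=tuple(reversed(subset)), folds=5, seed=1)
        assert a.algorithm == b.algorithm


class TestDifferentialRegions:
    def test_identical_cohorts_unflagged(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(8, size=(30, 40)),
                              columns=[f"S{i}" for i in range(40)])
        out = differential_regions(counts, [f"S{i}" for i in range(20)],
                                   [f"S{i}" for i in range(20, 40)])
        assert not out["flagged"].any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(8.0, size=(30, 40)).astype(float),
                              columns=[f"S{i}" for i in range(40)])
        healthy = [f"S{i}" for i in range(20)]
        cases = [f"S{i}" for i in range(20, 40)]
        sd = counts.loc[0, healthy].std(ddof=1)
        counts.loc[0, cases] += 3 * sd
        out = differential_regions(counts, healthy, cases)
        assert bool(out.loc[0, "flagged"])

    def test_flagged_set_shrinks_with_alpha(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.poisson(6.0, size=(50, 30)).astype(float),
                              columns=[f"S{i}" for i in range(30)])
        healthy = [f"S{i}" for i in range(15)]
        cases = [f"S{i}" for i in range(15, 30)]
        counts.loc[:9, cases] *= 2.5
        loose = differential_regions(counts, healthy, cases, alpha=0.05)
        strict = differential_regions(counts, healthy, cases, alpha=0.005)
        assert strict["flagged"].sum() <= loose["flagged"].sum()
        flagged_strict = set(strict.index[strict["flagged"]])
        flagged_loose = set(loose.index[loose["flagged"]])
        assert flagged_strict <= flagged_loose

    def test_too_few_healthy_rejected(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            differential_regions(counts, ["a", "b"], ["c", "d"])
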