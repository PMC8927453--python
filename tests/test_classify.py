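"""LOOCV classification, the eight-metric suite, and contribution analysis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (adjusted_rand_score, fowlkes_mallows_score,
                             matthews_corrcoef)

from burnmech.classify import (ConfusionMatrix, combine_rates,
                               compute_metrics, feature_contributions,
                               loocv_classify, roc_auc)
from burnmech.errors import InvalidTaskError, SchemaError


def _labels_from_confusion(tp, fp, fn, tn):
    """Reconstruct (y_true, y_pred) vectors realizing the given counts."""
    y_true = np.array([True] * (tp + fn) + [False] * (fp + tn))
    y_pred = np.array([True] * tp + [False] * fn + [True] * fp + [False] * tn)
    return y_true, y_pred


def _brute_force_ari(y_true, y_pred):
    """Pair-counting adjusted Rand index by explicit enumeration."""
    n = len(y_true)
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = y_true[i] == y_true[j]
            same_p = y_pred[i] == y_pred[j]
            if same_t and same_p:
                a += 1
            elif same_t:
                b += 1
            elif same_p:
                c += 1
            else:
                d += 1
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    max_index = ((a + b) + (a + c)) / 2
    if max_index == expected:
        return 1.0
    return (a - expected) / (max_index - expected)


def _brute_force_auc(probs, y_true):
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    pos = probs[y_true]
    neg = probs[~y_true]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_hand_computed_example(self):
        cm = ConfusionMatrix(tp=95, fp=2, fn=2, tn=36)
        metrics, notes = compute_metrics(cm)
        assert metrics["accuracy"] == pytest.approx(131 / 135)
        assert metrics["sensitivity"] == pytest.approx(95 / 97)
        assert metrics["specificity"] == pytest.approx(36 / 38)
        assert metrics["f1"] == pytest.approx(190 / 194)
        # independent route: the same counts as explicit label vectors
        y_true, y_pred = _labels_from_confusion(95, 2, 2, 36)
        assert metrics["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert metrics["fmi"] == pytest.approx(fowlkes_mallows_score(y_true, y_pred))
        assert metrics["ari"] == pytest.approx(adjusted_rand_score(y_true, y_pred))

    def test_perfect_classification(self):
        metrics, _ = compute_metrics(ConfusionMatrix(50, 0, 0, 30),
                                     np.r_[np.ones(50), np.zeros(30)],
                                     np.r_[np.ones(50), np.zeros(30)].astype(bool))
        for name, value in metrics.items():
            assert value == pytest.approx(1.0), name

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            m1, _ = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
            m2, _ = compute_metrics(ConfusionMatrix(tn, fn, fp, tp))
            assert m1["sensitivity"] == pytest.approx(m2["specificity"])
            assert m1["specificity"] == pytest.approx(m2["sensitivity"])
            assert m1["accuracy"] == pytest.approx(m2["accuracy"])
            assert m1["mcc"] == pytest.approx(m2["mcc"])
            assert m1["ari"] == pytest.approx(m2["ari"])

    def test_ari_against_brute_force_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 12, size=4))
            if tp + fp + fn + tn < 2:
                continue
            metrics, _ = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
            y_true, y_pred = _labels_from_confusion(tp, fp, fn, tn)
            assert metrics["ari"] == pytest.approx(
                _brute_force_ari(y_true, y_pred)), (tp, fp, fn, tn)

    def test_auc_against_all_pairs_count(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y = rng.random(30) < 0.5
            if y.all() or not y.any():
                continue
            probs = np.round(rng.random(30), 1)  # duplicates force tie handling
            assert roc_auc(probs, y) == pytest.approx(_brute_force_auc(probs, y))

    def test_zero_denominator_reported_as_nan(self):
        metrics, notes = compute_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert np.isnan(metrics["sensitivity"])
        assert any("sensitivity" in n for n in notes)


class TestLoocv:
    def _clouds(self, rng, n=40, sep=5.0):
        X = np.vstack([rng.normal(0, 1, (n, 5)) + sep,
                       rng.normal(0, 1, (n, 5)) - sep])
        y = np.array(["human"] * n + ["porcine"] * n)
        return X, y

    def test_perfectly_separable_clouds(self, rng):
        X, y = self._clouds(rng)
        rep = loocv_classify(X, y, task_label="separable")
        for name, value in rep.metrics().items():
            assert value == pytest.approx(1.0), name
        assert rep.confusion.tp == 40 and rep.confusion.tn == 40

    def test_permuted_labels_fall_to_chance(self, rng):
        X, y = self._clouds(rng)
        y_perm = y[rng.permutation(y.size)]
        rep = loocv_classify(X, y_perm)
        majority = 0.5
        se = np.sqrt(majority * (1 - majority) / y.size)
        assert abs(rep.accuracy - majority) <= 3 * se

    def test_deterministic(self, rng):
        X, y = self._clouds(rng, sep=0.8)
        r1 = loocv_classify(X, y)
        r2 = loocv_classify(X, y)
        assert r1.metrics() == r2.metrics()
        np.testing.assert_array_equal(r1.oof_probabilities, r2.oof_probabilities)
        assert r1.contributions == r2.contributions

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(InvalidTaskError):
            loocv_classify(X, np.array(["human"] * 20))

    def test_non_finite_features_rejected(self, rng):
        X, y = self._clouds(rng)
        X[3, 2] = np.nan
        with pytest.raises(InvalidTaskError):
            loocv_classify(X, y)


class TestContributions:
    def test_single_informative_feature_dominates(self, rng):
        n = 100
        X = rng.normal(0, 1, (2 * n, 5))
        y = np.array([True] * n + [False] * n)
        X[:n, 2] += 4.0  # feature 2 carries all the signal
        shares = feature_contributions(X, y)
        assert shares["feature_2"] > 0.8

    def test_shares_sum_to_one(self, rng):
        X, y = rng.normal(size=(60, 5)), rng.random(60) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        shares = feature_contributions(X, y)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mu_most_discriminative_on_default_study(self, default_study):
        """mu, given the largest between-class separation, earns the top share."""
        from burnmech.pipeline import FEATURE_COLUMNS
        kept = default_study["kept"]
        shares = feature_contributions(kept[list(FEATURE_COLUMNS)],
                                       kept["tissue"].to_numpy())
        assert max(shares, key=shares.get) == "mu_MPa"


class TestCombineRates:
    def _table(self, n, rate):
        return pd.DataFrame({"ut_stress_MPa": np.ones(n), "rate_mm_s": rate})

    def test_row_concatenation(self):
        combined = combine_rates([self._table(133, 0.3), self._table(131, 2.0),
                                  self._table(140, 8.0)])
        assert len(combined) == 404

    def test_self_combination_doubles(self):
        t = self._table(10, 0.3)
        assert len(combine_rates([t, t])) == 20

    def test_column_order_preserved_and_mismatch_rejected(self):
        t = self._table(5, 0.3)
        assert list(combine_rates([t, t]).columns) == list(t.columns)
        with pytest.raises(SchemaError):
            combine_rates([t, t[list(t.columns)[::-1]]])
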