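"""Metric formulas versus brute-force oracles and hand-computed examples."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support, r2_score

from vitalradar import classification_metrics, r2_star, regression_metrics


# ---- brute-force oracles (independent loop implementations) -----------------

def brute_rmse(y, p):
    return float(np.sqrt(sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)))


def brute_mae(y, p):
    return float(sum(abs(a - b) for a, b in zip(y, p)) / len(y))


def brute_r2(y, p):
    m = sum(y) / len(y)
    sse = sum((a - b) ** 2 for a, b in zip(y, p))
    sst = sum((a - m) ** 2 for a in y)
    return 1.0 - sse / sst


def brute_r2_star(y, p):
    return 1.0 - sum((a - b) ** 2 for a, b in zip(y, p)) / sum(a * a for a in y)


def brute_confusion(y, p, k):
    cm = [[0] * k for _ in range(k)]
    for a, b in zip(y, p):
        cm[a][b] += 1
    return np.array(cm)


class TestRegressionMetricsAgainstOracles:
    def test_thousand_random_instances_to_1e12(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            y = rng.normal(size=(n, 2))
            p = y + rng.normal(scale=0.5, size=(n, 2))
            got = regression_metrics(y, p)
            for j, name in enumerate(("fc", "fr")):
                assert got[f"rmse_{name}"] == pytest.approx(
                    brute_rmse(y[:, j], p[:, j]), abs=1e-12)
                assert got[f"mae_{name}"] == pytest.approx(
                    brute_mae(y[:, j], p[:, j]), abs=1e-12)
                assert got[f"r2_{name}"] == pytest.approx(
                    brute_r2(y[:, j], p[:, j]), abs=1e-12)
                assert r2_star(y[:, j], p[:, j]) == pytest.approx(
                    brute_r2_star(y[:, j], p[:, j]), abs=1e-12)

    def test_matches_sklearn_r2(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(50, 2))
        p = y + rng.normal(scale=0.3, size=(50, 2))
        got = regression_metrics(y, p)
        assert got["r2_fc"] == pytest.approx(r2_score(y[:, 0], p[:, 0]), abs=1e-12)
        assert got["r2_fr"] == pytest.approx(r2_score(y[:, 1], p[:, 1]), abs=1e-12)

    def test_perfect_prediction(self):
        y = np.array([[1.0, 0.2], [1.5, 0.3]])
        got = regression_metrics(y, y.copy())
        assert got["rmse_fc"] == 0 and got["mae_fr"] == 0
        assert got["r2_fc"] == 1.0 and got["r2_fr"] == 1.0

    def test_hand_example_constant_predictor(self):
        # y=[1,2,3], p=[2,2,2]: RMSE=sqrt(2/3), MAE=2/3, R2=0 (SSE=SST=2)
        y = np.column_stack([[1, 2, 3], [1, 2, 3]]).astype(float)
        p = np.full((3, 2), 2.0)
        got = regression_metrics(y, p)
        assert got["rmse_fc"] == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert got["mae_fc"] == pytest.approx(2 / 3, abs=1e-12)
        assert got["r2_fc"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift(self):
        y = np.random.default_rng(2).normal(size=(20, 2))
        got = regression_metrics(y, y + 0.37)
        for name in ("fc", "fr"):
            assert got[f"rmse_{name}"] == pytest.approx(0.37, abs=1e-12)
            assert got[f"mae_{name}"] == pytest.approx(0.37, abs=1e-12)

    def test_zero_variance_truth_flagged(self):
        y = np.ones((5, 2))
        got = regression_metrics(y, y + 0.1)
        assert np.isnan(got["r2_fc"])


class TestR2Star:
    def test_perfect_is_one(self):
        y = np.array([0.9, 1.1, 1.3])
        assert r2_star(y, y) == 1.0

    def test_hand_example(self):
        assert r2_star([2.0, 2.0], [1.0, 1.0]) == pytest.approx(0.75, abs=1e-15)

    def test_zero_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_star(y, np.zeros(3)) == pytest.approx(0.0, abs=1e-15)

    def test_zero_energy_truth_rejected(self):
        with pytest.raises(ValueError):
            r2_star(np.zeros(4), np.ones(4))

    def test_constant_true_block_stays_defined(self):
        # the motivating case: one (Fc, Fr) shared by a block of records
        y = np.full(100, 1.2)
        p = y + np.random.default_rng(0).normal(scale=0.05, size=100)
        v = r2_star(y, p)
        assert 0.9 < v < 1.0


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = classification_metrics(y, y)
        assert rep.values["accuracy"] == 1.0
        assert rep.values["precision"] == 1.0
        assert rep.values["recall"] == 1.0
        assert rep.values["f1"] == 1.0
        assert np.array_equal(np.diag(rep.confusion), [2, 2, 2])
        assert rep.confusion.sum() == 6

    def test_hand_computed_contingency(self):
        # positive class: TP=40, FP=10, FN=20, TN=30
        y = np.array([1] * 60 + [0] * 40)
        p = np.array([1] * 40 + [0] * 20 + [1] * 10 + [0] * 30)
        rep = classification_metrics(y, p, n_classes=2, class_names=("neg", "pos"))
        row = rep.per_class.loc["pos"]
        assert row["precision"] == pytest.approx(0.8, abs=1e-12)
        assert row["recall"] == pytest.approx(2 / 3, abs=1e-12)
        assert row["f1"] == pytest.approx(8 / 11, abs=1e-12)
        assert rep.values["accuracy"] == pytest.approx(0.7, abs=1e-12)

    def test_thousand_random_instances_against_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 3, size=n)
            p = rng.integers(0, 3, size=n)
            if len(np.unique(y)) < 3 or len(np.unique(p)) < 3:
                continue  # keep macro averages non-degenerate
            rep = classification_metrics(y, p)
            cm = brute_confusion(y, p, 3)
            assert np.array_equal(rep.confusion, cm)
            assert rep.values["accuracy"] == pytest.approx(
                np.trace(cm) / n, abs=1e-12)
            pr, rc, f1, _ = precision_recall_fscore_support(
                y, p, average="macro", zero_division=np.nan)
            assert rep.values["precision"] == pytest.approx(pr, abs=1e-12)
            assert rep.values["recall"] == pytest.approx(rc, abs=1e-12)
            assert rep.values["f1"] == pytest.approx(f1, abs=1e-12)

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, size=200)
        p = rng.integers(0, 3, size=200)
        base = classification_metrics(y, p).values
        perm = np.array([2, 0, 1])
        permuted = classification_metrics(perm[y], perm[p]).values
        for k in ("accuracy", "precision", "recall", "f1"):
            assert base[k] == pytest.approx(permuted[k], abs=1e-12)

    def test_uniform_random_accuracy_near_chance(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1, 2], 1000)
        p = rng.integers(0, 3, size=3000)
        rep = classification_metrics(y, p)
        assert rep.values["accuracy"] == pytest.approx(1 / 3, abs=0.03)

    def test_absent_class_recall_flagged_not_averaged(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0, 1, 1, 2])
        rep = classification_metrics(y, p)
        assert np.isnan(rep.per_class.loc["stress", "recall"])
        assert np.isfinite(rep.values["recall"])


# ---- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st

finite_floats = st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, allow_infinity=False)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(finite_floats, finite_floats), min_size=2,
                max_size=30))
def test_r2_star_matches_its_defining_formula(pairs):
    y = np.array([a for a, _ in pairs])
    p = np.array([b for _, b in pairs])
    if np.sum(y**2) == 0:
        with pytest.raises(ValueError):
            r2_star(y, p)
        return
    expected = 1.0 - np.sum((y - p) ** 2) / np.sum(y**2)
    assert r2_star(y, p) == pytest.approx(expected, rel=1e-9, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 2), min_size=3, max_size=60),
       st.permutations([0, 1, 2]))
def test_macro_metrics_invariant_under_any_relabeling(labels, perm):
    y = np.array(labels)
    p = np.roll(y, 1)  # a deterministic imperfect predictor
    perm = np.array(perm)
    a = classification_metrics(y, p).values
    b = classification_metrics(perm[y], perm[p]).values
    for key in ("accuracy", "precision", "recall", "f1"):
        if np.isnan(a[key]) or np.isnan(b[key]):
            assert np.isnan(a[key]) == np.isnan(b[key])
        else:
            assert a[key] == pytest.approx(b[key], abs=1e-12)
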