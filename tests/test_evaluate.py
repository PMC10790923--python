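import json
import math

import numpy as np
import pytest

from nirspain.datasets import LabelledDataset
from nirspain.evaluate import (
    EvalConfig,
    EvalError,
    binary_metrics,
    chance_threshold,
    nested_cv,
    outer_split,
)


class TestOuterSplit:
    def test_60_40_split_of_20_participants(self):
        groups = np.repeat([f"P{i}" for i in range(20)], 3)
        train, test = outer_split(groups, 0.6, seed=0)
        assert len(train) == 12 and len(test) == 8

    def test_deterministic_and_disjoint(self):
        groups = np.repeat([f"P{i}" for i in range(10)], 5)
        a = outer_split(groups, 0.6, seed=7)
        b = outer_split(groups, 0.6, seed=7)
        assert a == b
        assert a[0] & a[1] == set()
        assert a[0] | a[1] == set(groups)

    def test_too_few_participants(self):
        with pytest.raises(EvalError, match="5 participants"):
            outer_split(np.array(["A", "B", "C"]), 0.6, 0)


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        acc, f1, tpr, tnr, auc = binary_metrics(y, y, scores=y.astype(float))
        assert (acc, f1, tpr, tnr, auc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        acc, f1, tpr, tnr, _ = binary_metrics(y_true, y_pred)
        assert acc == pytest.approx(0.8)
        assert f1 == pytest.approx(0.75)
        assert tpr == pytest.approx(0.75)
        assert tnr == pytest.approx(5 / 6, abs=1e-4)

    def test_single_class_truth_warns(self):
        with pytest.warns(UserWarning, match="single-class"):
            _, _, tpr, tnr, auc = binary_metrics(np.zeros(4, int), np.zeros(4, int))
        assert np.isnan(tpr) and np.isnan(tnr) and np.isnan(auc)

    def test_accuracy_between_rates_when_balanced(self, rng):
        y_true = np.array([0, 1] * 20)
        y_pred = rng.integers(0, 2, 40)
        acc, _, tpr, tnr, _ = binary_metrics(y_true, y_pred)
        assert min(tpr, tnr) - 1e-12 <= acc <= max(tpr, tnr) + 1e-12


def exact_binomial_threshold(n, alpha_num=1, alpha_den=20):
    """Integer-arithmetic oracle: smallest k with CDF(k; n, 1/2) >= 1 - alpha.

    Works entirely in exact integers (alpha = alpha_num / alpha_den), so it is
    immune to the floating-point rounding of any library CDF.
    """
    total = 2**n
    acc = 0
    c = 1  # C(n, 0)
    for k in range(n + 1):
        acc += c
        if acc * alpha_den >= (alpha_den - alpha_num) * total:
            return k / n
        c = c * (n - k) // (k + 1)
    return 1.0


class TestChanceThreshold:
    def test_printed_values(self):
        assert round(chance_threshold(400), 2) == 0.54
        assert chance_threshold(160) == 0.5625

    def test_asymptote(self):
        assert abs(chance_threshold(10**6) - 0.5) < 1e-3

    @pytest.mark.parametrize("n", [1, 7, 23, 160, 400, 1111, 5000, 10_000])
    def test_matches_exact_summation_oracle(self, n):
        assert chance_threshold(n) == exact_binomial_threshold(n)

    def test_monotone_toward_half(self):
        ns = [20, 50, 100, 400, 1600]
        thr = [chance_threshold(n) for n in ns]
        assert all(a >= b - 1e-12 for a, b in zip(thr, thr[1:]))

    def test_invalid_alpha(self):
        with pytest.raises(EvalError):
            chance_threshold(100, alpha=1.5)


def make_dataset(rng, n_participants=8, rows_per=24, n_features=6, effect=1.0,
                 task="demand"):
    X, y, groups = [], [], []
    for p in range(n_participants):
        lab = p % 2  # participant-level labels keep the grouping honest
        X.append(rng.normal(0, 1, (rows_per, n_features))
                 + effect * lab * np.eye(n_features)[0])
        y += [lab] * rows_per
        groups += [f"P{p:02d}"] * rows_per
    return LabelledDataset(
        X=np.vstack(X), y=np.array(y), groups=np.array(groups),
        feature_names=[f"f{i}" for i in range(n_features)],
        task=task, stream="hr", balance_report={},
    )


SMALL_CFG = dict(
    n_repeats=2, inner_folds=3, rf_trees=50,
    grids={"SVM": {"C": [1.0], "gamma": [0.1]}, "kNN": {"n_neighbors": [3]},
           "RF": {"max_features": ["sqrt"]}, "NB": {}},
)


class TestNestedCv:
    def test_metrics_well_formed_and_deterministic(self, rng):
        ds = make_dataset(rng)
        cfg = EvalConfig(algorithms=("SVM", "NB"), seed=5, **SMALL_CFG)
        rep1 = nested_cv(ds, cfg)
        rep2 = nested_cv(ds, cfg)
        metrics = rep1.per_repeat[["accuracy", "f1", "tpr", "tnr", "auc"]].to_numpy()
        assert np.all((metrics >= 0) & (metrics <= 1))
        assert rep1.per_repeat.equals(rep2.per_repeat)

    def test_nb_skips_tuning(self, rng):
        ds = make_dataset(rng)
        cfg = EvalConfig(algorithms=("NB",), seed=0, **SMALL_CFG)
        rep = nested_cv(ds, cfg)
        assert all(json.loads(p) == {"tuned": False} for p in rep.per_repeat["params"])

    def test_strong_effect_beats_chance(self, rng):
        ds = make_dataset(rng, effect=3.0)
        cfg = EvalConfig(algorithms=("SVM",), seed=1, **SMALL_CFG)
        rep = nested_cv(ds, cfg)
        assert rep.per_repeat["accuracy"].mean() > rep.chance_thresholds["realised_mean"]

    def test_aggregate_matches_recomputation(self, rng):
        ds = make_dataset(rng)
        cfg = EvalConfig(algorithms=("SVM", "NB"), seed=2, **SMALL_CFG)
        rep = nested_cv(ds, cfg)
        agg = rep.aggregate()
        manual = rep.per_repeat[rep.per_repeat["algorithm"] == "SVM"]["accuracy"]
        assert agg[("mean", "accuracy")]["SVM"] == pytest.approx(manual.mean())
        assert agg[("sd", "accuracy")]["SVM"] == pytest.approx(manual.std(ddof=1))

    def test_config_validation(self):
        with pytest.raises(EvalError):
            EvalConfig(train_fraction=1.5)
        with pytest.raises(EvalError):
            EvalConfig(inner_folds=1)
        with pytest.raises(EvalError):
            EvalConfig(algorithms=("SVM", "MLP"))


def test_math_comb_oracle_consistency():
    # guard against drift in the incremental-combinations update used above
    n, c = 30, 1
    for k in range(n):
        c = c * (n - k) // (k + 1)
        assert c == math.comb(n, k + 1)
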