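"""Nested cross-validation, metrics, and binomial chance correction.

The outer loop is a repeated participant-level 60/40 holdout (10 repeats);
all windows of a participant fall on one side of every split. Within each
repeat, feature scaling, any SMOTE balancing, ReliefF selection and the inner
10-fold grid search all see the outer training set only; the outer test set
is scored once with the refitted model. Naive Bayes skips the inner loop.

Observed accuracies are compared against the corrected chance level: the
smallest above-chance classification rate that a binomial test at the given
alpha would call significant for the test-set size.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from nirspain.datasets import LabelledDataset, balance_with_smote, build_task_dataset, TASKS, STREAMS
from nirspain.selection import select_features


class EvalError(ValueError):
    pass


ALGORITHMS = ("SVM", "kNN", "NB", "RF")


def default_grids(n_trees=500):
    """Hyperparameter grids; listed simple-to-complex so ties resolve simple."""
    return {
        "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.001, 0.01, 0.1, 1.0]},
        "kNN": {"n_neighbors": [3, 5, 7, 9, 11, 13, 15]},
        "RF": {"max_features": ["sqrt", 0.333, 0.5]},
        "NB": {},
    }


@dataclass
class EvalConfig:
    n_repeats: int = 10
    train_fraction: float = 0.6
    inner_folds: int = 10
    algorithms: tuple = ALGORITHMS
    grids: dict = field(default_factory=default_grids)
    rf_trees: int = 500
    relieff_k: int | None = None  # override the sqrt rule (fNIRS uses 15)
    manual_cutoff: int | None = None
    smote_threshold: float = 1.1
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise EvalError("train_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise EvalError("inner_folds must be >= 2")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise EvalError(f"unknown algorithms {unknown}")


def _make_estimator(algorithm, config, seed):
    if algorithm == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if algorithm == "kNN":
        return KNeighborsClassifier()
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=config.rf_trees, random_state=seed)
    raise EvalError(f"unknown algorithm {algorithm!r}")


def outer_split(groups, train_fraction=0.6, seed=0):
    """Participant-level holdout split: (train_participants, test_participants)."""
    groups = np.asarray(groups)
    if groups.size == 0:
        raise EvalError("group vector missing or empty")
    participants = np.unique(groups)
    if len(participants) < 5:
        raise EvalError("need at least 5 participants for a group-wise split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(participants)
    n_train = int(round(train_fraction * len(participants)))
    n_train = min(max(n_train, 1), len(participants) - 1)
    return set(perm[:n_train]), set(perm[n_train:])


def binary_metrics(y_true, y_pred, scores=None):
    """(accuracy, f1, tpr, tnr, auc); positive class is 1 (Hard / pain)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise EvalError("empty test set")
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    accuracy = (tp + tn) / len(y_true)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: tpr/tnr/auc undefined")
        return float(accuracy), float(f1), float("nan"), float("nan"), float("nan")
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    auc = float("nan") if scores is None else float(roc_auc_score(y_true, scores))
    return float(accuracy), float(f1), float(tpr), float(tnr), auc


def chance_threshold(n_test, alpha=0.05, n_classes=2):
    """Corrected chance level for a finite test set.

    Smallest k with BinomCDF(k; n_test, 1/n_classes) >= 1 - alpha, divided by
    n_test: accuracies at or above this rate are unlikely (p < alpha) under
    guessing. Approaches 1/n_classes as n_test grows.
    """
    if n_test < 1:
        raise EvalError("n_test must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise EvalError("alpha must be in (0, 1)")
    p = 1.0 / n_classes
    k = int(binom.ppf(1.0 - alpha, n_test, p))
    while binom.cdf(k, n_test, p) < 1.0 - alpha:
        k += 1
    return k / n_test


@dataclass
class CrossValReport:
    task: str
    stream: str
    per_repeat: pd.DataFrame  # algorithm, repeat, metrics, n_test, params
    chance_thresholds: dict  # {"realised": mean over repeats, "printed_n": ...}
    config: EvalConfig
    selected_features: list  # per repeat

    METRICS = ("accuracy", "f1", "tpr", "tnr", "auc")

    def aggregate(self) -> pd.DataFrame:
        g = self.per_repeat.groupby("algorithm")[list(self.METRICS)]
        mean, sd = g.mean(), g.std(ddof=1)
        out = pd.concat({"mean": mean, "sd": sd}, axis=1)
        return out.reindex([a for a in ALGORITHMS if a in mean.index])

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["algorithms"] = list(cfg["algorithms"])
        return {
            "task": self.task,
            "stream": self.stream,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "aggregate": json.loads(self.aggregate().to_json()),
            "chance_thresholds": self.chance_thresholds,
            "config": cfg,
            "selected_features": self.selected_features,
        }


def _row_hash(X, y):
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def nested_cv(dataset: LabelledDataset, config: EvalConfig | None = None) -> CrossValReport:
    """Repeated participant-level holdout with an inner tuning loop."""
    config = config or EvalConfig()
    rows, selected_all = [], []
    master = np.random.SeedSequence(config.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(config.n_repeats)]
    for rep, rep_seed in enumerate(repeat_seeds):
        for attempt in range(10):
            split_seed = rep_seed + attempt
            train_p, test_p = outer_split(dataset.groups, config.train_fraction, split_seed)
            tr = np.isin(dataset.groups, list(train_p))
            te = ~tr
            if len(np.unique(dataset.y[tr])) == 2 and len(np.unique(dataset.y[te])) == 2:
                break
            warnings.warn(f"repeat {rep}: degenerate single-class partition; resampled "
                          f"with seed {split_seed + 1}")
        X_tr, y_tr = dataset.X[tr], dataset.y[tr]
        X_te, y_te = dataset.X[te], dataset.y[te]
        test_hash = _row_hash(X_te, y_te)

        scaler = StandardScaler().fit(X_tr)
        Z_tr, Z_te = scaler.transform(X_tr), scaler.transform(X_te)

        ranked = select_features(Z_tr, y_tr, dataset.feature_names,
                                 k=config.relieff_k, manual_cutoff=config.manual_cutoff)
        idx = [dataset.feature_names.index(f) for f in ranked.selected]
        selected_all.append({"repeat": rep, "features": ranked.selected,
                             "k": ranked.k, "cutoff": ranked.cutoff})
        S_tr, S_te = Z_tr[:, idx], Z_te[:, idx]

        S_fit, y_fit, smote_report = balance_with_smote(
            S_tr, y_tr, k_neighbors=config.smote_k, seed=rep_seed,
            ratio_threshold=config.smote_threshold)

        for algorithm in config.algorithms:
            est = _make_estimator(algorithm, config, rep_seed)
            grid = config.grids.get(algorithm, {})
            if algorithm == "NB" or not grid:
                model, params = est.fit(S_fit, y_fit), {"tuned": False}
            else:
                inner = KFold(config.inner_folds, shuffle=True, random_state=rep_seed)
                search = GridSearchCV(est, grid, cv=inner, scoring="accuracy", n_jobs=1)
                search.fit(S_fit, y_fit)
                model, params = search.best_estimator_, dict(search.best_params_)
            y_pred = model.predict(S_te)
            if hasattr(model, "decision_function"):
                scores = model.decision_function(S_te)
            else:
                scores = model.predict_proba(S_te)[:, 1]
            acc, f1, tpr, tnr, auc = binary_metrics(y_te, y_pred, scores)
            rows.append({
                "algorithm": algorithm, "repeat": rep, "seed": rep_seed,
                "accuracy": acc, "f1": f1, "tpr": tpr, "tnr": tnr, "auc": auc,
                "n_test": int(te.sum()), "params": json.dumps(params, default=str),
                "smote": smote_report["smote_applied"],
            })
        assert _row_hash(X_te, y_te) == test_hash, "test rows mutated during tuning"

    per_repeat = pd.DataFrame(rows)
    n_tests = per_repeat.groupby("repeat")["n_test"].first()
    thresholds = {
        "realised_mean": float(np.mean([chance_threshold(n) for n in n_tests])),
        "per_repeat": {int(r): chance_threshold(int(n)) for r, n in n_tests.items()},
    }
    return CrossValReport(task=dataset.task, stream=dataset.stream, per_repeat=per_repeat,
                          chance_thresholds=thresholds, config=config,
                          selected_features=selected_all)


# --- study orchestration ---------------------------------------------------

#: reference analysis sample sizes for the corrected chance thresholds
PRINTED_N = {"demand": 400, "pain_easy": 160, "pain_hard": 160}


def run_study(processed_sessions, config: EvalConfig | None = None,
              tasks=TASKS, streams=STREAMS, fnirs_relieff_k=15) -> dict:
    """All task x stream classification analyses over a preprocessed cohort.

    Returns ``{(task, stream): CrossValReport}``-style dict keyed by
    ``"{task}_{stream}"``, each report carrying realised and printed-n chance
    thresholds. fNIRS analyses use the k=15 ReliefF override; HR analyses use
    the square-root rule (k=3 for 6 features).
    """
    from dataclasses import replace as _replace

    config = config or EvalConfig()
    reports = {}
    for task in tasks:
        for stream in streams:
            dataset = build_task_dataset(processed_sessions, task, stream)
            cfg = _replace(config, relieff_k=fnirs_relieff_k if stream == "fnirs" else None)
            report = nested_cv(dataset, cfg)
            report.chance_thresholds["printed_n"] = chance_threshold(PRINTED_N[task])
            reports[f"{task}_{stream}"] = report
    return reports


def report_tables(reports: dict) -> str:
    """Human-readable mean(sd) metric tables, one block per task x stream."""
    lines = []
    for key, rep in reports.items():
        agg = rep.aggregate()
        lines.append(f"== {key} ==")
        thr = rep.chance_thresholds
        lines.append(f"corrected chance: realised {thr['realised_mean']:.4f}"
                     + (f", printed-n {thr['printed_n']:.4f}" if "printed_n" in thr else ""))
        header = "metric    " + "".join(f"{a:>16}" for a in agg.index)
        lines.append(header)
        for metric in rep.METRICS:
            cells = "".join(
                f"  {agg[('mean', metric)][a]:.3f} ({agg[('sd', metric)][a]:.2f})"
                for a in agg.index)
            lines.append(f"{metric:<10}" + cells)
        lines.append("")
    return "\n".join(lines)
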