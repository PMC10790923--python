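"""Labelled dataset construction for the three classification problems.

* ``demand`` — Easy vs Hard game demand, full-game windows of all four game
  conditions collapsed by demand level.
* ``pain_easy`` / ``pain_hard`` — pain vs no-pain within one demand level,
  with per-participant duration matching: the analysed segment of both the
  game+pain and the game-only session is the first T seconds of the game,
  where T is that participant's cold-pressor immersion duration at that
  demand level. Matching balances the wall-clock data entering both classes.

SMOTE is provided for any residual class imbalance; it is applied by the
evaluation stage to training partitions only, never before the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from nirspain.features import (
    EpochFeatureTable,
    ProcessedSession,
    extract_session_features,
    fnirs_feature_columns,
    hr_feature_columns,
)

TASKS = ("demand", "pain_easy", "pain_hard")
STREAMS = ("fnirs", "hr")


class DatasetError(ValueError):
    pass


@dataclass
class LabelledDataset:
    X: np.ndarray  # (rows, features)
    y: np.ndarray  # binary, 1 = positive class (Hard / pain)
    groups: np.ndarray  # participant id per row
    feature_names: list
    task: str
    stream: str
    balance_report: dict

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise DatasetError("X, y and groups must be row-aligned")

    @property
    def class_counts(self):
        return {int(c): int(n) for c, n in zip(*np.unique(self.y, return_counts=True))}


def match_durations(pain_session: ProcessedSession, nopain_session: ProcessedSession):
    """Truncate a no-pain session to its pain counterpart's immersion duration.

    Both sessions must come from the same participant and demand level. The
    returned session's game interval covers the first T seconds of the game,
    T being the immersion duration (immersion starts with the game). If T
    exceeds the no-pain game length, the no-pain session is left whole with a
    warning.
    """
    if pain_session.participant_id != nopain_session.participant_id:
        raise DatasetError("duration matching requires the same participant")
    if pain_session.demand != nopain_session.demand:
        raise DatasetError("duration matching requires the same demand level")
    if pain_session.immersion_interval is None:
        raise DatasetError("pain session has no immersion interval")
    t_im = pain_session.immersion_interval[1] - pain_session.immersion_interval[0]
    g0, g1 = nopain_session.game_interval
    if t_im > (g1 - g0) + 1e-9:
        warnings.warn(
            f"{pain_session.participant_id}: immersion {t_im:.1f} s exceeds "
            f"no-pain game length {g1 - g0:.1f} s; clipping"
        )
        t_im = g1 - g0
    return replace(nopain_session, game_interval=(g0, g0 + t_im))


def smote(X_minority, X_majority=None, k_neighbors=5, target_count=None, seed=0):
    """Synthetic minority oversampling.

    Each synthetic sample lies on the segment between a minority sample and
    one of its ``k_neighbors`` nearest minority neighbours (Euclidean), at a
    uniform random position strictly inside the segment. Returns the minority
    set augmented to ``target_count`` rows (default: the majority count).
    """
    X_min = np.asarray(X_minority, float)
    if len(X_min) < 2:
        raise DatasetError("SMOTE requires at least 2 minority samples")
    if k_neighbors >= len(X_min):
        raise DatasetError("k_neighbors must be < minority count")
    if target_count is None:
        if X_majority is None:
            raise DatasetError("need X_majority or target_count")
        target_count = len(X_majority)
    n_new = target_count - len(X_min)
    if n_new <= 0:
        return X_min.copy()
    D = cdist(X_min, X_min)
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1)[:, :k_neighbors]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(X_min), size=n_new)
    neigh = nn[base, rng.integers(0, k_neighbors, size=n_new)]
    gaps = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=n_new)[:, None]
    synth = X_min[base] + gaps * (X_min[neigh] - X_min[base])
    return np.vstack([X_min, synth])


def balance_with_smote(X, y, k_neighbors=5, seed=0, ratio_threshold=1.1):
    """Equalise class counts by SMOTE when the imbalance ratio exceeds the
    threshold; returns (X, y, report)."""
    classes, counts = np.unique(y, return_counts=True)
    report = {"before": {int(c): int(n) for c, n in zip(classes, counts)}}
    if len(classes) != 2 or max(counts) / max(min(counts), 1) <= ratio_threshold:
        report["after"] = report["before"]
        report["smote_applied"] = False
        return X, y, report
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    X_maj = X[y != minority]
    k = min(k_neighbors, len(X_min) - 1)
    X_aug = smote(X_min, X_maj, k_neighbors=k, seed=seed)
    X_out = np.vstack([X_maj, X_aug])
    y_out = np.concatenate([np.full(len(X_maj), classes[np.argmax(counts)]),
                            np.full(len(X_aug), minority)])
    report["after"] = {int(c): int(n) for c, n in
                       zip(*np.unique(y_out, return_counts=True))}
    report["smote_applied"] = True
    return X_out, y_out, report


def _stream_columns(stream):
    if stream == "fnirs":
        return fnirs_feature_columns()
    if stream == "hr":
        return hr_feature_columns()
    raise DatasetError(f"unknown stream {stream!r}")


def _dataset_from_table(df: pd.DataFrame, task, stream) -> LabelledDataset:
    cols = _stream_columns(stream)
    if task == "demand":
        y = (df["demand"] == "Hard").astype(int).to_numpy()
    else:
        y = (df["pain"] == "pain").astype(int).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    return LabelledDataset(
        X=df[cols].to_numpy(float),
        y=y,
        groups=df["participant_id"].to_numpy(),
        feature_names=cols,
        task=task,
        stream=stream,
        balance_report={"class_counts": {int(c): int(n) for c, n in zip(classes, counts)}},
    )


def build_task_dataset(processed_sessions, task, stream="fnirs",
                       feature_table: EpochFeatureTable | None = None) -> LabelledDataset:
    """Build the labelled dataset for one task and feature stream.

    ``processed_sessions`` is the cohort's preprocessed game sessions. For the
    demand task a precomputed ``feature_table`` can be passed to avoid
    re-extracting features; the pain tasks always re-window the
    duration-matched segments.
    """
    if task not in TASKS:
        raise DatasetError(f"unknown task {task!r}")
    game_sessions = [ps for ps in processed_sessions if ps.game_interval is not None]
    if task == "demand":
        if feature_table is None:
            from nirspain.features import assemble_features
            feature_table = assemble_features(game_sessions)
        return _dataset_from_table(feature_table.df, task, stream)

    demand = "Easy" if task == "pain_easy" else "Hard"
    by_participant: dict[str, dict[str, ProcessedSession]] = {}
    for ps in game_sessions:
        if ps.demand != demand:
            continue
        by_participant.setdefault(ps.participant_id, {})[ps.pain] = ps
    frames = []
    for pid, pair in sorted(by_participant.items()):
        if "pain" not in pair or "no_pain" not in pair:
            warnings.warn(f"{pid}: missing {demand} pain/no-pain pair; skipped")
            continue
        pain_ps, nopain_ps = pair["pain"], pair["no_pain"]
        t_im = pain_ps.immersion_interval[1] - pain_ps.immersion_interval[0]
        matched = match_durations(pain_ps, nopain_ps)
        frames.append(extract_session_features(pain_ps, max_duration_s=t_im))
        frames.append(extract_session_features(matched))
    if not frames:
        raise DatasetError(f"no complete pain/no-pain pairs for task {task}")
    return _dataset_from_table(pd.concat(frames, ignore_index=True), task, stream)
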