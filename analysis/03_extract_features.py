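"""Extract the epoch feature table from the preprocessed game sessions.

Reads scratch/processed/ (written by 02_preprocess_sessions.py), windows each
game into 8-s epochs and computes the 96 fNIRS features (40 HbO statistics +
56 connectivity) and 6 heart-rate statistics per epoch. The full table goes
to scratch/features.csv; a small structural summary (row counts per
condition, column counts) goes to results/feature_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nirspain.features import ProcessedSession, assemble_features

ROOT = Path(__file__).resolve().parents[1]


def load_processed(path) -> ProcessedSession:
    z = np.load(path, allow_pickle=True)
    events = [(str(l), float(s), float(e)) for l, s, e in z["events"]]
    game = next(((s, e) for l, s, e in events if l == "game"), None)
    imm = next(((s, e) for l, s, e in events if l == "immersion"), None)
    return ProcessedSession(
        participant_id=str(z["participant_id"]),
        condition=str(z["condition"]),
        hbo=z["hbo"],
        hr=z["hr"],
        sample_rate=float(z["sample_rate"]),
        game_interval=game,
        immersion_interval=imm,
    )


def main():
    processed = [load_processed(p) for p in sorted((ROOT / "scratch" / "processed").glob("*.npz"))]
    game_sessions = [ps for ps in processed if ps.game_interval is not None]
    table = assemble_features(game_sessions)
    (ROOT / "scratch").mkdir(exist_ok=True)
    table.to_csv(ROOT / "scratch" / "features.csv")
    summary = (table.df.groupby("condition")
               .agg(rows=("participant_id", "size"),
                    participants=("participant_id", "nunique"))
               .reset_index())
    summary["fnirs_feature_cols"] = len(table.fnirs_columns)
    summary["hr_feature_cols"] = len(table.hr_columns)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary.to_csv(res / "feature_summary.csv", index=False)
    print(f"{len(table.df)} epochs from {len(game_sessions)} game sessions")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
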