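"""Run the six classification analyses (3 tasks x 2 feature streams).

Reads scratch/processed/, builds the demand and duration-matched pain
datasets, and runs nested group-wise cross-validation (ReliefF selection +
inner grid search) for SVM, kNN, NB and RF. Writes per-analysis metric
tables to results/classification_<task>_<stream>.csv, the per-repeat records
to results/classification_per_repeat.csv, and a text report mirroring the
mean (sd) table layout to results/classification_report.txt, with corrected
chance levels attached.
"""

import argparse
import importlib.util
import json
from pathlib import Path

import pandas as pd

from nirspain.evaluate import EvalConfig, run_study, report_tables

ROOT = Path(__file__).resolve().parents[1]

_spec = importlib.util.spec_from_file_location("extract", Path(__file__).parent / "03_extract_features.py")
_extract = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_extract)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--quick", action="store_true",
                    help="reduced grids / repeats / trees for a fast pass")
    args = ap.parse_args()

    processed = [_extract.load_processed(p)
                 for p in sorted((ROOT / "scratch" / "processed").glob("*.npz"))]
    if args.quick:
        cfg = EvalConfig(n_repeats=3, inner_folds=3, rf_trees=100, seed=args.seed,
                         grids={"SVM": {"C": [1.0, 10.0], "gamma": [0.01, 0.1]},
                                "kNN": {"n_neighbors": [3, 7, 11]},
                                "RF": {"max_features": ["sqrt"]}, "NB": {}})
    else:
        cfg = EvalConfig(seed=args.seed)
    reports = run_study(processed, cfg)

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    per_repeat = []
    for key, rep in reports.items():
        agg = rep.aggregate()
        agg.columns = [f"{m}_{s}" for s, m in agg.columns]
        agg.to_csv(res / f"classification_{key}.csv")
        pr = rep.per_repeat.copy()
        pr.insert(0, "analysis", key)
        per_repeat.append(pr)
        thr = rep.chance_thresholds
        print(f"{key}: SVM acc {agg.loc['SVM', 'accuracy_mean']:.3f} "
              f"(chance {thr['realised_mean']:.3f} realised / {thr['printed_n']:.4f} printed-n)")
    pd.concat(per_repeat, ignore_index=True).to_csv(res / "classification_per_repeat.csv", index=False)
    (res / "classification_report.txt").write_text(report_tables(reports))
    (res / "chance_thresholds.json").write_text(json.dumps(
        {k: r.chance_thresholds for k, r in reports.items()}, indent=1))
    print(f"tables -> {res}")


if __name__ == "__main__":
    main()
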