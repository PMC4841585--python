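"""Full benchmark reproduction against the curated peptide spreadsheet.

Requires the externally supplied table of experimentally mapped
S-sulfenylated / non-S-sulfenylated 21-mer cysteine peptides (place it at
data/benchmark/sulfenylation_sites.xlsx or pass --xlsx).  Runs the complete
protocol: dataset loading, repeated balanced 10-fold cross-validation for
each encoder, and an independent 145/268 hold-out evaluation.

Usage:
    python scripts/benchmark_reproduction.py --xlsx <path> --seed 0 \
        --out results/benchmark.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from sulfsite.benchmark import load_benchmark_xlsx
from sulfsite.evaluation import evaluate_predictions
from sulfsite.model import ModelConfig, repeated_balanced_cv, train_ensemble


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--xlsx", type=Path, default=Path("data/benchmark/sulfenylation_sites.xlsx")
    )
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--repeats", type=int, default=20)
    parser.add_argument("--out", type=Path, default=Path("results/benchmark.json"))
    args = parser.parse_args()

    data = load_benchmark_xlsx(args.xlsx)
    n_pos = sum(data.labels)
    results = {
        "positives": {"value": n_pos, "n": len(data)},
        "negatives": {"value": len(data) - n_pos, "n": len(data)},
    }
    config = ModelConfig(seed=args.seed)
    for scheme in ("aaindex", "binary", "psaap"):
        s = repeated_balanced_cv(data, scheme, config, k=10, repeats=args.repeats)
        results[f"cv_auc_{scheme}"] = {"value": round(s.mean["AUC"], 4), "n": len(data)}
        results[f"cv_auc_sd_{scheme}"] = {
            "value": round(s.sd["AUC"], 4),
            "n": args.repeats,
        }

    # Independent split mirroring the published 145/268 hold-out.
    rng = np.random.default_rng(args.seed + 7)
    pos_idx = [i for i, y in enumerate(data.labels) if y == 1]
    neg_idx = [i for i, y in enumerate(data.labels) if y == 0]
    test = sorted(
        list(rng.choice(pos_idx, size=145, replace=False))
        + list(rng.choice(neg_idx, size=268, replace=False))
    )
    train = sorted(set(range(len(data))) - set(test))
    model = train_ensemble(data.subset(train), "aaindex", config, n_models=20)
    held = data.subset(test)
    preds = model.predict_windows(held.windows)
    report = evaluate_predictions(
        held.labels, [p.probability for p in preds], cutoff=config.cutoff
    )
    results["independent_auc"] = {"value": round(report.AUC, 4), "n": len(held)}
    results["independent_mcc"] = {"value": round(report.MCC, 4), "n": len(held)}

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2) + "\n")
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
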