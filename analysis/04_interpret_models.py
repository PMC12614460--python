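#!/usr/bin/env python
"""Summarize convergence and interpretability artifacts from a pipeline run.

Reads results/run/ (from 03_tune_and_evaluate.py) and reports the swarm
convergence improvement per tuned family and the global feature-importance
rankings of the tuned models, writing a combined summary table.
"""

import argparse
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rundir", type=Path, default=Path("results/run"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for family in ("random_forest", "xgboost"):
        path = args.rundir / f"trace_{family}.csv"
        if not path.exists():
            continue
        trace = pd.read_csv(path)
        first, last = trace.best_fitness.iloc[0], trace.best_fitness.iloc[-1]
        print(f"{family}: CV error {first:.4f} -> {last:.4f} over "
              f"{len(trace)} iterations (best CV accuracy {1 - last:.4f})")

    summaries = []
    for path in sorted(args.rundir.glob("importance_*.csv")):
        model = path.stem.replace("importance_", "")
        ranking = pd.read_csv(path)
        ranking.insert(0, "model", model)
        summaries.append(ranking)
        top = ", ".join(ranking.feature.head(3))
        print(f"{model} top predictors: {top}")
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(
            args.outdir / "importance_summary.csv", index=False)
        print(f"wrote importance_summary.csv -> {args.outdir}")


if __name__ == "__main__":
    main()
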