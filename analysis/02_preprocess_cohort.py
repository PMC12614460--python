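#!/usr/bin/env python
"""Split, impute, screen, scale, and rebalance the generated cohort.

Reads results/cohort.csv (from 01_simulate_cohort.py), applies the
leakage-guarded preprocessing chain, and writes the partition tables, the
univariate screening report, and the SMOTE-balanced training set.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from salp_clinrisk import preprocess
from salp_clinrisk.cohort import OUTCOME_COLUMN


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--top-k", type=int, default=9)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.outdir / "cohort.csv")
    split = preprocess.split_cohort(table, seed=args.seed)
    print(f"split sizes: train {len(split.train)}, validation "
          f"{len(split.validation)}, test {len(split.test)}")

    parts = {}
    for name, idx in (("train", split.train), ("validation", split.validation),
                      ("test", split.test)):
        parts[name] = preprocess.impute_chained(
            table.iloc[idx].reset_index(drop=True), n_cycles=10, seed=args.seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = preprocess.screen_features(parts["train"], alpha=args.alpha,
                                            top_k=args.top_k)
    screen.sort_values("p_value").to_csv(args.outdir / "feature_screen.csv", index=False)
    selected = screen.loc[screen["selected"], "variable"].tolist()
    print(f"{int((screen.p_value < args.alpha).sum())} variables at p < {args.alpha}; "
          f"kept top {len(selected)}: {', '.join(selected)}")

    keep = selected + [OUTCOME_COLUMN]
    _, train_t, val_t, test_t = preprocess.standardize(
        parts["train"][keep], parts["validation"][keep], parts["test"][keep])
    train_bal = preprocess.apply_smote(train_t, seed=args.seed)
    for name, df in (("train", train_t), ("validation", val_t), ("test", test_t),
                     ("train_smote", train_bal)):
        df.to_csv(args.outdir / f"{name}_scaled.csv", index=False)
    n1 = int(train_bal[OUTCOME_COLUMN].sum())
    print(f"SMOTE balanced training set: {n1} / {len(train_bal) - n1} per class")


if __name__ == "__main__":
    main()
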