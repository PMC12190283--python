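#!/usr/bin/env python
"""Train and evaluate classifiers on the stored feature tables.

One shared subject-level split is used for every condition and
classifier family so per-condition accuracies are paired. Outputs:

* ``classification_summary.csv`` — one row per (condition, family) with
  the selected hyperparameters, mean per-subject accuracy with its
  expanded uncertainty, MCC and confusion counts;
* ``condition_vs_reference.csv`` — paired one-tailed p-values asking
  whether each condition beats the reference accuracy;
* ``reports.json`` — full per-subject detail.

Example::

    python analysis/03_classification.py --workdir results/run1 \
        --families rf --reduced-grid
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from eegmfe import classify
from eegmfe.pipeline import reports_to_frame
from eegmfe.stats import accuracy_condition_test


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--test-fraction", type=float, default=30 / 104)
    parser.add_argument(
        "--families", nargs="+", default=["svm", "rf", "knn"],
        choices=["svm", "rf", "knn"],
    )
    parser.add_argument(
        "--reduced-grid", action="store_true",
        help="use the small desk-scale hyperparameter grids",
    )
    args = parser.parse_args()

    feat_dir = args.workdir / "features"
    tables = {
        p.stem: pd.read_csv(p) for p in sorted(feat_dir.glob("*.csv"))
    }
    if not tables:
        raise SystemExit(f"no feature tables in {feat_dir}")

    grids = classify.reduced_grids() if args.reduced_grid else classify.default_grids()
    grids = {f: grids[f] for f in args.families}

    any_table = next(iter(tables.values()))
    subjects = any_table.drop_duplicates("subject_id")[
        ["subject_id", "group", "dataset_id"]
    ]
    split = classify.make_split(
        subjects, test_fraction=args.test_fraction, seed=args.seed
    )
    print(f"split: {len(split.train_subjects)} train / "
          f"{len(split.test_subjects)} test subjects")

    reports = {}
    for cond, table in tables.items():
        train = table[table["subject_id"].isin(split.train_subjects)]
        test = table[table["subject_id"].isin(split.test_subjects)]
        for family, grid in grids.items():
            chosen = classify.loso_select(train, grid, seed=args.seed)
            rep = classify.fit_evaluate(
                train, test, family, chosen, seed=args.seed, condition=cond
            )
            reports[(cond, family)] = rep
            print(f"{cond:13s} {family:4s} acc {rep.mean_accuracy:.3f} "
                  f"± {rep.expanded_uncertainty:.3f}  MCC {rep.mcc:.3f}")

    summary = reports_to_frame(reports)
    summary.to_csv(args.workdir / "classification_summary.csv", index=False)

    rows = []
    for family in grids:
        ref = reports.get(("reference", family))
        if ref is None:
            continue
        for cond in tables:
            if cond == "reference":
                continue
            p = accuracy_condition_test(
                ref.per_subject_accuracy,
                reports[(cond, family)].per_subject_accuracy,
            )
            rows.append({"condition": cond, "classifier": family,
                         "p_one_tailed_vs_reference": p})
    if rows:
        pd.DataFrame(rows).to_csv(
            args.workdir / "condition_vs_reference.csv", index=False
        )

    detail = {f"{cond}/{family}": rep.to_dict()
              for (cond, family), rep in reports.items()}
    (args.workdir / "reports.json").write_text(json.dumps(detail, indent=1))
    print(f"wrote summaries under {args.workdir}")


if __name__ == "__main__":
    main()
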