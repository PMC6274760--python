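"""Leave-dataset-out accuracy comparison: multi-task vs single-task.

Trains the mean-regularized multi-task learner (NET), a linear SVM and
lasso logistic regression on every cohort subset of size 2..4 and tests on
the held-out cohorts, with 5-fold stratified CV for hyperparameters.
Writes the accuracy table and summary under results/ and prints the mean
accuracy and its variability per training-set count.

Usage:  python analysis/03_evaluate.py [--data scratch/processed] [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from crosscohort_mtl import evaluate, io
from crosscohort_mtl.data import MultiTaskData
from crosscohort_mtl.demo import DEMO_GRIDS, DEMO_OPTS

def _load(data_dir: Path):
    import glob

    from crosscohort_mtl import io
    cohorts = []
    for expr_path in sorted(glob.glob(str(data_dir / "*_expr.tsv"))):
        cohorts.append(io.read_cohort(expr_path,
                                      expr_path.replace("_expr.tsv", "_meta.csv")))
    return MultiTaskData(cohorts)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("scratch/processed"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--repetitions", type=int, default=3)
    args = ap.parse_args()

    data = _load(args.data)
    algorithms = ["NET", "SVM_LIN", "LR_L1"]
    tables = []
    for n_d in (2, 3, 4):
        print(f"leave-dataset-out at n_d={n_d} ...")
        tables.append(evaluate.leave_dataset_out(
            data, algorithms, n_d=n_d, repetitions=args.repetitions,
            seed=args.seed, grids=DEMO_GRIDS, opts=DEMO_OPTS))
    table = pd.concat(tables, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "accuracy_table.csv", index=False)
    summ = evaluate.summarize(table)
    summ["mean"].to_csv(args.out / "accuracy_summary.csv", index=False)
    summ["test_set_se"].to_csv(args.out / "accuracy_test_set_se.csv", index=False)
    io.write_manifest(args.out, {"repetitions": args.repetitions},
                      {"seed": args.seed}, paths={"data": args.data})

    print("\nmean held-out accuracy (SE over repetitions):")
    print(summ["mean"].to_string(index=False))
    spread = (summ["test_set_se"].groupby(["algorithm", "n_d"])
              ["across_test_sd"].mean().rename("mean_across_test_sd")
              .reset_index())
    print("\nacross-test-set spread of accuracies (mean SD per repetition):")
    print(spread.to_string(index=False))


if __name__ == "__main__":
    main()
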