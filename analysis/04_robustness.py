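"""Bootstrap consistency, stability and success rates: NET vs linear SVM.

For every cohort subset and 20 stratified bootstrap replicates, fits both
algorithms, extracts signed gene profiles, and summarizes horizontal /
vertical consistency (per replicate), stability (per subset) and the
paired success rates of NET over SVM.  Writes the report under results/.

Usage:  python analysis/04_robustness.py [--data scratch/processed] [--seed 0]
"""

import argparse
import glob
from pathlib import Path

import pandas as pd

from crosscohort_mtl import io, robustness
from crosscohort_mtl.data import MultiTaskData
from crosscohort_mtl.demo import DEMO_OPTS, _demo_point


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("scratch/processed"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--bootstraps", type=int, default=20)
    args = ap.parse_args()

    cohorts = [io.read_cohort(p, p.replace("_expr.tsv", "_meta.csv"))
               for p in sorted(glob.glob(str(args.data / "*_expr.tsv")))]
    data = MultiTaskData(cohorts)
    algorithms = ["NET", "SVM_LIN"]
    report = robustness.run_robustness(
        data, algorithms, B=args.bootstraps, seed=args.seed,
        subset_sizes=(2, 3, 4, 5),
        hyperparams={a: _demo_point(a) for a in algorithms}, opts=DEMO_OPTS)

    args.out.mkdir(parents=True, exist_ok=True)
    io.write_report(report.to_long(), args.out / "robustness_report.csv")
    summary = report.summary()
    summary.to_csv(args.out / "robustness_summary.csv", index=False)

    print("mean consistency / stability per (algorithm, n_d):")
    wide = summary.pivot_table(index=["kind", "n_d"], columns="algorithm",
                               values="mean").round(3)
    print(wide.to_string())

    rows = []
    for kind in ("horizontal", "vertical"):
        for n_d in (2, 3, 4):
            rows.append({"metric": f"{kind} consistency", "n_d": n_d,
                         "success_rate_NET_over_SVM":
                         report.consistency_success_rate("NET", "SVM_LIN",
                                                         kind, n_d)})
    for n_d in (2, 3, 4, 5):
        rows.append({"metric": "stability", "n_d": n_d,
                     "success_rate_NET_over_SVM":
                     report.stability_success_rate("NET", "SVM_LIN", n_d)})
    sr = pd.DataFrame(rows)
    sr.to_csv(args.out / "success_rates.csv", index=False)
    io.write_manifest(args.out, {"B": args.bootstraps},
                      {"seed": args.seed}, paths={"data": args.data})
    print("\nsuccess rates (fraction of paired comparisons NET > SVM):")
    print(sr.to_string(index=False))


if __name__ == "__main__":
    main()
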