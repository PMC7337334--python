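"""The sample-composition experiment over the mixture grid.

Sweeps the proportion of non-affected subjects added to the affected
stratum and traces every battery statistic across conditions, averaging
over seeded replicates.  By default a reduced grid is used
(0.10 ... 1.00, 2.00, 4.00, 10.00 plus the three reference samples) with
50 replicates, which keeps a full run in the minutes range on one core;
pass --full-grid and --replicates 500 for the complete 22-condition design.

Writes results/tidy_results.csv and results/experiment.json.
Run 01_simulate_cohort.py first.
"""

import argparse
from pathlib import Path

from sympmix.experiment import BatteryConfig, MixtureDesign, run_experiment, tidy_results
from sympmix.io import read_symptom_table, write_results_json, write_tidy_csv

REDUCED_GRID = (0.10, 0.20, 0.40, 0.60, 0.80, 1.00, 2.00, 4.00, 10.00)
COHORT = Path("scratch/cohort.csv")
OUTDIR = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--replicates", type=int, default=50)
    parser.add_argument("--seed", type=int, default=303)
    parser.add_argument("--full-grid", action="store_true")
    args = parser.parse_args()

    data, labels = read_symptom_table(COHORT, case_column="affected")
    if args.full_grid:
        design = MixtureDesign(n_replicates=args.replicates, seed=args.seed)
    else:
        design = MixtureDesign(
            proportions=REDUCED_GRID, n_replicates=args.replicates, seed=args.seed
        )
    config = BatteryConfig(pa_kind="pearson")
    result = run_experiment(data, labels, design, config)

    OUTDIR.mkdir(exist_ok=True)
    tidy = tidy_results(result)
    write_tidy_csv(OUTDIR / "tidy_results.csv", tidy)
    write_results_json(OUTDIR / "experiment.json", result)

    wide = tidy.pivot(index="condition", columns="statistic", values="mean")
    order = ["dep"] + [str(p) for p in design.proportions] + ["full", "nondep"]
    cols = ["average_correlation", "var_explained_first", "eigen_ratio",
            "cfi", "tli", "rmsea", "h_scale", "edge_median"]
    print(wide.loc[order, cols].round(3))
    print(f"\nconditions: {design.n_conditions}, replicates: {design.n_replicates}")
    print(f"written to {OUTDIR / 'tidy_results.csv'} (config hash {result.config_hash})")


if __name__ == "__main__":
    main()
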