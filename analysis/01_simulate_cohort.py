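"""Simulate the study cohort: ordinal symptom battery with sum-score caseness.

Draws n = 6,000 subjects from the single-factor graded-response generator
(12 items, 6 categories, loadings 0.5-0.8, right-skewed thresholds),
calibrates the sum-score cutoff to ~6% prevalence, and writes the cohort
table to scratch/ (it is fully regenerable from the seed).  Run from the
repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from sympmix.io import write_provenance
from sympmix.synthetic import GeneratorConfig, simulate_cohort, write_csv

SEED = 11
OUT = Path("scratch")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = GeneratorConfig(n_subjects=6000, target_prevalence=0.06, seed=SEED)
    data, labels, _ = simulate_cohort(config)
    write_csv(OUT / "cohort.csv", data, labels)
    write_provenance(
        OUT / "cohort.provenance.json",
        {
            "n_subjects": config.n_subjects,
            "n_items": config.n_items,
            "n_categories": config.n_categories,
            "loadings": config.loadings,
            "thresholds": config.thresholds,
            "target_prevalence": config.target_prevalence,
        },
        seed=SEED,
    )
    print(f"cohort written to {OUT / 'cohort.csv'}")
    print(f"  n = {data.n_subjects}, items = {data.n_items}")
    print(f"  sum-score cutoff = {labels.cutoff}")
    print(f"  affected = {labels.n_affected} ({100 * labels.prevalence:.1f}%)")


if __name__ == "__main__":
    main()
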