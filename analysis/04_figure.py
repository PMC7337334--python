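"""Render the six-panel trajectory figure from the experiment results.

Reads results/tidy_results.csv (written by 03_mixture_experiment.py) and
writes scratch/composition_figure.png: correlations, both eigen indicators,
CFA fit indices, Mokken H, and network edge summaries, each as a function
of the proportion of non-affected subjects.
"""

from pathlib import Path

import pandas as pd

from sympmix.plotting import six_panel_figure

TIDY = Path("results/tidy_results.csv")
OUT = Path("scratch/composition_figure.png")


def main() -> None:
    tidy = pd.read_csv(TIDY)
    OUT.parent.mkdir(exist_ok=True)
    six_panel_figure(tidy, path=OUT)
    print(f"figure written to {OUT}")


if __name__ == "__main__":
    main()
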