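"""Six-panel summary figure of the mixture experiment.

Panel A: average polychoric correlation; B: variance explained by the first
eigenvalue; C: first/second eigenvalue ratio; D: CFA fit indices; E: Mokken
scale H; F: network edge summaries — each as a function of the proportion of
non-affected subjects, with the reference samples (dep, full, nondep) at the
ends of the axis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["six_panel_figure"]


def _axis_order(tidy: pd.DataFrame):
    conds = list(dict.fromkeys(tidy["condition"]))
    order = [c for c in ("dep",) if c in conds]
    order += sorted(
        (c for c in conds if c not in ("dep", "full", "nondep")), key=float
    )
    order += [c for c in ("full", "nondep") if c in conds]
    return order


def _series(tidy: pd.DataFrame, stat: str, order):
    sub = tidy[tidy["statistic"] == stat].set_index("condition")["mean"]
    return np.array([sub.get(c, np.nan) for c in order], dtype=float)


def six_panel_figure(tidy: pd.DataFrame, path=None):
    """Render the trajectory figure from a tidy results table."""
    order = _axis_order(tidy)
    x = np.arange(len(order))

    fig, axes = plt.subplots(3, 2, figsize=(11, 12), sharex=True)
    panels = [
        ("A  Average correlation", [("average_correlation", "average r")]),
        ("B  Variance explained (1st eigenvalue)", [("var_explained_first", "share")]),
        ("C  Eigenvalue ratio (1st/2nd)", [("eigen_ratio", "ratio")]),
        (
            "D  CFA fit indices",
            [("cfi", "CFI"), ("tli", "TLI"), ("rmsea", "RMSEA")],
        ),
        ("E  Mokken scalability", [("h_scale", "H (scale)")]),
        (
            "F  Network edges",
            [
                ("edge_median", "median"),
                ("edge_q25", "25th pct"),
                ("edge_q75", "75th pct"),
                ("edge_min", "min"),
                ("edge_max", "max"),
            ],
        ),
    ]
    for ax, (title, series) in zip(axes.ravel(), panels):
        for stat, label in series:
            ax.plot(x, _series(tidy, stat, order), marker="o", ms=3, label=label)
        ax.set_title(title, loc="left", fontsize=10)
        if len(series) > 1:
            ax.legend(fontsize=8)
        ax.grid(alpha=0.3)
    for ax in axes[-1]:
        ax.set_xticks(x)
        ax.set_xticklabels([str(c) for c in order], rotation=60, fontsize=7)
        ax.set_xlabel("proportion of non-affected subjects added")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
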