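"""Mokken scale analysis: scalability coefficients H for polytomous items.

The pairwise coefficient is the ratio of the observed covariance of two
items to the maximum covariance attainable under their fixed margins — the
covariance of the comonotonic (Fréchet upper bound) coupling.  Item and
scale coefficients aggregate the same numerators and denominators:

.. math::
    H_{ij} = \\frac{\\mathrm{Cov}(X_i, X_j)}{\\mathrm{Cov}^{\\max}(X_i, X_j)},
    \\qquad
    H = \\frac{\\sum_{i<j} \\mathrm{Cov}(X_i, X_j)}
              {\\sum_{i<j} \\mathrm{Cov}^{\\max}(X_i, X_j)}.

All covariances use the 1/n normalization; the ratios are invariant to
that choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from sympmix.polychoric import _as_values

__all__ = ["ScalabilityResult", "max_covariance_given_margins", "scalability"]


@dataclass(frozen=True)
class ScalabilityResult:
    H_pair: np.ndarray  # p x p, diagonal NaN
    H_item: np.ndarray
    H_scale: float
    cov_observed: np.ndarray
    cov_max: np.ndarray
    item_index: np.ndarray  # original column indices of retained items


def max_covariance_given_margins(
    margins_i: Sequence[int], margins_j: Sequence[int]
) -> float:
    """Covariance of the comonotonic coupling of two ordinal margins.

    The upper-Fréchet joint distribution is built by merging the two
    cumulative margins in sorted order; it maximizes the covariance over
    all couplings with the given margins.
    """
    ci = np.asarray(margins_i, dtype=float)
    cj = np.asarray(margins_j, dtype=float)
    if ci.sum() != cj.sum():
        raise ValueError("margins must have equal totals")
    n = ci.sum()
    if n <= 0:
        raise ValueError("margins must be non-empty")
    if np.count_nonzero(ci) < 2 or np.count_nonzero(cj) < 2:
        raise ValueError("degenerate (constant) item: max covariance undefined")

    vals_i = np.arange(ci.size)
    vals_j = np.arange(cj.size)
    mean_i = float(vals_i @ ci) / n
    mean_j = float(vals_j @ cj) / n

    # merge cumulative masses: joint mass between consecutive merge points
    cum_i = np.cumsum(ci)
    cum_j = np.cumsum(cj)
    merged = np.unique(np.concatenate((cum_i, cum_j)))
    prev = 0.0
    exy = 0.0
    for point in merged:
        mass = point - prev
        if mass > 0:
            x = vals_i[np.searchsorted(cum_i, prev, side="right")]
            y = vals_j[np.searchsorted(cum_j, prev, side="right")]
            exy += mass * x * y
        prev = point
    return exy / n - mean_i * mean_j


def scalability(data) -> ScalabilityResult:
    """Pairwise, per-item and scale H coefficients of an ordinal matrix.

    Constant items are excluded with a warning (their maximal covariance is
    undefined).  Per-item H uses all other retained items.
    """
    values = _as_values(data)
    n, p = values.shape
    keep = [j for j in range(p) if np.unique(values[:, j]).size >= 2]
    if len(keep) < p:
        warnings.warn(
            f"dropping degenerate item(s) at column(s) "
            f"{sorted(set(range(p)) - set(keep))}: constant responses",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-degenerate items remain")
    vals = values[:, keep]
    m = len(keep)

    cov_obs = np.cov(vals, rowvar=False, ddof=0)
    kmax = int(vals.max()) + 1
    margins = [np.bincount(vals[:, j], minlength=kmax) for j in range(m)]
    cov_max = np.zeros((m, m))
    for a in range(m):
        cov_max[a, a] = cov_obs[a, a]
        for b in range(a + 1, m):
            cov_max[a, b] = cov_max[b, a] = max_covariance_given_margins(
                margins[a], margins[b]
            )

    off = ~np.eye(m, dtype=bool)
    H_pair = np.full((m, m), np.nan)
    H_pair[off] = cov_obs[off] / cov_max[off]
    H_item = (cov_obs * off).sum(axis=1) / (cov_max * off).sum(axis=1)
    iu = np.triu_indices(m, k=1)
    H_scale = float(cov_obs[iu].sum() / cov_max[iu].sum())
    return ScalabilityResult(
        H_pair=H_pair,
        H_item=H_item,
        H_scale=H_scale,
        cov_observed=cov_obs,
        cov_max=cov_max,
        item_index=np.asarray(keep),
    )
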