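"""Eigenvalue summaries and Horn-style parallel analysis.

Dimensionality is judged three ways: (i) the spectrum of the latent
correlation matrix (variance explained by the first eigenvalue, first/second
eigenvalue ratio, with the conventional unidimensionality rules of thumb
> 20% and >= 3); (ii) parallel analysis, which retains the components whose
eigenvalues exceed the 95th percentile of eigenvalues obtained from
structure-free copies of the data built by independently permuting every
column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from sympmix.polychoric import nearest_pd, polychoric_matrix, _as_values

__all__ = [
    "EigenSummary",
    "ParallelAnalysisResult",
    "eigen_summary",
    "parallel_analysis",
    "unidimensionality_flags",
]


@dataclass(frozen=True)
class EigenSummary:
    eigenvalues: np.ndarray  # descending
    var_explained_first: float
    eigen_ratio: float


@dataclass(frozen=True)
class ParallelAnalysisResult:
    n_components: int
    actual_eigenvalues: np.ndarray
    threshold_eigenvalues: np.ndarray
    n_random_sets: int


def eigen_summary(rho: np.ndarray) -> EigenSummary:
    """Descending eigenvalues with the two unidimensionality indicators."""
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(rho, rho.T):
        raise ValueError("input must be symmetric")
    vals = np.linalg.eigvalsh(rho)[::-1]
    p = rho.shape[0]
    lam1 = float(vals[0])
    lam2 = float(vals[1])
    ratio = lam1 / lam2 if lam2 > 0 else np.inf
    return EigenSummary(
        eigenvalues=vals,
        var_explained_first=lam1 / p,
        eigen_ratio=float(ratio),
    )


def _correlation_eigenvalues(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "pearson":
        rho = np.corrcoef(values, rowvar=False)
        # constant columns yield NaN rows; treat them as uncorrelated
        bad = ~np.isfinite(rho)
        if bad.any():
            rho = np.where(bad, 0.0, rho)
            np.fill_diagonal(rho, 1.0)
    elif kind == "polychoric":
        rho = nearest_pd(polychoric_matrix(values).rho)
    else:
        raise ValueError("correlation_kind must be 'polychoric' or 'pearson'")
    return np.linalg.eigvalsh(rho)[::-1]


def parallel_analysis(
    data,
    n_random_sets: int = 100,
    percentile: float = 95.0,
    correlation_kind: str = "polychoric",
    rng: Optional[np.random.Generator] = None,
) -> ParallelAnalysisResult:
    """Component retention by column-permutation parallel analysis.

    Each random set is the observed data with every column independently
    permuted (preserving item margins, destroying inter-item structure).
    The retention threshold at rank *k* is the requested percentile of the
    permuted eigenvalues at that rank; counting stops at the first rank
    whose observed eigenvalue fails to exceed its threshold.

    ``correlation_kind='polychoric'`` matches the main analysis;
    ``'pearson'`` is a fast path for large replicate counts.
    """
    if n_random_sets < 1:
        raise ValueError("n_random_sets must be >= 1")
    values = _as_values(data)
    rng = rng if rng is not None else np.random.default_rng()

    actual = _correlation_eigenvalues(values, correlation_kind)
    p = actual.size
    perm_eigs = np.empty((n_random_sets, p))
    shuffled = values.copy()
    for r in range(n_random_sets):
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        eig = _correlation_eigenvalues(shuffled, correlation_kind)
        if eig.size != p:  # degenerate drop changed dimension; pad with zeros
            eig = np.pad(eig, (0, p - eig.size))
        perm_eigs[r] = eig
    thresholds = np.percentile(perm_eigs, percentile, axis=0)

    n_components = 0
    for k in range(p):
        if actual[k] > thresholds[k]:
            n_components += 1
        else:
            break
    return ParallelAnalysisResult(
        n_components=n_components,
        actual_eigenvalues=actual,
        threshold_eigenvalues=thresholds,
        n_random_sets=n_random_sets,
    )


def unidimensionality_flags(summary: EigenSummary) -> tuple:
    """Rules of thumb: first-eigenvalue variance share strictly above 20%
    and first/second eigenvalue ratio of at least 3."""
    return (summary.var_explained_first > 0.20, summary.eigen_ratio >= 3.0)
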