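"""Two-step maximum-likelihood polychoric correlations.

Step 1 estimates each item's normal-scale thresholds from its marginal
category proportions; step 2 maximizes, for every item pair, the bivariate
ordinal likelihood over the latent correlation with the thresholds held
fixed.  Cell probabilities are bivariate-normal rectangle probabilities,

.. math::
    P(a < X \\le b,\\; c < Y \\le d)
    = \\int_a^b \\phi(x)\\,
      \\left[\\Phi\\!\\left(\\tfrac{d - \\rho x}{\\sqrt{1-\\rho^2}}\\right)
           - \\Phi\\!\\left(\\tfrac{c - \\rho x}{\\sqrt{1-\\rho^2}}\\right)\\right] dx,

evaluated by fixed-order Gauss–Legendre quadrature on each x-interval
(truncated at |x| = 8, beyond which the normal mass is below 1e-15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

__all__ = [
    "ThresholdSet",
    "PolychoricMatrix",
    "PairEstimate",
    "DegenerateItemError",
    "thresholds_from_margins",
    "rectangle_probabilities",
    "pair_log_likelihood",
    "estimate_pair",
    "contingency_table",
    "polychoric_matrix",
    "nearest_pd",
    "average_offdiagonal",
]

PROB_FLOOR = 1e-12  # cell-probability floor before taking logs
RHO_BOUND = 1.0 - 1e-6  # clip for |rho| at the boundary
_TRUNC = 8.0  # latent-scale truncation for quadrature
_GL_ORDER = 48

_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_ORDER)


class DegenerateItemError(ValueError):
    """Raised when an item has fewer than two non-empty categories."""


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing normal-scale cutpoints of one ordinal item."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if tau.size == 0:
            raise DegenerateItemError("item needs at least 2 non-empty categories")
        if not np.all(np.isfinite(tau)):
            raise ValueError("interior thresholds must be finite")
        if np.any(np.diff(tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "tau", tau)

    @property
    def n_categories(self) -> int:
        return self.tau.size + 1

    @property
    def extended(self) -> np.ndarray:
        """Cutpoints padded with -inf and +inf."""
        return np.concatenate(([-np.inf], self.tau, [np.inf]))


class PairEstimate(NamedTuple):
    rho: float
    loglik: float
    boundary: bool
    converged: bool


@dataclass(frozen=True)
class PolychoricMatrix:
    """p x p latent correlation matrix with per-item thresholds."""

    rho: np.ndarray
    thresholds: List[ThresholdSet]
    n_effective: int
    item_labels: Optional[List[str]] = None
    boundary_pairs: Optional[List[tuple]] = None
    dropped_items: Optional[List[int]] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho must be square")
        if not np.allclose(r, r.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho must have unit diagonal")
        object.__setattr__(self, "rho", r)

    @property
    def n_items(self) -> int:
        return self.rho.shape[0]

    def to_frame(self):
        import pandas as pd

        labels = self.item_labels or [f"item_{j + 1}" for j in range(self.n_items)]
        return pd.DataFrame(self.rho, index=labels, columns=labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def thresholds_from_margins(category_counts: Sequence[int]) -> ThresholdSet:
    """Thresholds as normal quantiles of the cumulative margin.

    Zero-count categories are collapsed into their neighbour toward the
    nearer tail before estimation, which keeps all thresholds finite and
    strictly increasing.
    """
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("category counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    nonzero = counts[counts > 0]
    if nonzero.size < 2:
        raise DegenerateItemError("item needs at least 2 non-empty categories")
    # collapsing empty categories = dropping their (duplicate) cutpoints
    cum = np.cumsum(nonzero)[:-1] / total
    return ThresholdSet(ndtri(cum))


def rectangle_probabilities(
    rho: float, tau_i: ThresholdSet, tau_j: ThresholdSet
) -> np.ndarray:
    """Full ``K_i x K_j`` table of bivariate-normal cell probabilities."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    a = np.clip(tau_i.extended, -_TRUNC, _TRUNC)  # x cutpoints, length Ki+1
    cj = tau_j.extended  # y cutpoints, ndtr handles +-inf
    lo, hi = a[:-1], a[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    # nodes: (Ki, M)
    x = mid[:, None] + half[:, None] * _GL_X[None, :]
    wphi = half[:, None] * _GL_W[None, :] * np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
    s = np.sqrt(1.0 - rho * rho)
    z = (cj[None, None, :] - rho * x[:, :, None]) / s  # (Ki, M, Kj+1)
    inner = np.diff(ndtr(z), axis=2)  # (Ki, M, Kj)
    probs = np.einsum("im,imj->ij", wphi, inner)
    return probs


def pair_log_likelihood(
    rho: float,
    tau_i: ThresholdSet,
    tau_j: ThresholdSet,
    table: np.ndarray,
    prob_floor: float = PROB_FLOOR,
) -> float:
    """Multinomial log-likelihood of a contingency table at latent rho."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("table counts must be nonnegative")
    probs = rectangle_probabilities(rho, tau_i, tau_j)
    return float(np.sum(table * np.log(np.maximum(probs, prob_floor))))


def contingency_table(x: np.ndarray, y: np.ndarray, kx: int, ky: int) -> np.ndarray:
    """Cross-classification counts of two dense-coded ordinal vectors."""
    code = np.asarray(x) * ky + np.asarray(y)
    return np.bincount(code, minlength=kx * ky).reshape(kx, ky)


def estimate_pair(
    table: np.ndarray,
    tau_i: Optional[ThresholdSet] = None,
    tau_j: Optional[ThresholdSet] = None,
    tol: float = 1e-6,
    full_output: bool = False,
):
    """ML estimate of the latent correlation from a contingency table.

    Thresholds default to the two-step margin estimates of the table itself.
    The likelihood is maximized by bounded scalar optimization on
    ``[-1 + 1e-6, 1 - 1e-6]``; solutions at the boundary are returned
    clipped and flagged.
    """
    table = np.asarray(table, dtype=float)
    if tau_i is None:
        tau_i = thresholds_from_margins(table.sum(axis=1))
        # collapse empty rows so dims match the collapsed thresholds
        table = table[table.sum(axis=1) > 0]
    if tau_j is None:
        tau_j = thresholds_from_margins(table.sum(axis=0))
        table = table[:, table.sum(axis=0) > 0]

    res = minimize_scalar(
        lambda r: -pair_log_likelihood(r, tau_i, tau_j, table),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(f"polychoric optimizer failed to converge: {res.message}")
    rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    boundary = abs(rho) >= RHO_BOUND - 10 * tol
    est = PairEstimate(rho=rho, loglik=-float(res.fun), boundary=boundary, converged=True)
    return est if full_output else est.rho


def _as_values(data) -> np.ndarray:
    values = getattr(data, "values", data)
    return np.asarray(values)


def polychoric_matrix(data, item_labels: Optional[List[str]] = None) -> PolychoricMatrix:
    """Estimate all pairwise polychoric correlations of an ordinal matrix.

    Items with fewer than two observed categories are dropped with a
    warning; observed codes are densified per item, which collapses empty
    categories exactly as :func:`thresholds_from_margins` does.
    """
    values = _as_values(data)
    n, p = values.shape
    codes: List[np.ndarray] = []
    taus: List[ThresholdSet] = []
    kept: List[int] = []
    dropped: List[int] = []
    for j in range(p):
        uniq, inv = np.unique(values[:, j], return_inverse=True)
        if uniq.size < 2:
            dropped.append(j)
            continue
        counts = np.bincount(inv)
        taus.append(thresholds_from_margins(counts))
        codes.append(inv)
        kept.append(j)
    if dropped:
        warnings.warn(
            f"dropping degenerate item(s) at column(s) {dropped}: "
            "fewer than 2 observed categories",
            stacklevel=2,
        )
    m = len(kept)
    if m < 2:
        raise DegenerateItemError("fewer than 2 non-degenerate items remain")

    rho = np.eye(m)
    boundary_pairs: List[tuple] = []
    for a in range(m):
        for b in range(a + 1, m):
            table = contingency_table(
                codes[a], codes[b], taus[a].n_categories, taus[b].n_categories
            )
            try:
                est = estimate_pair(table, taus[a], taus[b], full_output=True)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"polychoric estimation failed for item pair ({kept[a]}, {kept[b]})"
                ) from exc
            rho[a, b] = rho[b, a] = est.rho
            if est.boundary:
                boundary_pairs.append((kept[a], kept[b]))

    if item_labels is not None:
        labels = [item_labels[j] for j in kept]
    else:
        labels = [f"item_{j + 1}" for j in kept]
    return PolychoricMatrix(
        rho=rho,
        thresholds=taus,
        n_effective=n,
        item_labels=labels,
        boundary_pairs=boundary_pairs or None,
        dropped_items=dropped or None,
    )


def nearest_pd(rho: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair with unit diagonal.

    Returns the input unchanged when it is already positive definite.
    """
    rho = np.asarray(rho, dtype=float)
    if not np.allclose(rho, rho.T):
        raise ValueError("input must be symmetric")
    vals, vecs = np.linalg.eigh(rho)
    if vals.min() > eig_floor:
        return rho
    clipped = np.maximum(vals, eig_floor)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return 0.5 * (fixed + fixed.T)


def average_offdiagonal(rho: np.ndarray) -> float:
    """Arithmetic mean of the upper-triangle correlations."""
    rho = np.asarray(rho, dtype=float)
    iu = np.triu_indices_from(rho, k=1)
    return float(rho[iu].mean())
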