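"""Regularized partial-correlation networks via the graphical lasso.

A Gaussian graphical model is fitted to the (PD-repaired) latent correlation
matrix over a descending log-spaced penalty path; the extended Bayesian
information criterion (EBIC, hyperparameter gamma) selects the penalty.
Edges are the off-diagonal partial correlations
``-K_ij / sqrt(K_ii K_jj)`` of the selected precision matrix K; edge
summaries are taken over *all* p(p-1)/2 possible edges, zeros included, so
the median of a sparse network can legitimately be 0.

The L1-penalized inverse-covariance optimization is delegated to
scikit-learn's coordinate-descent graphical lasso; path construction, EBIC
scoring and the KKT diagnostics are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

__all__ = [
    "NetworkResult",
    "penalty_path",
    "glasso_fit",
    "kkt_residual",
    "ebic_select",
    "edge_summaries",
    "network_battery",
    "edge_list",
]

EDGE_EPS = 1e-8  # |partial| below this counts as an exact zero


@dataclass(frozen=True)
class NetworkResult:
    precision: np.ndarray
    partials: np.ndarray
    penalty: float
    ebic_gamma: float
    edge_count: int
    summaries: Dict[str, float]
    ebic: float = np.nan


def penalty_path(
    rho: np.ndarray, n_points: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending log-spaced penalties from ``max |off-diagonal|`` down to
    ``min_ratio`` times it; a single point at 0 when there is no correlation
    to shrink."""
    rho = np.asarray(rho, dtype=float)
    off = rho[np.triu_indices_from(rho, k=1)]
    lam_max = float(np.abs(off).max()) if off.size else 0.0
    if lam_max <= 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_points)


def _partials_from_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    partials = -K / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return 0.5 * (partials + partials.T)


def glasso_fit(
    rho: np.ndarray,
    penalty: float,
    tol: Optional[float] = None,
    max_iter: int = 10_000,
    kkt_tol: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Precision and working covariance at one penalty.

    Solves ``max_K log det K - tr(R K) - penalty * sum_{i != j} |K_ij|``
    (off-diagonal penalty only) by block coordinate descent.
    ``penalty = 0`` is the unpenalized MLE, the direct inverse of R.

    The convergence tolerance defaults to ``1e-4`` times the mean absolute
    off-diagonal of R and is tightened (up to 100x) until the KKT residual
    falls below ``kkt_tol``.
    """
    R = np.asarray(rho, dtype=float)
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if penalty == 0.0:
        precision = np.linalg.inv(R)
        return 0.5 * (precision + precision.T), R.copy()
    off = R[np.triu_indices_from(R, k=1)]
    if tol is None:
        tol = max(1e-4 * float(np.abs(off).mean()), 1e-8)
    last_exc = None
    for _ in range(3):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, precision = _sk_graphical_lasso(
                    R, alpha=float(penalty), tol=tol, enet_tol=1e-10, max_iter=max_iter
                )
        except FloatingPointError as exc:
            last_exc = exc
            tol /= 10.0
            continue
        precision = 0.5 * (precision + precision.T)
        if kkt_residual(R, precision, penalty) <= kkt_tol:
            return precision, cov
        tol /= 10.0
    if last_exc is not None:
        raise RuntimeError(
            f"graphical lasso failed to converge at penalty {penalty:g}: {last_exc}"
        ) from last_exc
    raise RuntimeError(
        f"graphical lasso KKT residual above {kkt_tol:g} at penalty {penalty:g}"
    )


def kkt_residual(R: np.ndarray, precision: np.ndarray, penalty: float) -> float:
    """Largest violation of the glasso stationarity conditions.

    At the optimum, ``Sigma_hat = K^{-1}`` satisfies
    ``|Sigma_hat_ij - R_ij| <= penalty`` off-diagonal, with equality
    (``Sigma_hat_ij - R_ij = penalty * sign(K_ij)``) wherever
    ``K_ij != 0``, and matches R on the diagonal.
    """
    sigma = np.linalg.inv(precision)
    diff = sigma - R
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    res_diag = float(np.abs(np.diag(diff)).max())
    zero = off & (np.abs(precision) <= EDGE_EPS)
    nonzero = off & (np.abs(precision) > EDGE_EPS)
    res = res_diag
    if zero.any():
        res = max(res, float(np.maximum(np.abs(diff[zero]) - penalty, 0.0).max()))
    if nonzero.any():
        res = max(
            res,
            float(np.abs(diff[nonzero] - penalty * np.sign(precision[nonzero])).max()),
        )
    return res


def _edge_count(partials: np.ndarray) -> int:
    iu = np.triu_indices_from(partials, k=1)
    return int(np.sum(np.abs(partials[iu]) > EDGE_EPS))


def ebic_select(
    fits: List[Tuple[float, np.ndarray]],
    R: np.ndarray,
    n: int,
    gamma: float = 0.5,
) -> NetworkResult:
    """Pick the penalty minimizing ``EBIC = -2 l + E log n + 4 E gamma log p``.

    ``l = (n/2)(log det K - tr(R K))`` is the Gaussian log-likelihood and E
    the number of nonzero upper-triangle precision entries.  Ties go to the
    larger penalty (the sparser model).

    Parameters
    ----------
    fits
        ``(penalty, precision)`` pairs, any order.
    """
    if not fits:
        raise ValueError("at least one fit is required")
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    best = None
    for penalty, K in sorted(fits, key=lambda f: -f[0]):
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            continue
        ll = 0.5 * n * (logdet - float(np.sum(R * K)))
        partials = _partials_from_precision(K)
        E = _edge_count(partials)
        ebic = -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)
        if best is None or ebic < best[0] - 1e-12:
            best = (ebic, penalty, K, partials, E)
    if best is None:
        raise RuntimeError("no positive-definite fit on the path")
    ebic, penalty, K, partials, E = best
    return NetworkResult(
        precision=K,
        partials=partials,
        penalty=float(penalty),
        ebic_gamma=gamma,
        edge_count=E,
        summaries=edge_summaries(partials),
        ebic=float(ebic),
    )


def edge_summaries(partials: np.ndarray) -> Dict[str, float]:
    """Median/quartiles/extremes over all possible edges, zeros included."""
    iu = np.triu_indices_from(np.asarray(partials), k=1)
    e = np.asarray(partials)[iu]
    return {
        "median": float(np.median(e)),
        "min": float(e.min()),
        "max": float(e.max()),
        "q25": float(np.percentile(e, 25)),
        "q75": float(np.percentile(e, 75)),
    }


def network_battery(
    rho: np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_points: int = 100,
    min_ratio: float = 0.01,
) -> NetworkResult:
    """Path construction, glasso fits and EBIC selection in one call."""
    R = np.asarray(getattr(rho, "rho", rho), dtype=float)
    path = penalty_path(R, n_points=n_points, min_ratio=min_ratio)
    fits = []
    for lam in path:
        try:
            K, _ = glasso_fit(R, lam)
        except RuntimeError:
            continue  # skip non-converged penalties; EBIC picks among the rest
        fits.append((float(lam), K))
    return ebic_select(fits, R, n=n, gamma=gamma)


def edge_list(result: NetworkResult, item_labels: Optional[List[str]] = None):
    """Nonzero edges as a tidy table (item_a, item_b, partial_correlation)."""
    import pandas as pd

    p = result.partials.shape[0]
    labels = item_labels or [f"item_{j + 1}" for j in range(p)]
    rows = []
    iu = np.triu_indices(p, k=1)
    for a, b in zip(*iu):
        w = result.partials[a, b]
        if abs(w) > EDGE_EPS:
            rows.append({"item_a": labels[a], "item_b": labels[b], "partial_correlation": w})
    return pd.DataFrame(rows, columns=["item_a", "item_b", "partial_correlation"])
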