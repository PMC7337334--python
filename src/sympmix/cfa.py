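"""Single-factor confirmatory factor analysis on a latent correlation matrix.

The model states that every off-diagonal correlation is the product of the
two item loadings, :math:`\\Sigma_{ij}(\\lambda) = \\lambda_i \\lambda_j`.
Loadings are estimated by (diagonally) weighted least squares over the
p(p-1)/2 unique correlations; the weights are inverse sampling variances of
the polychoric correlations when available (nonparametric bootstrap over
subjects) and a uniform ``1/(n-1)`` scale otherwise, which places the test
statistic on the familiar chi-square-like scale without the bootstrap cost.
Fit is summarized by CFI, TLI and RMSEA with the zero-correlation model as
the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from sympmix.polychoric import _as_values, contingency_table, estimate_pair, thresholds_from_margins

__all__ = [
    "CfaFit",
    "implied_matrix",
    "fit_one_factor",
    "test_statistic",
    "fit_indices",
    "cfa_battery",
    "bootstrap_pair_variances",
]

LOADING_BOUND = 1.0 - 1e-6


@dataclass(frozen=True)
class CfaFit:
    """Estimated loadings plus test statistics and fit indices."""

    loadings: np.ndarray
    T: float
    df: int
    T_baseline: float
    df_baseline: int
    CFI: float
    TLI: float
    RMSEA: float
    n_used: int
    objective: float = np.nan
    boundary: bool = False
    tli_defined: bool = True


def implied_matrix(loadings: np.ndarray) -> np.ndarray:
    """Model-implied correlation matrix ``lambda lambda^T`` with unit diagonal."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1.0):
        raise ValueError("|loading| must be < 1")
    implied = np.outer(lam, lam)
    np.fill_diagonal(implied, 1.0)
    return implied


def _pair_weights(p: int, weights) -> np.ndarray:
    n_pairs = p * (p - 1) // 2
    if weights is None:
        return np.ones(n_pairs)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_pairs,):
        raise ValueError(f"weights must have length {n_pairs}")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w


def fit_one_factor(
    rho_matrix,
    weights: Optional[np.ndarray] = None,
    n: Optional[int] = None,
    tol: float = 1e-8,
) -> Tuple[np.ndarray, float, bool]:
    """Weighted least-squares loadings of the one-factor model.

    Minimizes ``sum_{i<j} w_ij (r_ij - l_i l_j)^2`` with loadings
    constrained to ``(-1 + 1e-6, 1 - 1e-6)``.  Three starts are tried —
    a first-eigenvector scaling, a flat 0.5 vector, and zero — and the
    best optimum wins, ties breaking toward the smaller-norm solution;
    the sign is normalized so the mean loading is >= 0.

    Returns ``(loadings, objective, boundary_flag)``.
    """
    R = np.asarray(getattr(rho_matrix, "rho", rho_matrix), dtype=float)
    p = R.shape[0]
    if n is not None and n <= p:
        raise ValueError("sample size must exceed the number of items")
    iu = np.triu_indices(p, k=1)
    r = R[iu]
    w = _pair_weights(p, weights)

    def objective(lam):
        resid = r - lam[iu[0]] * lam[iu[1]]
        return float(np.sum(w * resid**2))

    def gradient(lam):
        resid = r - lam[iu[0]] * lam[iu[1]]
        g = np.zeros(p)
        wr = -2.0 * w * resid
        np.add.at(g, iu[0], wr * lam[iu[1]])
        np.add.at(g, iu[1], wr * lam[iu[0]])
        return g

    vals, vecs = np.linalg.eigh(R)
    lam1, v1 = vals[-1], vecs[:, -1]
    start_eig = np.clip(v1 * np.sqrt(max(lam1, 0.0)), -0.95, 0.95)
    # the zero start is stationary: it survives only when no correlation is
    # left to explain, making it the canonical solution for identity input
    starts = [start_eig, np.full(p, 0.5), np.zeros(p)]

    best = None
    bounds = [(-LOADING_BOUND, LOADING_BOUND)] * p
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=gradient,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 2000},
        )
        # ties (e.g. an identity input, where any one-hot loading vector is
        # also a zero-residual optimum) break toward the smaller-norm solution
        if (
            best is None
            or res.fun < best.fun - 1e-9
            or (abs(res.fun - best.fun) <= 1e-9
                and np.linalg.norm(res.x) < np.linalg.norm(best.x))
        ):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("one-factor fit failed from every start")
    lam = best.x
    if lam.mean() < 0:
        lam = -lam
    boundary = bool(np.any(np.abs(lam) >= LOADING_BOUND - 1e-9))
    return lam, float(best.fun), boundary


def test_statistic(
    rho_matrix,
    loadings: np.ndarray,
    n: int,
    pair_variances: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Residual-based fit statistic and its zero-correlation baseline.

    ``T = sum_{i<j} (r_ij - sigma_ij(lambda))^2 / v_ij`` where ``v_ij`` are
    per-pair sampling variances of the correlations.  Without supplied
    variances a uniform ``1/(n-1)`` is used, i.e. ``T = (n-1) * SSR``.
    """
    R = np.asarray(getattr(rho_matrix, "rho", rho_matrix), dtype=float)
    p = R.shape[0]
    iu = np.triu_indices(p, k=1)
    r = R[iu]
    if pair_variances is None:
        v = np.full(r.size, 1.0 / max(n - 1, 1))
    else:
        v = np.asarray(pair_variances, dtype=float)
        if np.any(v <= 0):
            raise ValueError("pair variances must be strictly positive")
    implied = implied_matrix(loadings)[iu]
    T = float(np.sum((r - implied) ** 2 / v))
    T_baseline = float(np.sum(r**2 / v))
    return T, T_baseline


def fit_indices(
    T: float, df: int, T_baseline: float, df_baseline: int, n: int
) -> Tuple[float, float, float, bool]:
    """CFI, TLI and RMSEA from test statistics.

    Returns ``(CFI, TLI, RMSEA, tli_defined)``; TLI is flagged undefined
    when the baseline statistic does not exceed its degrees of freedom.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    tiny = 1e-12
    excess = max(T - df, 0.0)
    denom = max(T_baseline - df_baseline, T - df, tiny)
    cfi = float(np.clip(1.0 - excess / denom, 0.0, 1.0))
    base_ratio = T_baseline / df_baseline
    tli_defined = base_ratio > 1.0
    tli = ((base_ratio - T / df) / (base_ratio - 1.0)) if tli_defined else np.nan
    rmsea = float(np.sqrt(max((T - df) / (df * (n - 1)), 0.0)))
    return cfi, float(tli), rmsea, tli_defined


def bootstrap_pair_variances(
    data,
    n_boot: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Nonparametric bootstrap sampling variances of each polychoric r.

    Subjects are resampled with replacement; thresholds and the pair
    correlation are re-estimated per resample (the full two-step procedure),
    and the empirical variance across resamples is returned per pair, in
    upper-triangle order.  Variances are floored at ``1e-6 / n`` to keep the
    DWLS weights finite on exceptionally stable pairs.
    """
    values = _as_values(data)
    n, p = values.shape
    rng = rng if rng is not None else np.random.default_rng()
    n_pairs = p * (p - 1) // 2
    rhos = np.empty((n_boot, n_pairs))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = values[idx]
        codes = []
        taus = []
        for j in range(p):
            uniq, inv = np.unique(sample[:, j], return_inverse=True)
            codes.append(inv)
            taus.append(
                thresholds_from_margins(np.bincount(inv)) if uniq.size >= 2 else None
            )
        k = 0
        for a in range(p):
            for bj in range(a + 1, p):
                if taus[a] is None or taus[bj] is None:
                    rhos[b, k] = np.nan
                else:
                    table = contingency_table(
                        codes[a], codes[bj], taus[a].n_categories, taus[bj].n_categories
                    )
                    rhos[b, k] = estimate_pair(table, taus[a], taus[bj])
                k += 1
    var = np.nanvar(rhos, axis=0, ddof=1)
    return np.maximum(var, 1e-6 / n)


def cfa_battery(
    rho_matrix,
    n: int,
    pair_variances: Optional[np.ndarray] = None,
) -> CfaFit:
    """Fit the one-factor model and assemble all fit statistics."""
    R = np.asarray(getattr(rho_matrix, "rho", rho_matrix), dtype=float)
    p = R.shape[0]
    df = p * (p - 1) // 2 - p
    df_baseline = p * (p - 1) // 2
    if df <= 0:
        raise ValueError("one-factor model needs at least 4 items (df > 0)")
    weights = None if pair_variances is None else 1.0 / np.asarray(pair_variances)
    lam, obj, boundary = fit_one_factor(R, weights=weights, n=n)
    T, T_baseline = test_statistic(R, lam, n, pair_variances)
    cfi, tli, rmsea, tli_defined = fit_indices(T, df, T_baseline, df_baseline, n)
    return CfaFit(
        loadings=lam,
        T=T,
        df=df,
        T_baseline=T_baseline,
        df_baseline=df_baseline,
        CFI=cfi,
        TLI=tli,
        RMSEA=rmsea,
        n_used=n,
        objective=obj,
        boundary=boundary,
        tli_defined=tli_defined,
    )
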