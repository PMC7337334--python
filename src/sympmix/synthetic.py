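"""Synthetic ordinal symptom data from a probit graded-response model.

A single latent severity trait :math:`\\theta \\sim N(0, 1)` drives every
item: the latent response of item *j* is

.. math:: y_j = \\lambda_j \\theta + e_j, \\qquad e_j \\sim N(0, 1 - \\lambda_j^2),

so each :math:`y_j` is standard normal and the latent inter-item correlation
is :math:`\\lambda_i \\lambda_j`.  The observed ordinal response is the index
of the interval of the item's threshold vector into which :math:`y_j` falls.
Caseness ("affected") is defined by a sum-score cutoff calibrated to a target
prevalence — the collider on which downstream sample selection conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd


def _default_loadings(n_items: int) -> np.ndarray:
    # heterogeneous discriminations, mid-to-high range typical of a
    # well-constructed clinical scale
    return np.linspace(0.5, 0.8, n_items)


def _default_thresholds(n_items: int, n_categories: int) -> np.ndarray:
    """Right-skewed thresholds: most population mass in the low categories.

    The base cutpoints put roughly 69% of subjects in category 0 and < 1%
    in the top category, mimicking symptom-frequency data in a general
    population.  A small per-item shift keeps items non-identical.
    """
    base = 0.5 + 0.52 * np.arange(n_categories - 1)
    shifts = np.linspace(-0.2, 0.2, n_items)
    return base[None, :] + shifts[:, None]


@dataclass(frozen=True)
class GeneratorConfig:
    """Population parameters of the graded-response generator.

    Parameters
    ----------
    n_subjects
        Number of subjects to draw.
    n_items, n_categories
        Battery shape; items are coded ``0 .. n_categories - 1``.
    loadings
        Per-item factor loadings, each in ``[0, 1)``.
    thresholds
        ``n_items x (n_categories - 1)`` matrix of strictly increasing
        cutpoints on the standard-normal scale.
    n_factors, factor_correlation
        Number of latent traits (items split into contiguous blocks) and
        their common inter-correlation when ``n_factors > 1``.
    target_prevalence
        Fraction of subjects to classify as affected via the sum-score
        cutoff (default 0.061).
    seed
        Root seed; every random stream in the pipeline derives from it.
    """

    n_subjects: int
    n_items: int = 12
    n_categories: int = 6
    loadings: Optional[np.ndarray] = None
    thresholds: Optional[np.ndarray] = None
    n_factors: int = 1
    factor_correlation: float = 0.0
    target_prevalence: float = 0.061
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")
        if self.n_categories < 2:
            raise ValueError("n_categories must be at least 2")
        if self.n_factors <= 0:
            raise ValueError("n_factors must be positive")
        if not -1.0 < self.factor_correlation < 1.0:
            raise ValueError("factor_correlation must lie in (-1, 1)")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        lo = self.loadings if self.loadings is not None else _default_loadings(self.n_items)
        lo = np.asarray(lo, dtype=float)
        if lo.shape != (self.n_items,):
            raise ValueError(f"loadings must have length {self.n_items}")
        if np.any(lo < 0.0) or np.any(lo >= 1.0):
            raise ValueError("every loading must lie in [0, 1)")
        th = (
            self.thresholds
            if self.thresholds is not None
            else _default_thresholds(self.n_items, self.n_categories)
        )
        th = np.asarray(th, dtype=float)
        if th.shape != (self.n_items, self.n_categories - 1):
            raise ValueError(
                f"thresholds must have shape ({self.n_items}, {self.n_categories - 1})"
            )
        if np.any(np.diff(th, axis=1) <= 0.0):
            raise ValueError("each threshold row must be strictly increasing")
        object.__setattr__(self, "loadings", lo)
        object.__setattr__(self, "thresholds", th)


@dataclass(frozen=True)
class SymptomMatrix:
    """An ``n x p`` integer matrix of ordinal item responses."""

    values: np.ndarray
    category_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if v.shape[1] < 2:
            raise ValueError("at least 2 items are required")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("values must be integer-coded")
        if v.size and (v.min() < 0 or v.max() >= self.category_count):
            raise ValueError(
                f"entries must lie in 0..{self.category_count - 1}"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset(self, index: np.ndarray) -> "SymptomMatrix":
        return SymptomMatrix(self.values[np.asarray(index)], self.category_count)


@dataclass(frozen=True)
class CaseLabels:
    """Boolean affected/non-affected labels from a sum-score cutoff."""

    affected: np.ndarray
    cutoff: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "affected", np.asarray(self.affected, dtype=bool))

    @property
    def prevalence(self) -> float:
        return float(self.affected.mean())

    @property
    def n_affected(self) -> int:
        return int(self.affected.sum())


def generate(config: GeneratorConfig) -> Tuple[SymptomMatrix, np.ndarray]:
    """Draw a symptom matrix and its latent trait scores.

    Returns
    -------
    data : SymptomMatrix
    theta : ndarray
        Latent scores, shape ``(n_subjects,)`` for a single factor or
        ``(n_subjects, n_factors)`` otherwise.

    Notes
    -----
    Latent draws and item noise come from independent streams spawned from
    the config seed, so later pipeline stages that spawn their own streams
    never perturb the generated data.
    """
    ss = np.random.SeedSequence(config.seed)
    theta_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    n, p, k = config.n_subjects, config.n_items, config.n_categories
    if config.n_factors == 1:
        theta = theta_rng.standard_normal(n)
        theta_items = theta[:, None]  # broadcast over items
        item_factor = np.zeros(p, dtype=int)
    else:
        corr = np.full((config.n_factors, config.n_factors), config.factor_correlation)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        theta = theta_rng.standard_normal((n, config.n_factors)) @ chol.T
        # contiguous blocks of items per factor, as balanced as possible
        item_factor = (np.arange(p) * config.n_factors) // p
        theta_items = theta[:, item_factor]

    lam = config.loadings
    noise_sd = np.sqrt(1.0 - lam**2)
    latent = theta_items * lam[None, :] + noise_rng.standard_normal((n, p)) * noise_sd[None, :]

    values = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        values[:, j] = np.searchsorted(config.thresholds[j], latent[:, j], side="left")
    data = SymptomMatrix(values, category_count=k)
    return data, theta


def sum_scores(data: SymptomMatrix) -> np.ndarray:
    """Per-subject total score, range ``0 .. p * (K - 1)``."""
    return data.values.sum(axis=1)


def calibrate_cutoff(scores: np.ndarray, target_prevalence: float) -> Tuple[int, float]:
    """Smallest observed score value whose upper-tail fraction is <= target.

    Returns the cutoff together with the realized prevalence
    ``mean(scores >= cutoff)``.

    Raises
    ------
    ValueError
        If all scores are identical (no cutoff can separate a tail).
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    scores = np.asarray(scores)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("target prevalence unreachable: all scores are equal")
    n = scores.size
    # fraction of scores >= u for each unique value u, ascending u
    counts_ge = n - np.searchsorted(np.sort(scores), uniq, side="left")
    ok = counts_ge / n <= target_prevalence
    idx = int(np.argmax(ok))
    if not ok[idx]:
        raise ValueError("target prevalence unreachable")
    cutoff = int(uniq[idx])
    realized = float(counts_ge[idx] / n)
    return cutoff, realized


def classify(scores: np.ndarray, cutoff: int) -> CaseLabels:
    """Label subjects affected when their sum score reaches the cutoff."""
    scores = np.asarray(scores)
    return CaseLabels(affected=scores >= int(cutoff), cutoff=int(cutoff))


def simulate_cohort(config: GeneratorConfig) -> Tuple[SymptomMatrix, CaseLabels, np.ndarray]:
    """Generate data, calibrate the cutoff, and classify in one call."""
    data, theta = generate(config)
    scores = sum_scores(data)
    cutoff, _ = calibrate_cutoff(scores, config.target_prevalence)
    labels = classify(scores, cutoff)
    return data, labels, theta


def to_frame(data: SymptomMatrix, labels: Optional[CaseLabels] = None) -> pd.DataFrame:
    """Tabular view: ``item_1 .. item_p``, ``sum_score``, and ``affected``."""
    p = data.n_items
    df = pd.DataFrame(data.values, columns=[f"item_{j + 1}" for j in range(p)])
    df["sum_score"] = sum_scores(data)
    if labels is not None:
        df["affected"] = labels.affected.astype(int)
    return df


def write_csv(path, data: SymptomMatrix, labels: Optional[CaseLabels] = None) -> None:
    to_frame(data, labels).to_csv(path, index=False)
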