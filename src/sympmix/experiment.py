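"""The sample-composition mixture experiment.

Starting from a stratified cohort (affected vs non-affected by a sum-score
cutoff), each numeric condition pi builds samples consisting of *all*
affected subjects plus a without-replacement draw of
``round(pi * n_affected)`` non-affected subjects; three symbolic conditions
— ``dep`` (affected only), ``full`` (the whole cohort) and ``nondep``
(non-affected only) — complete the grid (22 conditions with defaults).
Every statistic of the analysis battery (average polychoric correlation,
eigen summaries, parallel analysis, one-factor CFA fit, Mokken H, network
edge summaries) is computed per replicate and averaged across replicates
per condition; symbolic conditions are computed once on their fixed sample.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from sympmix import cfa as cfa_mod
from sympmix import mokken as mokken_mod
from sympmix import network as network_mod
from sympmix.dimensionality import eigen_summary, parallel_analysis
from sympmix.polychoric import average_offdiagonal, nearest_pd, polychoric_matrix
from sympmix.synthetic import CaseLabels, SymptomMatrix

__all__ = [
    "MixtureDesign",
    "BatteryConfig",
    "BatteryResult",
    "ExperimentResult",
    "draw_mixture",
    "run_battery",
    "run_experiment",
    "tidy_results",
]

DEFAULT_PROPORTIONS = (
    0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00,
    2.00, 3.00, 4.00, 5.00, 6.00, 7.00, 8.00, 9.00, 10.00,
)
SYMBOLIC_CONDITIONS = ("dep", "full", "nondep")

#: scalar statistics averaged across replicates
SCALAR_STATISTICS = (
    "average_correlation",
    "var_explained_first",
    "eigen_ratio",
    "pa_components",
    "cfi",
    "tli",
    "rmsea",
    "h_scale",
    "edge_median",
    "edge_min",
    "edge_max",
    "edge_q25",
    "edge_q75",
    "edge_count",
)


@dataclass(frozen=True)
class MixtureDesign:
    """The condition grid: numeric mixing proportions plus the three
    reference samples, with the replicate count and root seed."""

    proportions: Tuple[float, ...] = DEFAULT_PROPORTIONS
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        props = tuple(float(x) for x in self.proportions)
        if any(x <= 0 for x in props):
            raise ValueError("proportions must be positive")
        if any(b <= a for a, b in zip(props, props[1:])):
            raise ValueError("proportions must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "proportions", props)

    @property
    def conditions(self) -> List[Union[str, float]]:
        """Ordered labels: ``dep``, the numeric grid, ``full``, ``nondep``."""
        return ["dep", *self.proportions, "full", "nondep"]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class BatteryConfig:
    """Settings shared by every battery invocation.

    ``pa_kind='polychoric'`` reuses the main correlation type inside
    parallel analysis; ``'pearson'`` is the fast path for replicated
    designs.  ``cfa_n_boot > 0`` switches the CFA test statistic to
    bootstrap-estimated per-pair variances (the DWLS weighting); 0 keeps
    the uniform ``1/(n-1)`` fast fallback.
    """

    pa_sets: int = 100
    pa_kind: str = "polychoric"
    pa_percentile: float = 95.0
    cfa_n_boot: int = 0
    ebic_gamma: float = 0.5
    path_points: int = 100
    path_min_ratio: float = 0.01
    min_sample: int = 50


@dataclass
class BatteryResult:
    """One sample's full statistic set, plus per-stage errors if any."""

    statistics: Dict[str, float]
    correlation_matrix: Optional[np.ndarray]
    sample_size: int
    n_affected: int
    n_nonaffected: int
    stage_errors: Dict[str, str] = field(default_factory=dict)
    loadings: Optional[np.ndarray] = None


@dataclass
class ExperimentResult:
    """Replicate-averaged statistics per condition."""

    conditions: List[Union[str, float]]
    means: Dict[Union[str, float], Dict[str, float]]
    sds: Dict[Union[str, float], Dict[str, float]]
    valid_counts: Dict[Union[str, float], Dict[str, int]]
    mean_correlation: Dict[Union[str, float], np.ndarray]
    n_replicates: int
    seed: int
    config_hash: str
    sample_sizes: Dict[Union[str, float], Dict[str, float]]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def draw_mixture(
    affected_index: np.ndarray,
    nonaffected_index: np.ndarray,
    proportion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """All affected subjects plus ``round(proportion * n_affected)``
    non-affected subjects drawn without replacement (half-up rounding)."""
    affected_index = np.asarray(affected_index)
    nonaffected_index = np.asarray(nonaffected_index)
    if proportion <= 0:
        raise ValueError("proportion must be positive")
    m = _round_half_up(proportion * affected_index.size)
    if m > nonaffected_index.size:
        raise ValueError(
            f"condition {proportion:g}: needs {m} non-affected subjects, "
            f"only {nonaffected_index.size} available"
        )
    extra = rng.choice(nonaffected_index, size=m, replace=False)
    return np.concatenate((affected_index, extra))


def run_battery(
    data: SymptomMatrix,
    n_affected: int = 0,
    config: Optional[BatteryConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> BatteryResult:
    """Run the full psychometric battery on one sample.

    The polychoric matrix is estimated once, PD-repaired once, and shared
    by the eigen, CFA and network stages; parallel analysis and Mokken
    scalability run on the raw data.  A failure in any downstream stage is
    recorded in ``stage_errors`` and leaves the other stages' statistics
    intact; a polychoric-stage failure invalidates the whole battery.
    """
    config = config or BatteryConfig()
    rng = rng if rng is not None else np.random.default_rng()
    n = data.n_subjects
    if n < config.min_sample:
        raise ValueError(f"sample size {n} below configured minimum {config.min_sample}")

    stats: Dict[str, float] = {k: np.nan for k in SCALAR_STATISTICS}
    errors: Dict[str, str] = {}
    loadings = None

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm = polychoric_matrix(data)
        R = nearest_pd(pm.rho)
    except Exception as exc:  # polychoric failure is fatal for the replicate
        return BatteryResult(
            statistics=stats,
            correlation_matrix=None,
            sample_size=n,
            n_affected=n_affected,
            n_nonaffected=n - n_affected,
            stage_errors={"polychoric": str(exc)},
        )
    stats["average_correlation"] = average_offdiagonal(R)

    try:
        es = eigen_summary(R)
        stats["var_explained_first"] = es.var_explained_first
        stats["eigen_ratio"] = es.eigen_ratio
    except Exception as exc:
        errors["eigen"] = str(exc)

    try:
        pa = parallel_analysis(
            data,
            n_random_sets=config.pa_sets,
            percentile=config.pa_percentile,
            correlation_kind=config.pa_kind,
            rng=rng,
        )
        stats["pa_components"] = float(pa.n_components)
    except Exception as exc:
        errors["parallel_analysis"] = str(exc)

    try:
        pair_var = None
        if config.cfa_n_boot > 0:
            pair_var = cfa_mod.bootstrap_pair_variances(
                data, n_boot=config.cfa_n_boot, rng=rng
            )
        fit = cfa_mod.cfa_battery(R, n=n, pair_variances=pair_var)
        stats["cfi"] = fit.CFI
        stats["tli"] = fit.TLI
        stats["rmsea"] = fit.RMSEA
        loadings = fit.loadings
    except Exception as exc:
        errors["cfa"] = str(exc)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = mokken_mod.scalability(data)
        stats["h_scale"] = sc.H_scale
    except Exception as exc:
        errors["mokken"] = str(exc)

    try:
        net = network_mod.network_battery(
            R,
            n=n,
            gamma=config.ebic_gamma,
            n_points=config.path_points,
            min_ratio=config.path_min_ratio,
        )
        stats["edge_median"] = net.summaries["median"]
        stats["edge_min"] = net.summaries["min"]
        stats["edge_max"] = net.summaries["max"]
        stats["edge_q25"] = net.summaries["q25"]
        stats["edge_q75"] = net.summaries["q75"]
        stats["edge_count"] = float(net.edge_count)
    except Exception as exc:
        errors["network"] = str(exc)

    return BatteryResult(
        statistics=stats,
        correlation_matrix=R,
        sample_size=n,
        n_affected=n_affected,
        n_nonaffected=n - n_affected,
        stage_errors=errors,
        loadings=loadings,
    )


def _config_hash(design: MixtureDesign, config: BatteryConfig, n_subjects: int) -> str:
    payload = {
        "proportions": design.proportions,
        "n_replicates": design.n_replicates,
        "seed": design.seed,
        "battery": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "n_subjects": n_subjects,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(
    data: SymptomMatrix,
    labels: CaseLabels,
    design: Optional[MixtureDesign] = None,
    config: Optional[BatteryConfig] = None,
) -> ExperimentResult:
    """Execute the battery over the whole mixture grid.

    Numeric conditions are replicated ``design.n_replicates`` times with
    independent seeded streams; symbolic conditions run once on their fixed
    sample.  Scalars are averaged over the replicates in which their stage
    succeeded; correlation matrices are averaged elementwise.
    """
    design = design or MixtureDesign()
    config = config or BatteryConfig()
    affected_idx = np.flatnonzero(labels.affected)
    nonaffected_idx = np.flatnonzero(~labels.affected)
    if affected_idx.size == 0 or nonaffected_idx.size == 0:
        raise ValueError("both strata must be non-empty")
    # feasibility check up-front, before any computation
    for prop in design.proportions:
        m = _round_half_up(prop * affected_idx.size)
        if m > nonaffected_idx.size:
            raise ValueError(
                f"infeasible condition {prop:g}: needs {m} non-affected subjects, "
                f"pool has {nonaffected_idx.size}"
            )

    ss = np.random.SeedSequence(design.seed)
    cond_seeds = ss.spawn(design.n_conditions)

    means: Dict = {}
    sds: Dict = {}
    counts: Dict = {}
    mean_corr: Dict = {}
    sizes: Dict = {}

    for cond, cseed in zip(design.conditions, cond_seeds):
        if cond == "dep":
            samples = [affected_idx]
        elif cond == "full":
            samples = [np.arange(data.n_subjects)]
        elif cond == "nondep":
            samples = [nonaffected_idx]
        else:
            rep_seeds = cseed.spawn(design.n_replicates)
            samples = None

        per_rep: List[Dict[str, float]] = []
        corr_stack: List[np.ndarray] = []
        nsz = []
        if samples is not None:  # symbolic condition: single run
            rng = np.random.default_rng(cseed)
            idx = samples[0]
            n_aff = int(labels.affected[idx].sum())
            res = run_battery(data.subset(idx), n_affected=n_aff, config=config, rng=rng)
            per_rep.append(res.statistics)
            if res.correlation_matrix is not None:
                corr_stack.append(res.correlation_matrix)
            nsz.append(res.sample_size)
        else:
            for rseed in rep_seeds:
                rng = np.random.default_rng(rseed)
                idx = draw_mixture(affected_idx, nonaffected_idx, float(cond), rng)
                res = run_battery(
                    data.subset(idx),
                    n_affected=affected_idx.size,
                    config=config,
                    rng=rng,
                )
                per_rep.append(res.statistics)
                if res.correlation_matrix is not None:
                    corr_stack.append(res.correlation_matrix)
                nsz.append(res.sample_size)

        cond_means: Dict[str, float] = {}
        cond_sds: Dict[str, float] = {}
        cond_counts: Dict[str, int] = {}
        for key in SCALAR_STATISTICS:
            vals = np.array([r[key] for r in per_rep], dtype=float)
            ok = np.isfinite(vals)
            cond_counts[key] = int(ok.sum())
            cond_means[key] = float(vals[ok].mean()) if ok.any() else np.nan
            cond_sds[key] = float(vals[ok].std(ddof=0)) if ok.any() else np.nan
        means[cond] = cond_means
        sds[cond] = cond_sds
        counts[cond] = cond_counts
        mean_corr[cond] = (
            np.mean(np.stack(corr_stack), axis=0) if corr_stack else None
        )
        sizes[cond] = {
            "sample_size": float(np.mean(nsz)),
            "n_affected": float(affected_idx.size if cond != "nondep" else 0),
            "n_nonaffected": float(np.mean(nsz))
            - float(affected_idx.size if cond != "nondep" else 0),
        }

    return ExperimentResult(
        conditions=design.conditions,
        means=means,
        sds=sds,
        valid_counts=counts,
        mean_correlation=mean_corr,
        n_replicates=design.n_replicates,
        seed=design.seed,
        config_hash=_config_hash(design, config, data.n_subjects),
        sample_sizes=sizes,
    )


def statistics_from_mean_matrix(
    result: ExperimentResult, condition, n: int, gamma: float = 0.5
) -> Dict[str, float]:
    """Eigen, CFA and network statistics recomputed on the replicate-averaged
    correlation matrix of one condition (the alternative reading of
    "averaging analyses": average the matrix first, analyze once)."""
    R = result.mean_correlation[condition]
    if R is None:
        raise ValueError(f"no averaged correlation matrix for condition {condition!r}")
    R = nearest_pd(R)
    out: Dict[str, float] = {"average_correlation": average_offdiagonal(R)}
    es = eigen_summary(R)
    out["var_explained_first"] = es.var_explained_first
    out["eigen_ratio"] = es.eigen_ratio
    fit = cfa_mod.cfa_battery(R, n=n)
    out.update({"cfi": fit.CFI, "tli": fit.TLI, "rmsea": fit.RMSEA})
    net = network_mod.network_battery(R, n=n, gamma=gamma)
    out["edge_median"] = net.summaries["median"]
    out["edge_count"] = float(net.edge_count)
    return out


def tidy_results(result: ExperimentResult) -> pd.DataFrame:
    """Long table: one row per (condition, statistic)."""
    rows = []
    for cond in result.conditions:
        symbolic = isinstance(cond, str)
        for key in SCALAR_STATISTICS:
            rows.append(
                {
                    "condition": str(cond),
                    "proportion": np.nan if symbolic else float(cond),
                    "statistic": key,
                    "mean": result.means[cond][key],
                    "replicate_sd": 0.0 if symbolic else result.sds[cond][key],
                    "n_replicates": 1 if symbolic else result.valid_counts[cond][key],
                    "single_run": symbolic,
                }
            )
    return pd.DataFrame(rows)
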