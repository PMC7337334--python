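"""Reading and writing symptom tables, results and run provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from sympmix.synthetic import CaseLabels, SymptomMatrix

__all__ = [
    "read_symptom_table",
    "write_symptom_table",
    "write_tidy_csv",
    "write_results_json",
    "config_hash",
    "write_provenance",
]

logger = logging.getLogger("sympmix")


def read_symptom_table(
    path,
    case_column: Optional[str] = None,
    n_categories: int = 6,
    item_prefix: str = "item_",
) -> Tuple[SymptomMatrix, Optional[CaseLabels]]:
    """Load a wide ordinal symptom table.

    Item columns are those starting with ``item_prefix`` (all columns except
    the case column when none match).  Rows with any missing item value are
    dropped with a logged count — listwise deletion, no imputation.  Codes
    must be integers in ``0 .. n_categories - 1``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    item_cols = [c for c in df.columns if c.startswith(item_prefix)]
    if not item_cols:
        item_cols = [c for c in df.columns if c != case_column]
    items = df[item_cols]

    complete = items.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        frac = n_dropped / len(df)
        logger.info(
            "dropped %d of %d rows (%.1f%%) with missing item values",
            n_dropped,
            len(df),
            100 * frac,
        )
    items = items[complete]

    values = np.empty(items.shape, dtype=np.int64)
    for j, col in enumerate(item_cols):
        col_vals = items[col].to_numpy()
        as_float = np.asarray(col_vals, dtype=float)
        if np.any(as_float != np.round(as_float)):
            bad = int(np.flatnonzero(as_float != np.round(as_float))[0])
            raise ValueError(f"non-integer value in column {col!r}, row {bad}")
        values[:, j] = as_float.astype(np.int64)
        if values[:, j].min() < 0 or values[:, j].max() >= n_categories:
            raise ValueError(
                f"column {col!r} has codes outside 0..{n_categories - 1}"
            )
    data = SymptomMatrix(values, category_count=n_categories)

    labels = None
    if case_column is not None:
        if case_column not in df.columns:
            raise ValueError(f"case column {case_column!r} not found")
        aff = df.loc[complete, case_column].to_numpy()
        if set(np.unique(aff)) - {0, 1, True, False}:
            raise ValueError(f"case column {case_column!r} must be binary 0/1")
        labels = CaseLabels(affected=aff.astype(bool), cutoff=-1)
    return data, labels


def write_symptom_table(path, data: SymptomMatrix, labels: Optional[CaseLabels] = None) -> None:
    from sympmix.synthetic import write_csv

    write_csv(path, data, labels)


def write_tidy_csv(path, tidy: pd.DataFrame) -> None:
    """Tidy results at 4-decimal print precision."""
    out = tidy.copy()
    for col in ("mean", "replicate_sd"):
        out[col] = out[col].map(lambda x: f"{x:.4f}" if np.isfinite(x) else "")
    out.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results_json(path, result) -> None:
    """Full-precision JSON dump of an ExperimentResult."""
    payload = {
        "conditions": [str(c) for c in result.conditions],
        "means": _jsonable(result.means),
        "sds": _jsonable(result.sds),
        "valid_counts": _jsonable(result.valid_counts),
        "sample_sizes": _jsonable(result.sample_sizes),
        "n_replicates": result.n_replicates,
        "seed": result.seed,
        "config_hash": result.config_hash,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int) -> None:
    from sympmix import __version__

    record = {
        "config": _jsonable(config),
        "seed": seed,
        "version": __version__,
        "config_hash": config_hash(config),
    }
    Path(path).write_text(json.dumps(record, indent=2))
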