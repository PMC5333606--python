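"""Cohort ingestion and preprocessing.

Real clinical tables mix numeric labs, yes/no history flags and free text.
The network machinery needs numbers, so loading keeps numeric columns, maps
textual yes/no columns to 1/0, and drops everything else with a logged
manifest of what was discarded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import DEFAULT_LABEL, Cohort

logger = logging.getLogger(__name__)

_YES = {"yes", "y", "true", "1"}
_NO = {"no", "n", "false", "0"}


def _map_yes_no(col: pd.Series) -> pd.Series | None:
    """Map a textual yes/no column to 1/0; None if not mappable."""
    values = col.dropna().astype(str).str.strip().str.lower()
    if len(values) == 0:
        return None
    if set(values.unique()) <= (_YES | _NO):
        mapped = values.map(lambda v: 1.0 if v in _YES else 0.0)
        out = pd.Series(np.nan, index=col.index, dtype=float)
        out.loc[mapped.index] = mapped
        return out
    return None


def load_cohort(path, label_column: str = DEFAULT_LABEL) -> Cohort:
    """Load a subjects x features CSV, keeping only usable numeric features.

    Yes/no text columns become 1/0; other text columns are dropped (each is
    named in the log, not an error). The label column is coerced to {0, 1}.
    """
    frame = pd.read_csv(path)
    if "subject_id" in frame.columns:
        frame = frame.set_index("subject_id")
    if label_column not in frame.columns:
        raise KeyError(f"label column {label_column!r} missing from {path}")
    label = frame[label_column]
    if not np.issubdtype(label.dtype, np.number):
        mapped = _map_yes_no(label)
        if mapped is None:
            raise ValueError(f"label column {label_column!r} is not binary")
        label = mapped
    label = label.astype(float)
    if not set(label.dropna().unique()) <= {0.0, 1.0}:
        raise ValueError(f"label column {label_column!r} is not binary 0/1")
    kept: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for name in frame.columns:
        if name == label_column:
            continue
        col = frame[name]
        if np.issubdtype(col.dtype, np.number):
            kept[name] = col.astype(float)
            continue
        mapped = _map_yes_no(col)
        if mapped is not None:
            kept[name] = mapped
        else:
            dropped.append(name)
    if dropped:
        logger.warning("dropped %d non-numeric column(s): %s",
                       len(dropped), ", ".join(dropped))
    out = pd.DataFrame(kept, index=frame.index)
    out.insert(0, label_column, label.astype(int))
    return Cohort(out, label_column)


def select_balanced_subset(cohort: Cohort, n_total: int, seed: int) -> Cohort:
    """Seeded sample of ``n_total`` subjects, exactly half per class.

    Sampling is without replacement; a class with fewer than ``n_total / 2``
    subjects raises an error naming the shortfall.
    """
    if n_total % 2:
        raise ValueError("n_total must be even for a balanced subset")
    per_class = n_total // 2
    y = cohort.labels
    rng = np.random.default_rng(seed)
    chosen = []
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        if len(idx) < per_class:
            raise ValueError(
                f"class {cls} has {len(idx)} subjects, need {per_class} "
                f"(short by {per_class - len(idx)})")
        chosen.append(rng.choice(idx, size=per_class, replace=False))
    order = np.sort(np.concatenate(chosen))
    return Cohort(cohort.frame.iloc[order], cohort.label_column)
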