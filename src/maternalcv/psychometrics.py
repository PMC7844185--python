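"""Inclusion filtering, composite scoring, and reliability statistics.

The survey instruments are scored exactly as the study protocol
prescribes: the 27 mental-health items are averaged (range 1-5), the
14 resilience items summed (14-70), the 7 pandemic-life-stress items
summed (7-28), work stress is a single 1-10 item, the 13 binary
job-change indicators are counted (0-13), the 6 family-conflict items
summed (6-30) and the 20 father-involvement items averaged (1-5).
Missing items are never imputed: a missing item invalidates its
composite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import schema

__all__ = [
    "SCALES",
    "ScaleDefinition",
    "apply_inclusion_filter",
    "cronbach_alpha",
    "job_change_index",
    "pearson_correlation",
    "score_cohort",
    "score_scale",
    "subscale_correlation_matrix",
]

log = logging.getLogger(__name__)

SCORE_COLUMNS = tuple(schema.SCORE_RANGES)


@dataclass(frozen=True)
class ScaleDefinition:
    """How one composite is built from its item columns."""

    name: str
    item_columns: tuple[str, ...]
    aggregation: str  # mean | sum | count_of_positives | single_item
    valid_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.item_columns:
            raise ValueError(f"scale {self.name!r} has no item columns")
        if self.aggregation not in ("mean", "sum", "count_of_positives", "single_item"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


SCALES: dict[str, ScaleDefinition] = {
    "mental_health": ScaleDefinition("mental_health", schema.MH_ITEMS, "mean", (1, 5)),
    "resilience": ScaleDefinition("resilience", schema.RES_ITEMS, "sum", (1, 5)),
    "life_stress": ScaleDefinition("life_stress", schema.LIFE_STRESS_ITEMS, "sum", (1, 4)),
    "work_stress": ScaleDefinition("work_stress", (schema.WORK_STRESS_ITEM,), "single_item", (1, 10)),
    "job_change_index": ScaleDefinition("job_change_index", schema.JOB_CHANGE_ITEMS, "count_of_positives", (0, 1)),
    "family_conflict": ScaleDefinition("family_conflict", schema.CONFLICT_ITEMS, "sum", (1, 5)),
    "father_involvement": ScaleDefinition("father_involvement", schema.FI_ITEMS, "mean", (1, 5)),
}


class ValidationError(ValueError):
    """An item value outside its documented range."""


def _validate_items(table: pd.DataFrame, definition: ScaleDefinition) -> pd.DataFrame:
    missing = [c for c in definition.item_columns if c not in table.columns]
    if missing:
        raise KeyError(f"scale {definition.name!r}: missing item columns {missing}")
    items = table[list(definition.item_columns)]
    low, high = definition.valid_range
    bad = (items < low) | (items > high)
    if bad.to_numpy(na_value=False).any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValidationError(
            f"scale {definition.name!r}: value {table.at[row, col]!r} in "
            f"column {col!r}, row {row!r} outside [{low}, {high}]"
        )
    return items


def score_scale(table: pd.DataFrame, definition: ScaleDefinition) -> pd.Series:
    """Row-wise composite; a missing item yields a missing score (no
    imputation), raising no error but flagged via the returned NaN."""
    items = _validate_items(table, definition).astype(float)
    complete = items.notna().all(axis=1)
    if definition.aggregation == "mean":
        out = items.mean(axis=1)
    elif definition.aggregation in ("sum", "count_of_positives"):
        out = items.sum(axis=1)
    else:  # single_item
        out = items.iloc[:, 0]
    out = out.where(complete)
    n_missing = int((~complete).sum())
    if n_missing:
        log.warning("scale %s: %d rows with missing items -> missing score",
                    definition.name, n_missing)
    out.name = definition.name
    return out


def job_change_index(indicators) -> int:
    """Count of positive indicators among the 13 pandemic job-change items."""
    arr = np.asarray(indicators)
    if arr.shape != (13,):
        raise ValueError(f"expected 13 indicators, got shape {arr.shape}")
    if not np.isin(arr, (0, 1, False, True)).all():
        raise ValidationError(f"non-binary job-change indicator in {arr!r}")
    return int(arr.sum())


def score_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort table plus the seven derived composite columns."""
    scored = table.copy()
    for name, definition in SCALES.items():
        scored[name] = score_scale(table, definition)
    return scored


def apply_inclusion_filter(table: pd.DataFrame, report: bool = False):
    """Study inclusion rules: mothers, adult (18+), youngest child 1-10.

    Age is recorded in bands that all start at 18, so the adult rule
    removes only rows with an unrecognised band.  Returns the retained
    rows (and, with ``report=True``, a dict of removals per rule).
    """
    required = (schema.ROLE_COLUMN, "maternal_age", "age_youngest_child")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"inclusion filter: missing required columns {missing}")

    is_mother = table[schema.ROLE_COLUMN] == "mother"
    adult = table["maternal_age"].isin(schema.AGE_LEVELS)
    child_ok = table["age_youngest_child"].between(1, 10)

    counts = {
        "not_mother": int((~is_mother).sum()),
        "not_adult": int((is_mother & ~adult).sum()),
        "child_age_out_of_range": int((is_mother & adult & ~child_ok).sum()),
    }
    kept = table[is_mother & adult & child_ok]
    log.info("inclusion filter: kept %d of %d rows (removed %s)",
             len(kept), len(table), counts)
    if report:
        return kept, counts
    return kept


def cronbach_alpha(items) -> float:
    """Internal-consistency reliability of a multi-item scale.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(row sums))``
    with unbiased (n-1) variances throughout.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("items must be an n x k matrix with k >= 2")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(arr).any():
        raise ValueError("missing values not allowed in reliability input")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1).sum()
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ZeroDivisionError("total score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def subscale_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the four symptom-subscale means."""
    means = {}
    for name, cols in schema.MH_SUBSCALES.items():
        _validate_items(table, ScaleDefinition(name, cols, "mean", (1, 5)))
        means[name] = table[list(cols)].mean(axis=1)
    frame = pd.DataFrame(means)
    if (frame.std(ddof=1) == 0).any():
        # all-identical degenerate input: correlations forced to 1
        n_sub = frame.shape[1]
        if frame.nunique().eq(1).all() and frame.iloc[0].nunique() == 1:
            return pd.DataFrame(np.ones((n_sub, n_sub)),
                                index=frame.columns, columns=frame.columns)
        raise ZeroDivisionError("a subscale score is constant; correlation undefined")
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
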