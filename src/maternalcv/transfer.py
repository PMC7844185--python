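"""Cross-country transfer validation of selected models.

Each country's best-performing model (a factor subset, not its fitted
coefficients) is re-evaluated by repeated k-fold cross-validation on
every country's data, coefficients re-estimated on the target training
folds.  The resulting RMSEp distributions show how well one country's
model specification travels: with three cohorts this yields nine
(source model x target data) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model_search import (
    CVConfig,
    FactorCatalog,
    ModelSpec,
    _sweep,
    build_design_matrix,
    make_fold_partition,
    model_column_indices,
)

__all__ = [
    "TransferResult",
    "cross_fit",
    "distribution_overlap",
    "pairwise_overlap",
    "summarize_transfer",
]


@dataclass
class TransferResult:
    """Long-format per-repeat RMSEp for every (source, target) pair."""

    table: pd.DataFrame  # columns: source, target, repeat, rmse

    def vector(self, source: str, target: str) -> np.ndarray:
        sel = self.table[(self.table.source == source) & (self.table.target == target)]
        return sel.sort_values("repeat")["rmse"].to_numpy()

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted({(s, t) for s, t in zip(self.table.source, self.table.target)})


def cross_fit(
    best_models: Mapping[str, ModelSpec],
    cohorts: Mapping[str, pd.DataFrame],
    catalog: FactorCatalog,
    cv: CVConfig,
    outcome: str = "mental_health",
) -> TransferResult:
    """Repeated-CV RMSEp of each source model on each target cohort.

    The same repeat seeds drive the partitions for all sources on a
    given target, so differences between distributions reflect the model
    specification and the data, never the partitioning.  The factor
    definitions must be shared across countries (one catalog).
    """
    for country, model in best_models.items():
        missing = [f for f in model.factors if f not in catalog.names]
        if missing:
            raise KeyError(
                f"model for {country!r} uses factors absent from the "
                f"shared catalog: {missing}"
            )
    records = []
    for target, scored in cohorts.items():
        X, blocks, _ = build_design_matrix(scored, catalog)
        y = scored[outcome].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"outcome for target {target!r} has missing values")
        sources = list(best_models)
        cols = [model_column_indices(best_models[s], blocks) for s in sources]
        for r in range(cv.repeats):
            rng = np.random.default_rng(np.random.SeedSequence([cv.seed, r]))
            fold_ids = make_fold_partition(len(y), cv.folds, rng)
            rmse = _sweep(X, y, fold_ids, cv.folds, cols, cv.engine,
                          cv.train_on_one)
            for s, value in zip(sources, rmse):
                records.append((s, target, r, float(value)))
    table = pd.DataFrame(records, columns=["source", "target", "repeat", "rmse"])
    return TransferResult(table)


def summarize_transfer(result: TransferResult) -> pd.DataFrame:
    """Five-number summary (plus mean) per (source, target) pair."""
    grouped = result.table.groupby(["source", "target"])["rmse"]
    summary = grouped.agg(
        n="size",
        mean="mean",
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max",
    ).reset_index()
    return summary


def distribution_overlap(x, y, bins: int = 40) -> float:
    """Proportion of overlap between two empirical distributions.

    Histogram both samples on a shared grid and integrate the pointwise
    minimum of the two densities; 1 means identical, 0 disjoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:  # all mass at a single point
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    fx, _ = np.histogram(x, bins=edges, density=True)
    fy, _ = np.histogram(y, bins=edges, density=True)
    width = edges[1] - edges[0]
    return float(np.minimum(fx, fy).sum() * width)


def pairwise_overlap(result: TransferResult, bins: int = 40) -> pd.DataFrame:
    """Overlap statistic between every two (source, target) RMSE vectors."""
    pairs = result.pairs
    labels = [f"{s}->{t}" for s, t in pairs]
    vectors = [result.vector(s, t) for s, t in pairs]
    n = len(pairs)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = distribution_overlap(vectors[i], vectors[j], bins)
    return pd.DataFrame(out, index=labels, columns=labels)
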