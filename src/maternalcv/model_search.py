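"""Exhaustive all-subsets regression search under repeated k-fold CV.

Every subset of the candidate-factor catalog (2^p models, intercept
always included, categorical factors entering as whole dummy blocks) is
scored by the root mean square error of prediction (RMSEp): within each
repeat a single fold partition is shared by all models, each model is
fit by OLS on the training folds and evaluated on the held-out fold,
and the model with the smallest RMSEp wins that repeat.  Winner tallies
across repeats express selection stability.

Two interchangeable engines compute the same RMSEp:

``naive``
    refits each model on each training split with ``numpy.linalg.lstsq``;
``gram``
    precomputes the full cross-product matrix once per partition and
    subtracts each fold's contribution, so a model/fold fit is a small
    linear solve regardless of n.  This is what makes the full
    2^15-model sweep tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "CVConfig",
    "Factor",
    "FactorCatalog",
    "ModelSpec",
    "SearchResult",
    "build_design_matrix",
    "cv_rmse",
    "default_catalog",
    "enumerate_models",
    "make_fold_partition",
    "run_search",
    "top_models_table",
]


@dataclass(frozen=True)
class Factor:
    """One candidate risk/protective factor.

    ``kind`` is ``continuous`` (single numeric column), ``binary``
    (single 0/1 column) or ``categorical`` (reference-coded dummy block).
    ``column`` names the cohort column; defaults to ``name``.
    """

    name: str
    kind: str
    levels: tuple = ()
    reference: object = None
    column: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical factor {self.name!r} needs >= 2 levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(f"reference {ref!r} not a level of {self.name!r}")

    @property
    def source_column(self) -> str:
        return self.column or self.name

    @property
    def ref_level(self):
        return self.reference if self.reference is not None else (
            self.levels[0] if self.levels else None
        )

    @property
    def n_design_columns(self) -> int:
        return len(self.levels) - 1 if self.kind == "categorical" else 1


@dataclass(frozen=True)
class FactorCatalog:
    """Ordered catalog of candidate factors; order fixes the bit-mask
    convention used throughout (bit i = factor i)."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names in catalog")

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def mask_for(self, factor_names) -> int:
        mask = 0
        for name in factor_names:
            mask |= 1 << self.names.index(name)
        return mask


def default_catalog(subset=None) -> FactorCatalog:
    """The study's 15 candidate factors (7 score-derived, 8 demographic).

    ``subset`` restricts to the named factors, preserving catalog order.
    """
    factors = (
        Factor("maternal_age", "categorical", schema.AGE_LEVELS, "18-30"),
        Factor("marital_status", "categorical", schema.MARITAL_LEVELS, "married"),
        Factor("education", "categorical", schema.EDUCATION_LEVELS, "college_or_below"),
        Factor("employment", "categorical", schema.EMPLOYMENT_LEVELS, "employed"),
        Factor("physical_health", "categorical", schema.HEALTH_LEVELS, "poor"),
        Factor("household_income", "continuous"),
        Factor("n_children", "continuous"),
        Factor("age_youngest_child", "continuous"),
        Factor("grandparental_support", "binary"),
        Factor("resilience", "continuous"),
        Factor("life_stress", "continuous"),
        Factor("work_stress", "continuous"),
        Factor("job_change_index", "continuous"),
        Factor("family_conflict", "continuous"),
        Factor("father_involvement", "continuous"),
    )
    if subset is not None:
        subset = tuple(subset)
        unknown = set(subset) - {f.name for f in factors}
        if unknown:
            raise KeyError(f"unknown factors {sorted(unknown)}")
        factors = tuple(f for f in factors if f.name in subset)
    return FactorCatalog(factors)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: an inclusion mask over the catalog."""

    mask: int
    factors: tuple[str, ...]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def formula(self, outcome: str = "mental_health") -> str:
        rhs = " + ".join(("1",) + self.factors)
        return f"{outcome} ~ {rhs}"


def enumerate_models(catalog: FactorCatalog) -> list[ModelSpec]:
    """All 2^p factor subsets in canonical (mask-ascending) order,
    starting with the intercept-only model."""
    names = catalog.names
    p = len(names)
    models = []
    for mask in range(1 << p):
        chosen = tuple(names[i] for i in range(p) if mask >> i & 1)
        models.append(ModelSpec(mask, chosen))
    return models


@dataclass
class CVConfig:
    """Repeated k-fold cross-validation settings.

    ``train_on_one`` inverts the orientation (fit on one fold, predict
    the other k-1); the standard orientation is the default.
    """

    folds: int = 10
    repeats: int = 200
    seed: int = 0
    engine: str = "gram"
    train_on_one: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.engine not in ("gram", "naive"):
            raise ValueError(f"unknown engine {self.engine!r}")


# --------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------

def build_design_matrix(scored: pd.DataFrame, catalog: FactorCatalog):
    """Design matrix with intercept column 0 and reference-coded dummies.

    Returns ``(X, blocks, column_names)`` where ``blocks`` maps each
    factor name to its design-column indices.
    """
    n = len(scored)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    blocks: dict[str, np.ndarray] = {}
    for factor in catalog.factors:
        col = factor.source_column
        if col not in scored.columns:
            raise KeyError(f"factor column {col!r} not in cohort")
        vals = scored[col]
        start = len(columns)
        if factor.kind == "categorical":
            observed = set(vals.dropna().unique())
            unknown = observed - set(factor.levels)
            if unknown:
                raise ValueError(
                    f"unseen level(s) {sorted(map(str, unknown))} for factor {factor.name!r}"
                )
            for level in factor.levels:
                if level == factor.ref_level:
                    continue
                columns.append((vals == level).to_numpy(dtype=float))
                names.append(f"{factor.name}:{level}")
        elif factor.kind == "binary":
            arr = vals.to_numpy(dtype=float)
            if not np.isin(arr[~np.isnan(arr)], (0.0, 1.0)).all():
                raise ValueError(f"binary factor {factor.name!r} has non-0/1 values")
            columns.append(arr)
            names.append(factor.name)
        else:
            columns.append(vals.to_numpy(dtype=float))
            names.append(factor.name)
        blocks[factor.name] = np.arange(start, len(columns))
    X = np.column_stack(columns)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; "
                         "score and filter the cohort first")
    return X, blocks, names


def model_column_indices(model: ModelSpec, blocks: dict) -> np.ndarray:
    idx = [np.array([0])] + [blocks[name] for name in model.factors]
    return np.concatenate(idx)


# --------------------------------------------------------------------
# folds and sweeps
# --------------------------------------------------------------------

def make_fold_partition(n: int, k: int, seed) -> np.ndarray:
    """Random fold labels 0..k-1; sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split n={n} rows into k={k} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    fold[rng.permutation(n)] = np.arange(n) % k
    return fold


def _solve_gram(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        # rank-deficient training block: minimum-norm least squares
        return np.linalg.lstsq(G, b, rcond=None)[0]


def _sweep_gram(X, y, fold_ids, k, model_cols, train_on_one=False):
    """RMSEp for every model under one partition via Gram subtraction."""
    G = X.T @ X
    by = X.T @ y
    fold_rows = [np.flatnonzero(fold_ids == f) for f in range(k)]
    Gf, bf, Xf, yf = [], [], [], []
    for rows in fold_rows:
        if rows.size == 0:
            raise ValueError("degenerate fold: a training or test fold is empty")
        Xi = X[rows]
        Gf.append(Xi.T @ Xi)
        bf.append(Xi.T @ y[rows])
        Xf.append(Xi)
        yf.append(y[rows])
    n_held = (k - 1) * len(y) if train_on_one else len(y)
    rmse = np.empty(len(model_cols))
    for m, cols in enumerate(model_cols):
        ix = np.ix_(cols, cols)
        sse = 0.0
        for f in range(k):
            if train_on_one:
                Gt, bt = Gf[f][ix], bf[f][cols]
                beta = _solve_gram(Gt, bt)
                # held-out error over the complement of fold f
                resid_all = y - X[:, cols] @ beta
                resid_f = yf[f] - Xf[f][:, cols] @ beta
                sse += resid_all @ resid_all - resid_f @ resid_f
            else:
                Gt = G[ix] - Gf[f][ix]
                bt = by[cols] - bf[f][cols]
                beta = _solve_gram(Gt, bt)
                resid = yf[f] - Xf[f][:, cols] @ beta
                sse += resid @ resid
        rmse[m] = np.sqrt(max(sse, 0.0) / n_held)
    return rmse


def _sweep_naive(X, y, fold_ids, k, model_cols, train_on_one=False):
    """Reference path: refit every model on every training split."""
    n = len(y)
    n_held = (k - 1) * n if train_on_one else n
    rmse = np.empty(len(model_cols))
    for m, cols in enumerate(model_cols):
        Xm = X[:, cols]
        sse = 0.0
        for f in range(k):
            in_fold = fold_ids == f
            train = in_fold if train_on_one else ~in_fold
            test = ~train
            if train.sum() < 1:
                raise ValueError("degenerate fold: empty training set")
            beta = np.linalg.lstsq(Xm[train], y[train], rcond=None)[0]
            resid = y[test] - Xm[test] @ beta
            sse += resid @ resid
        rmse[m] = np.sqrt(sse / n_held)
    return rmse


def _sweep(X, y, fold_ids, k, model_cols, engine, train_on_one=False):
    fn = _sweep_gram if engine == "gram" else _sweep_naive
    return fn(X, y, fold_ids, k, model_cols, train_on_one)


def cv_rmse(y, X, model_cols, partition, engine: str = "naive",
            train_on_one: bool = False) -> float:
    """RMSEp of a single model under one explicit fold partition.

    ``model_cols`` are design-column indices (include 0 for the
    intercept); ``partition`` assigns each row a fold label.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    partition = np.asarray(partition)
    if partition.shape[0] != len(y):
        raise ValueError("partition must cover every row")
    k = int(partition.max()) + 1
    cols = np.asarray(model_cols, dtype=np.int64)
    return float(_sweep(X, y, partition, k, [cols], engine, train_on_one)[0])


# --------------------------------------------------------------------
# search
# --------------------------------------------------------------------

@dataclass
class SearchResult:
    """Outcome of an all-subsets repeated-CV search."""

    models: list[ModelSpec]
    mean_rmse: np.ndarray          # per model, averaged over repeats
    win_counts: np.ndarray         # per model
    winners: np.ndarray            # winning model index per repeat
    repeats: int
    outcome: str = "mental_health"
    rmse_matrix: np.ndarray | None = None  # repeats x models, optional

    @property
    def win_pct(self) -> np.ndarray:
        return 100.0 * self.win_counts / self.repeats

    def best_model(self) -> ModelSpec:
        order = np.lexsort((self.mean_rmse, -self.win_counts))
        return self.models[order[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mask": [m.mask for m in self.models],
            "n_factors": [m.n_factors for m in self.models],
            "formula": [m.formula(self.outcome) for m in self.models],
            "mean_rmse": self.mean_rmse,
            "win_count": self.win_counts,
            "win_pct": self.win_pct,
        })


def _pick_winner(rmse, n_factors, rtol=1e-9, atol=1e-12):
    """Index of the repeat winner: minimum RMSEp, ties (within floating
    tolerance) broken by fewest factors, then canonical order."""
    best = rmse.min()
    tied = np.flatnonzero(rmse <= best + atol + rtol * best)
    return int(tied[np.argmin(n_factors[tied])])


def run_search(scored: pd.DataFrame, catalog: FactorCatalog, cv: CVConfig,
               outcome: str = "mental_health", models=None,
               keep_rmse_matrix: bool = False) -> SearchResult:
    """Evaluate every factor subset by repeated k-fold CV.

    Within a repeat all models share one fold partition, so the
    per-repeat winner is a fair comparison; partitions are drawn from
    ``(cv.seed, repeat)`` and are independent of the model set.
    """
    if outcome not in scored.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    X, blocks, _ = build_design_matrix(scored, catalog)
    y = scored[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    if models is None:
        models = enumerate_models(catalog)
    model_cols = [model_column_indices(m, blocks) for m in models]
    n_factors = np.array([m.n_factors for m in models])

    n = len(y)
    mean_rmse = np.zeros(len(models))
    win_counts = np.zeros(len(models), dtype=np.int64)
    winners = np.empty(cv.repeats, dtype=np.int64)
    matrix = np.empty((cv.repeats, len(models))) if keep_rmse_matrix else None
    for r in range(cv.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cv.seed, r]))
        fold_ids = make_fold_partition(n, cv.folds, rng)
        rmse = _sweep(X, y, fold_ids, cv.folds, model_cols, cv.engine,
                      cv.train_on_one)
        w = _pick_winner(rmse, n_factors)
        winners[r] = w
        win_counts[w] += 1
        mean_rmse += rmse
        if matrix is not None:
            matrix[r] = rmse
    mean_rmse /= cv.repeats
    return SearchResult(list(models), mean_rmse, win_counts, winners,
                        cv.repeats, outcome, matrix)


def top_models_table(result: SearchResult, k: int = 3) -> pd.DataFrame:
    """Top-k models by winner percentage, then mean RMSEp."""
    frame = result.to_frame()
    if k > len(frame):
        warnings.warn(f"requested top {k} of {len(frame)} models; truncating")
        k = len(frame)
    frame = frame.sort_values(
        ["win_pct", "mean_rmse", "n_factors", "mask"],
        ascending=[False, True, True, True],
    ).head(k)
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return frame.reset_index(drop=True)
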