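"""Robust standardized refits, descriptive comparisons, and moderation.

The winning model of each country's search is refit on the full cohort
as a standardized OLS regression with heteroskedasticity-consistent
(HC3 sandwich) standard errors and normal-reference Wald tests; the
model-level adjusted R-squared comes from the plain OLS fit.  Outcome
and continuous predictors are scaled to mean 0 / sd 1 (n-1 denominator);
dummy columns stay 0/1, so their coefficients are standardized mean
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import schema
from .model_search import FactorCatalog, ModelSpec, build_design_matrix

__all__ = [
    "FitSummary",
    "ModerationResult",
    "export_coefficients",
    "fit_winning_model",
    "group_comparison_table",
    "moderation_analysis",
    "robust_fit",
    "standardize",
]


@dataclass
class FitSummary:
    """Per-term standardized coefficients with sandwich inference."""

    table: pd.DataFrame  # index: term; columns: beta, se, z, p
    adj_r2: float
    n: int
    outcome: str = "mental_health"

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


@dataclass
class StandardizationParams:
    means: dict[str, float]
    sds: dict[str, float]


def standardize(frame: pd.DataFrame, columns: Sequence[str]):
    """Scale the named columns to mean 0, sd 1 (unbiased denominator).

    Returns the transformed copy and the transformation parameters for
    reuse on new data.  Constant columns cannot be standardized.
    """
    out = frame.copy()
    means, sds = {}, {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if sd == 0.0:
            raise ZeroDivisionError(
                f"cannot standardize constant column {col!r}"
            )
        out[col] = (vals - mu) / sd
        means[col], sds[col] = mu, sd
    return out, StandardizationParams(means, sds)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR localises the dependent columns
        from scipy.linalg import qr

        _, R, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


def robust_fit(y, X: pd.DataFrame, cov_type: str = "HC3",
               outcome: str = "mental_health") -> FitSummary:
    """OLS point estimates with sandwich standard errors.

    ``X`` must include a column named ``intercept`` or ``const``;
    adjusted R-squared is taken from the classical OLS fit (identical
    point estimates).
    """
    y = np.asarray(y, dtype=float)
    _check_full_rank(X)
    ols = sm.OLS(y, X).fit()
    robust = sm.OLS(y, X).fit(cov_type=cov_type, use_t=False)
    table = pd.DataFrame({
        "beta": robust.params,
        "se": robust.bse,
        "z": robust.tvalues,
        "p": robust.pvalues,
    })
    return FitSummary(table, float(ols.rsquared_adj), int(len(y)), outcome)


def _standardized_design(scored: pd.DataFrame, catalog: FactorCatalog,
                         factors: Sequence[str], outcome: str):
    sub = FactorCatalog(tuple(catalog[name] for name in factors))
    X, blocks, names = build_design_matrix(scored, sub)
    frame = pd.DataFrame(X, columns=names, index=scored.index)
    continuous = [
        f.name for f in sub.factors if f.kind == "continuous"
    ]
    frame, params = standardize(frame, continuous) if continuous else (frame, StandardizationParams({}, {}))
    y = scored[outcome].to_numpy(dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("outcome is constant; cannot standardize")
    y_std = (y - y.mean()) / sd
    return y_std, frame, params


def fit_winning_model(scored: pd.DataFrame, model: ModelSpec | Sequence[str],
                      catalog: FactorCatalog, outcome: str = "mental_health",
                      cov_type: str = "HC3") -> FitSummary:
    """Standardized robust refit of a selected model on a full cohort."""
    factors = model.factors if isinstance(model, ModelSpec) else tuple(model)
    y_std, X, _ = _standardized_design(scored, catalog, factors, outcome)
    return robust_fit(y_std, X, cov_type=cov_type, outcome=outcome)


@dataclass
class ModerationResult:
    """Interaction fit plus simple slopes of the focal stressors."""

    fit: FitSummary
    interactions: pd.DataFrame   # term, beta, se, z, p
    simple_slopes: pd.DataFrame  # focal, moderator level (-1/0/+1 sd), slope

    def interaction_term(self, focal: str) -> str:
        return [t for t in self.interactions.index if t.endswith(f"x{focal}")][0]


def moderation_analysis(
    scored: pd.DataFrame,
    catalog: FactorCatalog,
    base_model: ModelSpec | Sequence[str],
    moderator: str = "resilience",
    focal_terms: Sequence[str] = ("life_stress", "work_stress", "maternal_age"),
    outcome: str = "mental_health",
    cov_type: str = "HC3",
) -> ModerationResult:
    """Augment a base model with moderator-by-focal product terms.

    Continuous terms are standardized first, so products are centered
    and the focal main effect equals the simple slope at the moderator
    mean; slopes at one sd below/above follow from
    ``beta_focal -/+ beta_interaction``.
    """
    factors = list(base_model.factors if isinstance(base_model, ModelSpec)
                   else base_model)
    for name in (moderator, *focal_terms):
        if name not in catalog.names:
            raise KeyError(f"term {name!r} not in catalog")
        if name not in factors:
            factors.append(name)
    y_std, X, _ = _standardized_design(scored, catalog, factors, outcome)

    inter_names = []
    for focal in focal_terms:
        fac = catalog[focal]
        focal_cols = ([focal] if fac.kind != "categorical" else
                      [f"{focal}:{lv}" for lv in fac.levels if lv != fac.ref_level])
        for col in focal_cols:
            name = f"{moderator}x{col.split(':', 1)[-1] if ':' in col else col}"
            X[name] = X[moderator] * X[col]
            inter_names.append(name)

    fit = robust_fit(y_std, X, cov_type=cov_type, outcome=outcome)
    interactions = fit.table.loc[inter_names]

    rows = []
    for focal in focal_terms:
        if catalog[focal].kind == "categorical":
            continue
        b_main = fit.table.at[focal, "beta"]
        b_int = fit.table.at[f"{moderator}x{focal}", "beta"]
        for level, mult in (("-1sd", -1.0), ("mean", 0.0), ("+1sd", 1.0)):
            rows.append((focal, level, b_main + mult * b_int))
    slopes = pd.DataFrame(rows, columns=["focal", "moderator_at", "slope"])
    return ModerationResult(fit, interactions, slopes)


# --------------------------------------------------------------------
# descriptive comparisons (ANOVA / chi-square across countries)
# --------------------------------------------------------------------

_DEFAULT_CONTINUOUS = tuple(schema.SCORE_RANGES)
_DEFAULT_CATEGORICAL = (
    "maternal_age", "marital_status", "education", "employment",
    "physical_health", "grandparental_support", "n_children",
)


def group_comparison_table(
    cohorts: Mapping[str, pd.DataFrame],
    continuous: Sequence[str] = _DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = _DEFAULT_CATEGORICAL,
) -> pd.DataFrame:
    """Descriptives with one-way ANOVA (continuous) and Pearson
    chi-square (categorical, no continuity correction) across groups."""
    if len(cohorts) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    groups = list(cohorts)
    for var in continuous:
        samples = [cohorts[g][var].dropna().to_numpy(dtype=float) for g in groups]
        desc = {f"{g}": f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
                for g, s in zip(groups, samples)}
        if all(np.ptp(s) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
            stat, p = 0.0, float("nan")
        else:
            try:
                stat, p = stats.f_oneway(*samples)
            except ValueError:
                stat, p = float("nan"), float("nan")
        rows.append({"variable": var, "type": "continuous",
                     **desc, "statistic": float(stat), "p": float(p)})
    for var in categorical:
        counts = pd.DataFrame({
            g: cohorts[g][var].value_counts() for g in groups
        }).fillna(0).astype(int)
        desc = {}
        for g in groups:
            total = counts[g].sum()
            desc[g] = "; ".join(
                f"{lv}: {c} ({100 * c / total:.1f}%)"
                for lv, c in counts[g].items()
            )
        observed = counts.to_numpy().T
        observed = observed[:, observed.sum(axis=0) > 0]
        if observed.shape[1] < 2:
            stat, p = float("nan"), float("nan")  # constant in all groups
        else:
            stat, p, _, _ = stats.chi2_contingency(observed, correction=False)
        rows.append({"variable": var, "type": "categorical",
                     **desc, "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


def export_coefficients(
    fits: Mapping[str, FitSummary],
    models: Mapping[str, ModelSpec],
    catalog: FactorCatalog,
) -> pd.DataFrame:
    """Long-format coefficient export for cross-country display.

    Every catalog term appears for every country; terms belonging to
    factors not selected by that country's model are written as exact
    zeros with ``selected = False``.
    """
    rows = []
    for country, fit in fits.items():
        selected = set(models[country].factors)
        for factor in catalog.factors:
            if factor.kind == "categorical":
                terms = [f"{factor.name}:{lv}" for lv in factor.levels
                         if lv != factor.ref_level]
            else:
                terms = [factor.name]
            for term in terms:
                if factor.name in selected and term in fit.table.index:
                    beta = float(fit.table.at[term, "beta"])
                    rows.append((country, factor.name, term, beta, True))
                else:
                    rows.append((country, factor.name, term, 0.0, False))
    return pd.DataFrame(
        rows, columns=["country", "factor", "term", "beta", "selected"]
    )
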