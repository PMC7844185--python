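"""Seeded generator of multi-country survey cohorts.

The generator emulates the statistical structure a three-country online
survey of mothers during a pandemic lockdown would produce:

* item-level Likert responses whose internal consistency (Cronbach's
  alpha) matches configured targets, via a compound-symmetric latent
  Gaussian threshold model;
* a 27-item mental-health scale organised in four correlated symptom
  subscales (somatization, depression, anxiety, post-traumatic stress)
  that share one general factor;
* 13 binary job-change indicators whose count index correlates with a
  single 10-point work-stress item at a configured level;
* country-specific demographic marginals (e.g. grandparental child-care
  support far more prevalent in China than in the Netherlands); and
* a linear latent outcome with configurable standardized effects and
  interaction (moderation) terms.

All randomness flows from a single integer seed expanded into named
substreams, so adding a scale does not perturb the others and identical
configurations yield byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import schema

__all__ = [
    "GeneratorConfig",
    "calibrate_item_correlation",
    "calibrate_job_change_structure",
    "country_preset",
    "discretization_attenuation",
    "generate_cohort",
    "generate_items_from_trait",
    "generate_mental_health_items",
    "selection_scenario",
]

# Order matters: substream k of a seed is always the k-th name here, so
# appending new streams never perturbs existing ones.
_STREAMS = (
    "demographics",
    "resilience",
    "life_stress",
    "work_job",
    "family_conflict",
    "father_involvement",
    "noise",
    "mental_health",
)

#: published reliability targets per scale (item count in parentheses)
DEFAULT_ALPHAS = {
    "mental_health": 0.96,      # 27 items
    "father_involvement": 0.89,  # 20 items
    "job_change": 0.83,          # 13 binary indicators
    "life_stress": 0.82,         # 7 items
    "resilience": 0.85,          # 14 items
    "family_conflict": 0.85,     # 6 items
}

DEFAULT_JOB_CHANGE_PREVALENCE = 0.30
DEFAULT_JOB_CHANGE_WORK_R = 0.35
DEFAULT_SUBSCALE_LOADING = 0.98

_PRESET_N = {"CN": 922, "IT": 641, "NL": 900}
_GRANDPARENT_PREV = {"CN": 0.536, "IT": 0.183, "NL": 0.094}


# --------------------------------------------------------------------
# reliability calibration
# --------------------------------------------------------------------

def calibrate_item_correlation(alpha_target: float, k_items: int) -> float:
    """Invert the standardized-alpha identity for a compound-symmetric scale.

    For ``k`` exchangeable items with common inter-item correlation
    ``rho``, standardized alpha is ``k*rho / (1 + (k-1)*rho)``.  This
    returns the ``rho`` attaining ``alpha_target``.
    """
    if not 0.0 <= alpha_target < 1.0:
        raise ValueError(f"alpha_target must be in [0, 1), got {alpha_target}")
    if k_items < 2:
        raise ValueError(f"k_items must be >= 2, got {k_items}")
    return alpha_target / (k_items - alpha_target * (k_items - 1))


@lru_cache(maxsize=None)
def _inner_edges(levels: int) -> tuple[float, ...]:
    """Standard-normal cut points giving `levels` equal-probability bins."""
    return tuple(stats.norm.ppf(np.arange(1, levels) / levels))


@lru_cache(maxsize=None)
def discretization_attenuation(levels: int) -> float:
    """Correlation between a standard normal and its equal-probability
    discretization into ``levels`` ordered categories.

    Squaring this gives the (first-order) attenuation of a latent
    pairwise correlation once both variables are discretized; the
    generator divides target correlations by it so the *observed* item
    correlations, and hence alpha, match their targets.
    """
    edges = np.array([-np.inf, *_inner_edges(levels), np.inf])
    pdf = np.where(np.isfinite(edges), stats.norm.pdf(edges), 0.0)
    values = np.arange(1, levels + 1)
    cov = float(np.sum(values * (pdf[:-1] - pdf[1:])))
    var_d = (levels**2 - 1) / 12.0
    return cov / math.sqrt(var_d)


def _latent_rho(rho_target: float, levels: int) -> float:
    lam2 = discretization_attenuation(levels) ** 2
    return min(rho_target / lam2, 0.999)


def _discretize(z: np.ndarray, levels: int, low: int = 1) -> np.ndarray:
    edges = np.asarray(_inner_edges(levels))
    return (low + np.searchsorted(edges, z)).astype(np.int64)


def generate_items_from_trait(
    latent,
    k_items: int,
    rho: float,
    levels: tuple[int, int] = (1, 5),
    rng=0,
    compensate_discretization: bool = True,
) -> np.ndarray:
    """Draw ``k_items`` ordinal items sharing a latent trait.

    Each item is a thresholded Gaussian ``sqrt(rho')*t + sqrt(1-rho')*e``
    cut at equal-probability standard-normal quantiles.  With
    ``compensate_discretization`` the latent correlation is inflated so
    the discretized items attain the *target* pairwise correlation
    ``rho`` (and therefore the alpha it was calibrated from).

    The trait should be on an (approximately) standard-normal scale.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 1 or latent.size == 0:
        raise ValueError("latent must be a non-empty 1-d vector")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    low, high = levels
    n_levels = high - low + 1
    if n_levels < 2:
        raise ValueError("levels must span at least two categories")
    r = _latent_rho(rho, n_levels) if compensate_discretization else rho
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eps = rng.standard_normal((latent.size, k_items))
    z = math.sqrt(r) * latent[:, None] + math.sqrt(1.0 - r) * eps
    return _discretize(z, n_levels, low)


# --------------------------------------------------------------------
# 27-item mental-health scale: general factor + four subscale factors
# --------------------------------------------------------------------

def _mh_within_rho(alpha_target: float, loading: float) -> float:
    """Within-subscale item correlation making full-scale alpha hit target.

    With loading ``g`` of every subscale factor on the general factor,
    between-subscale item correlations are ``g**2`` times the
    within-subscale correlation; the mean inter-item correlation then
    determines standardized alpha of the 27-item composite.
    """
    sizes = schema.MH_SUBSCALE_SIZES
    k = sum(sizes)
    rbar = calibrate_item_correlation(alpha_target, k)
    within_pairs = sum(s * (s - 1) // 2 for s in sizes)
    total_pairs = k * (k - 1) // 2
    between_pairs = total_pairs - within_pairs
    rho_w = rbar * total_pairs / (within_pairs + between_pairs * loading**2)
    if rho_w >= 1.0:
        raise ValueError("alpha target unattainable at this subscale loading")
    return rho_w


def generate_mental_health_items(
    general,
    loading: float = DEFAULT_SUBSCALE_LOADING,
    alpha_target: float = DEFAULT_ALPHAS["mental_health"],
    rng=0,
) -> np.ndarray:
    """27 symptom items (1-5) driven by one general-psychopathology factor.

    Four subscale factors (6+5+6+10 items) each load ``loading`` on the
    general factor; items load compound-symmetrically on their subscale
    factor.  Discretization attenuation is compensated as in
    :func:`generate_items_from_trait`.
    """
    general = np.asarray(general, dtype=float)
    if general.ndim != 1 or general.size == 0:
        raise ValueError("general must be a non-empty 1-d vector")
    if not 0.0 < loading <= 1.0:
        raise ValueError(f"loading must be in (0, 1], got {loading}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rho_w = _latent_rho(_mh_within_rho(alpha_target, loading), 5)
    n = general.size
    blocks = []
    for size in schema.MH_SUBSCALE_SIZES:
        sub = loading * general + math.sqrt(1.0 - loading**2) * rng.standard_normal(n)
        eps = rng.standard_normal((n, size))
        z = math.sqrt(rho_w) * sub[:, None] + math.sqrt(1.0 - rho_w) * eps
        blocks.append(_discretize(z, 5, 1))
    return np.concatenate(blocks, axis=1)


# --------------------------------------------------------------------
# job-change indicators vs. work-stress item
# --------------------------------------------------------------------

def _bvn_upper(c: float, rho: float) -> float:
    """P(Z1 > c, Z2 > c) for standard bivariate normal with corr rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(mvn.cdf([-c, -c]))


def _bvn_lower_upper(u: float, c: float, rho: float) -> float:
    """P(Z1 < u, Z2 > c) for standard bivariate normal with corr rho."""
    if not np.isfinite(u):
        return float(stats.norm.sf(c)) if u > 0 else 0.0
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(stats.norm.cdf(u) - mvn.cdf([u, c]))


@lru_cache(maxsize=None)
def calibrate_job_change_structure(
    alpha_target: float = DEFAULT_ALPHAS["job_change"],
    r_target: float = DEFAULT_JOB_CHANGE_WORK_R,
    k: int = 13,
    prevalence: float = DEFAULT_JOB_CHANGE_PREVALENCE,
    work_levels: int = 10,
) -> tuple[float, float]:
    """Solve the two-parameter latent structure of the job-change block.

    Indicator ``j`` fires when ``a*w + b*u + sqrt(1-tau)*e_j > c`` with
    ``tau = a**2 + b**2``; ``w`` is the work-stress latent, ``u`` a
    job-change-specific factor.  ``tau`` is chosen so the Pearson (phi)
    inter-indicator correlation reproduces ``alpha_target``; ``a`` so the
    count index correlates ``r_target`` with the discretized work-stress
    item.  Returns ``(tau, a)``.
    """
    p = prevalence
    c = float(stats.norm.ppf(1.0 - p))
    phi_bar = calibrate_item_correlation(alpha_target, k)
    target_p11 = phi_bar * p * (1.0 - p) + p * p
    tau = brentq(lambda t: _bvn_upper(c, t) - target_p11, 1e-6, 0.999, xtol=1e-10)

    var_index = k * p * (1.0 - p) + k * (k - 1) * (target_p11 - p * p)
    var_d = (work_levels**2 - 1) / 12.0
    mean_d = (work_levels + 1) / 2.0
    edges = np.array([-np.inf, *_inner_edges(work_levels), np.inf])

    def index_work_corr(a: float) -> float:
        # cov(indicator, discretized w): sum over work-item bins of the
        # orthant probability that w falls in the bin and the indicator fires
        cov = 0.0
        for j in range(work_levels):
            pr = _bvn_lower_upper(edges[j + 1], c, a) - _bvn_lower_upper(edges[j], c, a)
            cov += (j + 1) * pr
        cov -= p * mean_d
        return k * cov / math.sqrt(var_index * var_d)

    a = brentq(lambda a_: index_work_corr(a_) - r_target, 1e-4,
               math.sqrt(tau) - 1e-6, xtol=1e-10)
    return float(tau), float(a)


# --------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------

def _default_item_correlations() -> dict[str, float]:
    return {
        "mental_health": _mh_within_rho(
            DEFAULT_ALPHAS["mental_health"], DEFAULT_SUBSCALE_LOADING
        ),
        "resilience": calibrate_item_correlation(DEFAULT_ALPHAS["resilience"], 14),
        "life_stress": calibrate_item_correlation(DEFAULT_ALPHAS["life_stress"], 7),
        "family_conflict": calibrate_item_correlation(DEFAULT_ALPHAS["family_conflict"], 6),
        "father_involvement": calibrate_item_correlation(DEFAULT_ALPHAS["father_involvement"], 20),
        "job_change": calibrate_item_correlation(DEFAULT_ALPHAS["job_change"], 13),
    }


_COMMON_BETAS = {
    "life_stress": 0.15,
    "work_stress": 0.12,
    "family_conflict": 0.20,
    "resilience": -0.25,
}

_COUNTRY_BETAS = {
    # Italy: younger mothers and poorer physical health at higher risk
    "IT": {
        "maternal_age:30-35": -0.06,
        "maternal_age:35-40": -0.12,
        "maternal_age:40-60": -0.18,
        "physical_health:fine": -0.10,
        "physical_health:good": -0.20,
    },
    # Netherlands: high education and unemployment as risk factors
    "NL": {
        "education:university": 0.08,
        "education:postgraduate": 0.15,
        "employment:unemployed": 0.12,
    },
    # China: high SES and poor health as risks; marriage, more children,
    # and grandparental child-care support as protective factors
    "CN": {
        "education:university": 0.08,
        "education:postgraduate": 0.15,
        "household_income": 0.10,
        "physical_health:fine": -0.08,
        "physical_health:good": -0.16,
        "marital_status:divorced_other": 0.10,
        "n_children": -0.10,
        "grandparental_support": -0.12,
    },
}

# resilience buffers pandemic stress in NL (life and work) and CN (work only)
_COUNTRY_INTERACTIONS = {
    "CN": {("resilience", "work_stress"): -0.06},
    "IT": {},
    "NL": {
        ("resilience", "life_stress"): -0.06,
        ("resilience", "work_stress"): -0.06,
    },
}

_COUNTRY_PREVALENCES = {
    "CN": {
        "role": {"mother": 1.0},
        "maternal_age": dict(zip(schema.AGE_LEVELS, (0.18, 0.40, 0.30, 0.12))),
        "marital_status": {"married": 0.95, "divorced_other": 0.05},
        "education": dict(zip(schema.EDUCATION_LEVELS, (0.35, 0.45, 0.20))),
        "employment": {"employed": 0.95, "unemployed": 0.05},
        "physical_health": dict(zip(schema.HEALTH_LEVELS, (0.08, 0.32, 0.60))),
        "household_income": {1: 0.10, 2: 0.20, 3: 0.40, 4: 0.20, 5: 0.10},
        "n_children": {1: 0.62, 2: 0.33, 3: 0.05},
        "age_youngest_child": {a: 0.1 for a in range(1, 11)},
        "grandparental_support": {1: 0.536, 0: 0.464},
    },
    "IT": {
        "role": {"mother": 1.0},
        "maternal_age": dict(zip(schema.AGE_LEVELS, (0.08, 0.25, 0.37, 0.30))),
        "marital_status": {"married": 0.88, "divorced_other": 0.12},
        "education": dict(zip(schema.EDUCATION_LEVELS, (0.40, 0.40, 0.20))),
        "employment": {"employed": 0.65, "unemployed": 0.35},
        "physical_health": dict(zip(schema.HEALTH_LEVELS, (0.10, 0.35, 0.55))),
        "household_income": {1: 0.15, 2: 0.25, 3: 0.35, 4: 0.17, 5: 0.08},
        "n_children": {1: 0.45, 2: 0.42, 3: 0.13},
        "age_youngest_child": {a: 0.1 for a in range(1, 11)},
        "grandparental_support": {1: 0.183, 0: 0.817},
    },
    "NL": {
        "role": {"mother": 1.0},
        "maternal_age": dict(zip(schema.AGE_LEVELS, (0.10, 0.30, 0.35, 0.25))),
        "marital_status": {"married": 0.85, "divorced_other": 0.15},
        "education": dict(zip(schema.EDUCATION_LEVELS, (0.30, 0.45, 0.25))),
        "employment": {"employed": 0.85, "unemployed": 0.15},
        "physical_health": dict(zip(schema.HEALTH_LEVELS, (0.06, 0.30, 0.64))),
        "household_income": {1: 0.08, 2: 0.20, 3: 0.37, 4: 0.23, 5: 0.12},
        "n_children": {1: 0.35, 2: 0.45, 3: 0.20},
        "age_youngest_child": {a: 0.1 for a in range(1, 11)},
        "grandparental_support": {1: 0.094, 0: 0.906},
    },
}

_CONTINUOUS_SCALES = ("resilience", "life_stress", "family_conflict", "father_involvement")


@dataclass
class GeneratorConfig:
    """Full parameterization of one country's synthetic cohort.

    ``noise_sd=None`` scales the residual so the latent outcome has unit
    variance, making the configured ``true_betas`` standardized effects.
    """

    country: str
    n: int
    seed: int = 0
    categorical_prevalences: dict = field(default_factory=dict)
    continuous_params: dict = field(default_factory=dict)
    item_correlations: dict = field(default_factory=_default_item_correlations)
    true_betas: dict = field(default_factory=dict)
    interaction_betas: dict = field(default_factory=dict)
    noise_sd: float | None = None
    subscale_loading: float = DEFAULT_SUBSCALE_LOADING
    job_change_prevalence: float = DEFAULT_JOB_CHANGE_PREVALENCE
    job_change_work_r: float = DEFAULT_JOB_CHANGE_WORK_R

    def __post_init__(self) -> None:
        if self.country not in schema.COUNTRIES:
            raise ValueError(f"unknown country label {self.country!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.subscale_loading <= 1.0:
            raise ValueError("subscale_loading must be in (0, 1]")
        for factor, prev in self.categorical_prevalences.items():
            total = sum(prev.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"prevalences for {factor!r} sum to {total}, expected 1"
                )
            if any(p < 0 for p in prev.values()):
                raise ValueError(f"negative prevalence for {factor!r}")
        for name, rho in self.item_correlations.items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"item correlation for {name!r} outside [0, 1)")

    # ---- derived population quantities -----------------------------

    def _prevalences(self) -> dict:
        merged = {k: dict(v) for k, v in _COUNTRY_PREVALENCES[self.country].items()}
        merged.update({k: dict(v) for k, v in self.categorical_prevalences.items()})
        return merged

    def _ordinal_moments(self, factor: str) -> tuple[float, float]:
        prev = self._prevalences()[factor]
        values = np.array(list(prev.keys()), dtype=float)
        probs = np.array(list(prev.values()), dtype=float)
        mean = float(values @ probs)
        var = float((values - mean) ** 2 @ probs)
        return mean, var

    def _score_moments(self, scale: str) -> tuple[float, float]:
        """Population mean/variance of a composite under the target
        inter-item correlation (discretized items, equal-probability bins)."""
        specs = {
            "resilience": (14, 5, "sum"),
            "life_stress": (7, 4, "sum"),
            "family_conflict": (6, 5, "sum"),
            "father_involvement": (20, 5, "mean"),
        }
        if scale == "work_stress":
            return (11 / 2.0, (10**2 - 1) / 12.0)
        if scale == "job_change_index":
            p = self.job_change_prevalence
            tau, _ = calibrate_job_change_structure(
                DEFAULT_ALPHAS["job_change"], self.job_change_work_r,
                13, p, 10,
            )
            c = float(stats.norm.ppf(1.0 - p))
            p11 = _bvn_upper(c, tau)
            var = 13 * p * (1 - p) + 13 * 12 * (p11 - p * p)
            return (13 * p, var)
        k, levels, agg = specs[scale]
        low, high = (1, levels)
        item_mean = (low + high) / 2.0
        item_var = (levels**2 - 1) / 12.0
        rho = self.item_correlations[scale]
        var_sum = k * item_var * (1 + (k - 1) * rho)
        if agg == "sum":
            return (k * item_mean, var_sum)
        return (item_mean, var_sum / k**2)

    def term_population_moments(self, term: str) -> tuple[float, float]:
        """(mean, variance) of the raw variable behind a model term."""
        if term in ("household_income", "n_children", "age_youngest_child"):
            return self._ordinal_moments(term)
        return self._score_moments(term)

    def signal_variance(self) -> float:
        """Variance of the systematic part of the latent outcome.

        Continuous terms enter standardized (variance 1); dummy terms
        contribute their Bernoulli/multinomial variance; work stress and
        the job-change index share the configured correlation.
        """
        prev = self._prevalences()
        var = 0.0
        by_factor: dict[str, dict] = {}
        for term, beta in self.true_betas.items():
            if ":" in term:
                factor, level = term.split(":", 1)
                by_factor.setdefault(factor, {})[level] = beta
            elif term == "grandparental_support":
                p = prev["grandparental_support"][1]
                var += beta**2 * p * (1 - p)
            else:
                var += beta**2
        for factor, betas in by_factor.items():
            pmap = prev[factor]
            mean = sum(b * pmap[lv] for lv, b in betas.items())
            second = sum(b**2 * pmap[lv] for lv, b in betas.items())
            var += second - mean**2
        b_ws = self.true_betas.get("work_stress", 0.0)
        b_jc = self.true_betas.get("job_change_index", 0.0)
        var += 2.0 * b_ws * b_jc * self.job_change_work_r
        for (m, f), beta in self.interaction_betas.items():
            # products of independent zero-mean standardized terms
            var += beta**2
        return var

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        resid = 1.0 - self.signal_variance()
        if resid <= 0:
            raise ValueError(
                "configured effects exceed unit outcome variance; "
                "set noise_sd explicitly"
            )
        return math.sqrt(resid)

    def outcome_population_moments(self) -> tuple[float, float]:
        prev = self._prevalences()
        mean = 0.0
        for term, beta in self.true_betas.items():
            if ":" in term:
                factor, level = term.split(":", 1)
                mean += beta * prev[factor][level]
            elif term == "grandparental_support":
                mean += beta * prev["grandparental_support"][1]
        var = self.signal_variance() + self.resolved_noise_sd() ** 2
        return mean, var


def country_preset(country: str, n: int | None = None, seed: int = 0,
                   **overrides) -> GeneratorConfig:
    """Fully-populated configuration for one of the three study countries.

    Defaults: published sample sizes (CN 922, IT 641, NL 900),
    grandparental-support prevalences (53.6% / 18.3% / 9.4%), reliability
    targets per scale, and country-specific effect signs (e.g. the
    grandparental-support effect is negative — protective — in China and
    family conflict is a risk factor everywhere).
    """
    if country not in schema.COUNTRIES:
        raise ValueError(f"unknown country label {country!r}")
    betas = dict(_COMMON_BETAS)
    betas.update(_COUNTRY_BETAS[country])
    cfg = dict(
        country=country,
        n=_PRESET_N[country] if n is None else n,
        seed=seed,
        categorical_prevalences={
            k: dict(v) for k, v in _COUNTRY_PREVALENCES[country].items()
        },
        continuous_params={s: (0.0, 1.0) for s in _CONTINUOUS_SCALES},
        true_betas=betas,
        interaction_betas=dict(_COUNTRY_INTERACTIONS[country]),
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


# --------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------

def _substreams(seed: int, country: str) -> dict[str, np.random.Generator]:
    # country label folded into the entropy so the three cohorts of one
    # run are independent draws rather than copies of each other
    root = np.random.SeedSequence([seed, schema.COUNTRIES.index(country)])
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _sample_categoricals(config: GeneratorConfig, rng: np.random.Generator,
                         n: int) -> dict[str, np.ndarray]:
    out = {}
    for factor in schema.DEMOGRAPHIC_COLUMNS:
        prev = config._prevalences()[factor]
        levels = list(prev.keys())
        probs = np.array([prev[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(levels), size=n, p=probs)
        out[factor] = np.array(levels, dtype=object)[idx]
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one country's cohort table.

    The latent outcome is ``y = sum(beta_f * x_f) + interactions + noise``
    where continuous ``x_f`` are composite scores standardized by their
    *population* moments (so generation works at n=1 and the betas stay
    on a standardized scale); the 27 mental-health items are then driven
    by the standardized latent outcome through the four-subscale
    structure.  Deterministic given the config (including seed).
    """
    n = config.n
    rngs = _substreams(config.seed, config.country)
    demo = _sample_categoricals(config, rngs["demographics"], n)

    data: dict[str, np.ndarray] = {}
    data[schema.ID_COLUMN] = np.array(
        [f"{config.country}-{i:06d}" for i in range(n)], dtype=object
    )
    data[schema.COUNTRY_COLUMN] = np.full(n, config.country, dtype=object)
    for factor in schema.DEMOGRAPHIC_COLUMNS:
        data[factor] = demo[factor]

    # predictor scales: latent trait -> items -> composite score
    item_cols = {
        "resilience": (schema.RES_ITEMS, (1, 5)),
        "life_stress": (schema.LIFE_STRESS_ITEMS, (1, 4)),
        "family_conflict": (schema.CONFLICT_ITEMS, (1, 5)),
        "father_involvement": (schema.FI_ITEMS, (1, 5)),
    }
    scores: dict[str, np.ndarray] = {}
    for scale, (cols, levels) in item_cols.items():
        rng = rngs[scale]
        mean, sd = config.continuous_params.get(scale, (0.0, 1.0))
        trait = mean + sd * rng.standard_normal(n)
        items = generate_items_from_trait(
            trait, len(cols), config.item_correlations[scale], levels, rng
        )
        for j, col in enumerate(cols):
            data[col] = items[:, j]
        agg = items.mean(axis=1) if scale == "father_involvement" else items.sum(axis=1)
        scores[scale] = agg.astype(float)

    # work stress item + job-change indicators (shared latent structure)
    rng = rngs["work_job"]
    w = rng.standard_normal(n)
    data[schema.WORK_STRESS_ITEM] = _discretize(w, 10, 1)
    tau, a = calibrate_job_change_structure(
        DEFAULT_ALPHAS["job_change"], config.job_change_work_r,
        13, config.job_change_prevalence, 10,
    )
    b = math.sqrt(max(tau - a * a, 0.0))
    u = rng.standard_normal(n)
    eps = rng.standard_normal((n, 13))
    c = float(stats.norm.ppf(1.0 - config.job_change_prevalence))
    x_latent = a * w[:, None] + b * u[:, None] + math.sqrt(1.0 - tau) * eps
    jc = (x_latent > c).astype(np.int64)
    for j, col in enumerate(schema.JOB_CHANGE_ITEMS):
        data[col] = jc[:, j]
    scores["work_stress"] = data[schema.WORK_STRESS_ITEM].astype(float)
    scores["job_change_index"] = jc.sum(axis=1).astype(float)

    # latent outcome
    terms: dict[str, np.ndarray] = {}
    for scale in list(scores):
        mean, var = config.term_population_moments(scale)
        terms[scale] = (scores[scale] - mean) / math.sqrt(var)
    for factor in ("household_income", "n_children", "age_youngest_child"):
        mean, var = config.term_population_moments(factor)
        vals = demo[factor].astype(float)
        terms[factor] = (vals - mean) / math.sqrt(var) if var > 0 else vals - mean
    terms["grandparental_support"] = demo["grandparental_support"].astype(float)

    def term_vector(name: str) -> np.ndarray:
        if name in terms:
            return terms[name]
        if ":" in name:
            factor, level = name.split(":", 1)
            lv = type(next(iter(config._prevalences()[factor])))(level) \
                if factor in ("household_income", "n_children") else level
            return (demo[factor] == lv).astype(float)
        raise KeyError(f"unknown model term {name!r}")

    y = np.zeros(n)
    for term, beta in config.true_betas.items():
        y += beta * term_vector(term)
    for (m_name, f_name), beta in config.interaction_betas.items():
        y += beta * term_vector(m_name) * term_vector(f_name)
    y += config.resolved_noise_sd() * rngs["noise"].standard_normal(n)

    mu_y, var_y = config.outcome_population_moments()
    g = (y - mu_y) / math.sqrt(var_y)
    mh = generate_mental_health_items(
        g, config.subscale_loading, DEFAULT_ALPHAS["mental_health"],
        rngs["mental_health"],
    )
    for j, col in enumerate(schema.MH_ITEMS):
        data[col] = mh[:, j]
    data[schema.LATENT_OUTCOME] = y

    return pd.DataFrame(data, columns=list(schema.COHORT_COLUMNS))


def write_cohort(table: pd.DataFrame, path) -> None:
    """UTF-8 comma-delimited export with the fixed documented header."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


# --------------------------------------------------------------------
# small bench scenarios for the model-search machinery
# --------------------------------------------------------------------

def selection_scenario(
    n: int,
    p: int = 8,
    true_betas: Mapping[int, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    outcome: str = "outcome",
):
    """Plain Gaussian-design benchmark for subset-selection experiments.

    ``p`` independent standard-normal candidate predictors ``f1..fp``;
    the outcome is a linear combination of those listed in
    ``true_betas`` (index -> coefficient) plus ``noise_sd`` Gaussian
    noise.  Returns ``(frame, catalog, true_mask)`` where ``true_mask``
    is the bit mask of the generating model in the catalog's canonical
    order.
    """
    from .model_search import Factor, FactorCatalog

    if true_betas is None:
        true_betas = {0: 0.5, 1: 0.4, 2: 0.3}
    if any(not 0 <= idx < p for idx in true_betas):
        raise ValueError("true_betas indices must lie in [0, p)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.zeros(n)
    for idx, beta in true_betas.items():
        y += beta * X[:, idx]
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    frame = pd.DataFrame(X, columns=[f"f{i+1}" for i in range(p)])
    frame[outcome] = y
    catalog = FactorCatalog(
        tuple(Factor(f"f{i+1}", "continuous") for i in range(p))
    )
    true_mask = 0
    for idx in true_betas:
        true_mask |= 1 << idx
    return frame, catalog, true_mask
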