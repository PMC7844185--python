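"""Generator: reliability calibration, determinism, structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pandas.testing import assert_frame_equal

import maternalcv as m
from maternalcv import schema
from maternalcv.psychometrics import cronbach_alpha
from maternalcv.synthetic import discretization_attenuation


class TestCalibrateItemCorrelation:
    def test_zero_reliability_forces_independence(self):
        assert m.calibrate_item_correlation(0.0, 14) == 0.0

    def test_perfect_reliability_limit_forces_unit_correlation(self):
        # as alpha -> 1 with k=2, rho -> 1
        assert m.calibrate_item_correlation(1 - 1e-9, 2) == pytest.approx(1.0, abs=1e-6)

    def test_inverts_standardized_alpha_for_27_items(self):
        rho = m.calibrate_item_correlation(0.96, 27)
        assert rho == pytest.approx(0.96 / (27 - 0.96 * 26), rel=1e-12)
        # independent confirmation: alpha computed from the implied
        # 27x27 compound-symmetric correlation matrix
        k = 27
        R = np.full((k, k), rho)
        np.fill_diagonal(R, 1.0)
        alpha = k / (k - 1) * (1 - np.trace(R) / R.sum())
        assert alpha == pytest.approx(0.96, abs=1e-12)

    @pytest.mark.parametrize("alpha,k", [(1.0, 5), (1.2, 5), (-0.1, 5), (0.8, 1)])
    def test_invalid_arguments(self, alpha, k):
        with pytest.raises(ValueError):
            m.calibrate_item_correlation(alpha, k)

    @given(st.floats(0.0, 0.99), st.integers(2, 40))
    def test_roundtrips_through_alpha_formula(self, alpha, k):
        rho = m.calibrate_item_correlation(alpha, k)
        back = k * rho / (1 + (k - 1) * rho)
        assert back == pytest.approx(alpha, abs=1e-9)


class TestGenerateItems:
    def test_same_seed_identical(self):
        latent = np.random.default_rng(0).standard_normal(50)
        a = m.generate_items_from_trait(latent, 5, 0.4, (1, 5), rng=3)
        b = m.generate_items_from_trait(latent, 5, 0.4, (1, 5), rng=3)
        np.testing.assert_array_equal(a, b)

    def test_zero_rho_items_uncorrelated(self):
        latent = np.random.default_rng(1).standard_normal(4000)
        items = m.generate_items_from_trait(latent, 6, 0.0, (1, 5), rng=2)
        corr = np.corrcoef(items.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_calibrated_rho_reproduces_alpha(self):
        # rho calibrated for alpha=0.85 on a 14-item 1-5 scale
        rho = m.calibrate_item_correlation(0.85, 14)
        latent = np.random.default_rng(5).standard_normal(5000)
        items = m.generate_items_from_trait(latent, 14, rho, (1, 5), rng=6)
        assert cronbach_alpha(items) == pytest.approx(0.85, abs=0.02)

    def test_item_values_within_levels(self):
        latent = np.random.default_rng(2).standard_normal(500)
        items = m.generate_items_from_trait(latent, 7, 0.5, (1, 4), rng=0)
        assert items.min() >= 1 and items.max() <= 4

    def test_empty_latent_rejected(self):
        with pytest.raises(ValueError):
            m.generate_items_from_trait([], 5, 0.3)

    def test_attenuation_factor_below_one_and_increasing_in_levels(self):
        lams = [discretization_attenuation(L) for L in (2, 4, 5, 10)]
        assert all(0 < l < 1 for l in lams)
        assert lams == sorted(lams)


class TestCountryPreset:
    def test_cn_defaults(self):
        cfg = m.country_preset("CN")
        assert cfg.n == 922
        assert cfg.categorical_prevalences["grandparental_support"][1] == 0.536

    def test_nl_defaults(self):
        cfg = m.country_preset("NL")
        assert cfg.n == 900
        assert cfg.categorical_prevalences["grandparental_support"][1] == 0.094

    def test_it_sample_size(self):
        assert m.country_preset("IT").n == 641

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            m.country_preset("XX")

    def test_effect_signs_match_study_direction(self):
        cn = m.country_preset("CN").true_betas
        assert cn["grandparental_support"] < 0
        assert cn["n_children"] < 0
        for country in ("CN", "IT", "NL"):
            betas = m.country_preset(country).true_betas
            assert betas["family_conflict"] > 0
            assert betas["resilience"] < 0
            assert betas["life_stress"] > 0

    def test_prevalences_validated(self):
        with pytest.raises(ValueError, match="sum"):
            m.country_preset(
                "CN", categorical_prevalences={"grandparental_support": {1: 0.6, 0: 0.5}}
            )


class TestGenerateCohort:
    def test_single_row_has_all_columns(self):
        table = m.generate_cohort(m.country_preset("CN", n=1, seed=0))
        assert len(table) == 1
        assert tuple(table.columns) == schema.COHORT_COLUMNS

    def test_deterministic_given_config(self):
        a = m.generate_cohort(m.country_preset("IT", n=60, seed=42))
        b = m.generate_cohort(m.country_preset("IT", n=60, seed=42))
        assert_frame_equal(a, b)
        c = m.generate_cohort(m.country_preset("IT", n=60, seed=43))
        assert not a.equals(c)

    def test_item_ranges_respected(self, cn_cohort):
        for cols, (lo, hi) in schema.ITEM_RANGES.items():
            vals = cn_cohort[list(cols)].to_numpy()
            assert vals.min() >= lo and vals.max() <= hi

    def test_zero_noise_binary_factor_group_gap_equals_beta(self):
        cfg = m.country_preset(
            "CN", n=400, seed=9,
            true_betas={"grandparental_support": 0.5},
            interaction_betas={}, noise_sd=0.0,
        )
        table = m.generate_cohort(cfg)
        y = table[schema.LATENT_OUTCOME]
        gap = (y[table.grandparental_support == 1].mean()
               - y[table.grandparental_support == 0].mean())
        assert gap == pytest.approx(0.5, abs=1e-12)

    def test_latent_effects_recovered_by_ols(self):
        """Regressing the latent outcome on the generating terms returns
        the configured standardized effects (3 Monte-Carlo SEs)."""
        import statsmodels.api as sm

        cfg = m.country_preset("CN", n=20000, seed=5, interaction_betas={})
        scored = m.score_cohort(m.generate_cohort(cfg))
        terms = {}
        for name in ("life_stress", "work_stress", "family_conflict",
                     "resilience", "household_income", "n_children"):
            mu, var = cfg.term_population_moments(name)
            terms[name] = (scored[name].astype(float) - mu) / np.sqrt(var)
        terms["grandparental_support"] = scored.grandparental_support.astype(float)
        for term in ("education:university", "education:postgraduate",
                     "physical_health:fine", "physical_health:good",
                     "marital_status:divorced_other"):
            factor, level = term.split(":")
            terms[term] = (scored[factor] == level).astype(float)
        X = sm.add_constant(pd.DataFrame(terms))
        fit = sm.OLS(scored[schema.LATENT_OUTCOME], X).fit()
        for name in terms:
            true = cfg.true_betas.get(name, 0.0)
            assert abs(fit.params[name] - true) < 3 * fit.bse[name], name

    def test_work_job_change_link(self):
        cfg = m.country_preset("CN", n=20000, seed=11)
        scored = m.score_cohort(m.generate_cohort(cfg))
        r, _ = m.pearson_correlation(scored.job_change_index, scored.work_stress)
        assert r == pytest.approx(0.35, abs=0.03)

    def test_composite_alphas_match_targets_at_scale(self):
        table = m.generate_cohort(m.country_preset("NL", n=8000, seed=13))
        targets = {
            schema.RES_ITEMS: 0.85,
            schema.LIFE_STRESS_ITEMS: 0.82,
            schema.CONFLICT_ITEMS: 0.85,
            schema.FI_ITEMS: 0.89,
            schema.JOB_CHANGE_ITEMS: 0.83,
        }
        for cols, alpha in targets.items():
            assert cronbach_alpha(table[list(cols)]) == pytest.approx(alpha, abs=0.02)


def test_selection_scenario_is_exact_under_zero_noise():
    frame, catalog, true_mask = m.selection_scenario(
        n=100, p=5, true_betas={0: 1.0, 3: -0.5}, noise_sd=0.0, seed=1
    )
    assert true_mask == 0b01001
    recon = frame.f1 * 1.0 - frame.f4 * 0.5
    np.testing.assert_allclose(frame.outcome, recon, atol=1e-12)
    assert len(catalog) == 5
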