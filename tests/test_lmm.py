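"""Random-intercept REML fit, Satterthwaite F-tests, variance explained and
the treatment / trait-biomass model suites."""
import numpy as np
import pandas as pd
import pytest

import traitpart as tp
from traitpart.evaluation import rcbd_oracle
from traitpart.lmm import _factorial_X, _neg2_reml, fit_random_intercept_lmm


@pytest.fixture(scope="module")
def rcbd():
    design = tp.generate_design(1, 4, seed=0)
    X = _factorial_X(design)
    rng = np.random.default_rng(10)
    blocks = design["block"].to_numpy()
    beff = dict(zip(np.unique(blocks), (3.0, -1.0, 0.5, -2.5)))
    y = (
        np.array([beff[b] for b in blocks])
        + 1.2 * design["nutrient"].to_numpy()
        + 0.6 * design["fence"].to_numpy()
        + rng.normal(0, 1.0, 16)
    )
    return design, X, y, blocks


class TestFit:
    def test_ols_limit_when_no_block_structure(self, rcbd):
        design, X, _, blocks = rcbd
        rng = np.random.default_rng(0)
        y = rng.normal(size=16)  # no block signal
        fit = fit_random_intercept_lmm(y, X, blocks)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        if fit.var_block < 1e-10:  # boundary: must reproduce OLS
            assert np.allclose(fit.coef, beta_ols, atol=1e-6)
        # with any rho the balanced-design GLS equals OLS anyway
        assert np.allclose(fit.coef, beta_ols, atol=1e-6)

    def test_balanced_coefficients_match_cell_mean_oracle(self, rcbd):
        design, X, y, blocks = rcbd
        fit = fit_random_intercept_lmm(y, X, blocks)
        # effect coding: intercept = grand mean, each term = half the
        # difference between its +1 and -1 marginal means
        coef = fit.coefficients
        assert coef["Intercept"] == pytest.approx(y.mean(), abs=1e-8)
        n = design["nutrient"].to_numpy()
        assert coef["nutrient"] == pytest.approx(
            (y[n == 1].mean() - y[n == 0].mean()) / 2, abs=1e-8
        )

    def test_scale_equivariance(self, rcbd):
        _, X, y, blocks = rcbd
        a = fit_random_intercept_lmm(y, X, blocks)
        b = fit_random_intercept_lmm(2.0 * y, X, blocks)
        assert np.allclose(b.coef, 2.0 * a.coef, rtol=1e-8)
        assert b.var_resid == pytest.approx(4.0 * a.var_resid, rel=1e-6)
        assert b.var_block == pytest.approx(4.0 * a.var_block, rel=1e-6, abs=1e-12)

    def test_matches_statsmodels_mixedlm(self, rcbd):
        """Independent cross-check: statsmodels MixedLM REML estimates."""
        import statsmodels.api as sm

        design, X, y, blocks = rcbd
        fit = fit_random_intercept_lmm(y, X, blocks)
        sm_fit = sm.MixedLM(y, X.to_numpy(), groups=blocks).fit(reml=True)
        assert np.allclose(fit.coef, sm_fit.fe_params, atol=1e-5)
        assert fit.var_resid == pytest.approx(sm_fit.scale, rel=1e-4)
        assert fit.var_block == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3, abs=1e-6
        )

    def test_criterion_beats_random_probes(self, rcbd):
        design, X, y, blocks = rcbd
        fit = fit_random_intercept_lmm(y, X, blocks)
        Z = fit.Z
        rng = np.random.default_rng(1)
        for rho in 10.0 ** rng.uniform(-6, 3, 20):
            assert fit.reml_criterion <= _neg2_reml(rho, fit.y, X.to_numpy(), Z)[0] + 1e-9

    def test_rank_deficiency_names_aliased_column(self, rcbd):
        design, X, y, blocks = rcbd
        X2 = X.copy()
        X2["dup"] = X2["nutrient"]
        with pytest.raises(ValueError, match="dup"):
            fit_random_intercept_lmm(y, X2, blocks)


class TestAnova:
    def test_rcbd_classical_equivalence(self, rcbd):
        design, X, y, blocks = rcbd
        fit = fit_random_intercept_lmm(y, X, blocks)
        got = tp.lmm_anova(fit).set_index("term")
        want = rcbd_oracle(y, design).set_index("term")
        for term in ("nutrient", "fence", "nutrient:fence"):
            assert got.loc[term, "F"] == pytest.approx(want.loc[term, "F"], abs=1e-6)
            assert got.loc[term, "p"] == pytest.approx(want.loc[term, "p"], abs=1e-6)
            assert got.loc[term, "den_df"] == pytest.approx(9.0, abs=1e-6)

    def test_null_p_uniform_and_alpha_calibrated(self):
        design = tp.generate_design(1, 4, seed=0)
        X = _factorial_X(design)
        blocks = design["block"].to_numpy()
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(400):
            beff = dict(zip(np.unique(blocks), rng.normal(0, 1.0, 4)))
            y = np.array([beff[b] for b in blocks]) + rng.normal(0, 1.0, 16)
            fit = fit_random_intercept_lmm(y, X, blocks)
            ps.extend(tp.lmm_anova(fit)["p"].tolist())
        ps = np.asarray(ps)
        assert 0.03 <= (ps < 0.05).mean() <= 0.07
        assert ps.mean() == pytest.approx(0.5, abs=0.05)

    def test_dominant_effect_has_largest_F(self, rcbd):
        design, X, _, blocks = rcbd
        y = 10.0 * design["nutrient"].to_numpy() + np.random.default_rng(3).normal(
            0, 0.5, 16
        )
        fit = fit_random_intercept_lmm(y, X, blocks)
        tab = tp.lmm_anova(fit).set_index("term")
        assert tab.loc["nutrient", "F"] == tab["F"].max()


class TestR2:
    def test_intercept_only_marginal_zero(self, rcbd):
        _, _, y, blocks = rcbd
        X = pd.DataFrame({"Intercept": np.ones(16)})
        fit = fit_random_intercept_lmm(y, X, blocks)
        r2m, r2c = tp.nakagawa_r2(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c >= r2m

    def test_no_block_variance_conditional_equals_marginal(self, rcbd):
        design, X, _, blocks = rcbd
        rng = np.random.default_rng(4)
        y = 2.0 * design["nutrient"].to_numpy() + rng.normal(0, 1, 16)
        fit = fit_random_intercept_lmm(y, X, blocks)
        if fit.var_block < 1e-12:
            r2m, r2c = tp.nakagawa_r2(fit)
            assert r2c == pytest.approx(r2m, abs=1e-10)

    def test_noiseless_response_marginal_near_one(self, rcbd):
        design, X, _, blocks = rcbd
        y = 3.0 * design["nutrient"].to_numpy() - 1.5 * design["fence"].to_numpy()
        y = y + np.random.default_rng(5).normal(0, 1e-6, 16)
        fit = fit_random_intercept_lmm(y, X, blocks)
        r2m, _ = tp.nakagawa_r2(fit)
        assert r2m == pytest.approx(1.0, abs=1e-6)

    def test_bounds_hold_on_suite_fits(self, cwm_tables, design, community):
        _, _, biomass, _ = community
        tb = tp.trait_biomass_models(cwm_tables, biomass, design)
        assert (tb["r2_marginal"] >= -1e-12).all()
        assert (tb["r2_conditional"] >= tb["r2_marginal"] - 1e-12).all()
        assert (tb["r2_conditional"] <= 1 + 1e-12).all()


class TestSuites:
    def test_model_count_per_site(self, cwm_tables, design, community):
        _, _, biomass, _ = community
        tests = tp.treatment_effect_suite(cwm_tables, biomass, design)
        # (6 traits x 3 components + biomass) = 19 models x 3 terms per site
        per_site = tests.groupby("site").size()
        assert (per_site == 19 * 3).all()

    def test_fence_only_signal_detected(self):
        hits = 0
        for s in range(5):
            design = tp.generate_design(1, 4, seed=s)
            params = tp.SimulationParams(
                seed=s, n_sites=1,
                turnover_effect={"fence": 4.0},
                itv_effect={"fence": {"height": 3.0}},
            )
            cover, traits, biomass, _ = tp.generate_community(design, params)
            spec = tp.bootstrap_cwm(traits, tp.filter_dominant(cover), seed=s)
            tests = tp.treatment_effect_suite(spec, biomass, design)
            row = tests[(tests["response"] == "height:specific")].set_index("term")
            if row.loc["fence", "p"] < row.loc["nutrient", "p"]:
                hits += 1
        assert hits >= 4

    def test_missing_response_skipped_run_continues(self, design, community):
        cover, traits, biomass, _ = community
        spec = tp.bootstrap_cwm(traits, tp.filter_dominant(cover), seed=1)
        spec.loc[spec["trait"] == "SLA", "value"] = np.nan
        tests = tp.treatment_effect_suite(spec, biomass, design)
        assert not (tests["response"] == "SLA:specific").any()
        assert (tests["response"] == "height:specific").any()

    def test_log_transform_flag_applied_only_to_positive(self, design, community):
        cover, traits, biomass, _ = community
        spec = tp.bootstrap_cwm(traits, tp.filter_dominant(cover), seed=1)
        tests = tp.treatment_effect_suite(
            spec, biomass, design, log_transform={"biomass": True}
        )
        assert tests[tests["response"] == "biomass"]["logged"].all()

    def test_zero_variance_predictor_skipped(self, design, community):
        _, _, biomass, _ = community
        flat = pd.DataFrame(
            {"plot_id": design["plot_id"], "trait": "SLA",
             "component": "specific", "value": 5.0, "bootstrap_se": 0.0}
        )
        tb = tp.trait_biomass_models(flat, biomass, design)
        assert tb.empty
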