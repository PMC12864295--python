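import warnings

import numpy as np
import pandas as pd
import pytest

from hfrtrends.lmm import (
    LMMFit,
    anova_region,
    fit_lmm,
    lrt,
    lrt_region,
    region_emmeans,
    variance_pct,
)
from tests.conftest import lmm_table


@pytest.fixture(scope="module")
def balanced_fit():
    df = lmm_table(1)
    return df, fit_lmm(df)


class TestFit:
    def test_variance_free_limit_collapses_to_ols(self):
        df = lmm_table(2, s2c=0.0, s2y=0.0, s2e=0.5)
        fit = fit_lmm(df)
        # OLS with sum-to-zero region contrasts on the same design
        X = np.ones((len(df), 4))
        regions = sorted(df["region"].unique())
        for k, r in enumerate(regions[:-1]):
            X[:, k + 1] = (df["region"] == r).astype(float) \
                - (df["region"] == regions[-1]).astype(float)
        beta_ols = np.linalg.lstsq(X, df["ln_mean"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=0.02)
        assert fit.sigma2_colony < 0.02 and fit.sigma2_year < 0.02

    def test_matches_statsmodels_mixedlm(self, balanced_fit):
        df, fit = balanced_fit
        import statsmodels.formula.api as smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(
                "ln_mean ~ C(region, Sum)", df, groups=np.ones(len(df)),
                vc_formula={"colony": "0 + C(colony_id)",
                            "year": "0 + C(year)"}).fit(reml=True)
        assert fit.sigma2_colony == pytest.approx(m.vcomp[0], abs=1e-3)
        assert fit.sigma2_year == pytest.approx(m.vcomp[1], abs=1e-3)
        assert fit.sigma2_resid == pytest.approx(m.scale, abs=1e-3)

    def test_invariant_to_row_and_label_order(self, balanced_fit):
        df, fit = balanced_fit
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        fit2 = fit_lmm(shuffled)
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-6)
        assert fit.sigma2_colony == pytest.approx(fit2.sigma2_colony, abs=1e-6)

    def test_single_colony_per_region_pins_colony_variance(self):
        df = lmm_table(3, colonies_per_region={
            "GreatLakesNiagara": 1, "StLawrence": 1, "Atlantic": 1, "Arctic": 1})
        fit = fit_lmm(df)
        assert fit.sigma2_colony < 0.05 or fit.boundary


class TestRegionTests:
    def test_lrt_identical_likelihoods_gives_p_one(self):
        a = LMMFit(beta=np.zeros(4), beta_names=[""] * 4, vbeta=np.eye(4),
                   sigma2_colony=0, sigma2_year=0, sigma2_resid=1,
                   log_likelihood=-100.0, reml=False, converged=True,
                   boundary=False, regions=list("abcd"), has_region=True,
                   n_obs=10)
        b = LMMFit(beta=np.zeros(1), beta_names=[""], vbeta=np.eye(1),
                   sigma2_colony=0, sigma2_year=0, sigma2_resid=1,
                   log_likelihood=-100.0, reml=False, converged=True,
                   boundary=False, regions=list("abcd"), has_region=False,
                   n_obs=10)
        res = lrt(a, b)
        assert res == {"chi2": 0.0, "df": 3, "p": 1.0}

    def test_lrt_rejects_reml_fits(self, balanced_fit):
        _, fit = balanced_fit
        with pytest.raises(ValueError, match="ML"):
            lrt(fit, fit)

    def test_four_regions_give_three_df(self, balanced_fit):
        df, _ = balanced_fit
        res = lrt_region(df)
        assert res["df"] == 3

    def test_strong_region_effect_detected(self, balanced_fit):
        df, fit = balanced_fit
        assert lrt_region(df)["p"] < 0.01
        assert anova_region(fit)["p"] < 0.01

    def test_satterthwaite_ddf_in_sane_range(self, balanced_fit):
        _, fit = balanced_fit
        res = anova_region(fit)
        assert res["ndf"] == 3
        # between (colonies - regions) and the observation count
        assert 13 <= res["ddf"] <= fit.n_obs

    def test_classical_limit_ddf_near_ols_residual_df(self):
        # force both variance estimates to the zero boundary by centring
        # the noise within every colony and year before adding the region
        # structure; the Satterthwaite ddf must then fall back to the
        # OLS-like residual df, far above the colony-level df
        df = lmm_table(5, s2c=0.0, s2y=0.0, s2e=0.5, n_years=6,
                       offsets={r: 0.0 for r in (
                           "GreatLakesNiagara", "StLawrence",
                           "Atlantic", "Arctic")})
        noise = df["ln_mean"] - df["ln_mean"].mean()
        noise = noise - df.groupby("colony_id")["ln_mean"].transform("mean") \
            + df["ln_mean"].mean()
        noise = noise - df.groupby("year")["ln_mean"].transform("mean") \
            + df["ln_mean"].mean()
        offs = df["region"].map({"GreatLakesNiagara": 0.9, "StLawrence": 1.1,
                                 "Atlantic": -0.9, "Arctic": -1.1})
        fit = fit_lmm(df.assign(ln_mean=3.0 + offs + noise))
        res = anova_region(fit)
        assert res["ddf"] > 20  # far above the colony-level df


class TestVariancePct:
    def test_share_arithmetic(self):
        fit = LMMFit(beta=np.zeros(1), beta_names=[""], vbeta=np.eye(1),
                     sigma2_colony=1.0, sigma2_year=1.0, sigma2_resid=2.0,
                     log_likelihood=0.0, reml=True, converged=True,
                     boundary=False, regions=["a"], has_region=False, n_obs=4)
        pct = variance_pct(fit)
        assert (pct["colony_pct"], pct["year_pct"], pct["residual_pct"]) == \
            (25.0, 25.0, 50.0)

    def test_zero_year_variance_gives_zero_share(self):
        df = lmm_table(6, s2y=0.0)
        pct = variance_pct(fit_lmm(df))
        assert pct["year_pct"] < 3.0


class TestMarginalMeans:
    def test_effects_sum_to_zero(self, balanced_fit):
        _, fit = balanced_fit
        em = region_emmeans(fit)
        assert em["effect_ln"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_zero_region_effects_give_equal_emms(self):
        import dataclasses
        df = lmm_table(7, s2c=0.02, offsets={r: 0.0 for r in (
            "GreatLakesNiagara", "StLawrence", "Atlantic", "Arctic")})
        fit = fit_lmm(df)
        # construction contract: EMM_i = b0 + effect_i, so zeroed region
        # coefficients collapse every marginal mean onto exp(b0) exactly
        beta0 = fit.beta.copy()
        beta0[1:] = 0.0
        zeroed = dataclasses.replace(fit, beta=beta0)
        em0 = region_emmeans(zeroed)
        np.testing.assert_allclose(em0["emm_ng_g"],
                                   np.exp(fit.beta[0]), rtol=1e-12)
        # and on null data the fitted spread stays modest
        em = region_emmeans(fit)
        assert np.ptp(np.log(em["emm_ng_g"])) < 1.0

    def test_known_offset_scales_marginal_mean(self):
        offs = {"GreatLakesNiagara": 0.0, "StLawrence": 1.0,
                "Atlantic": 0.0, "Arctic": -1.0}
        reps = []
        for s in range(8):
            fit = fit_lmm(lmm_table(100 + s, offsets=offs))
            em = region_emmeans(fit).set_index("region")
            reps.append(em.loc["StLawrence", "effect_ln"])
        # mean recovered effect near the sum-to-zero version of the truth
        truth = 1.0 - np.mean(list(offs.values()))
        assert np.mean(reps) == pytest.approx(truth, abs=0.35)

    def test_interval_brackets_point_estimate(self, balanced_fit):
        _, fit = balanced_fit
        em = region_emmeans(fit)
        assert (em["ci_low_ng_g"] < em["emm_ng_g"]).all()
        assert (em["emm_ng_g"] < em["ci_high_ng_g"]).all()
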