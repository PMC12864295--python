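import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hfrtrends.censored import (
    CensoredFit,
    apply_detection_policy,
    detection_rate,
    fit_censored_lognormal,
    impute_nondetects,
    plotting_position_replacements,
)
from hfrtrends.io import StudyConfig
from tests.conftest import make_measurements


class TestDetectionRate:
    def test_all_detected(self):
        assert detection_rate(np.ones(10, dtype=bool)) == 1.0

    def test_partial(self):
        d = np.array([True] * 4 + [False] * 6)
        assert detection_rate(d) == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            detection_rate(np.array([], dtype=bool))


class TestCensoredMLE:
    def test_uncensored_reduces_to_moment_mle(self, rng):
        x = rng.lognormal(0.5, 0.8, 200)
        fit = fit_censored_lognormal(x)
        logs = np.log(x)
        assert fit.mu == pytest.approx(logs.mean(), abs=1e-5)
        assert fit.sigma == pytest.approx(logs.std(ddof=0), abs=1e-5)
        assert fit.converged and fit.n_censored == 0

    def test_agrees_with_scipy_censored_fit(self, rng):
        """Independent oracle: scipy's CensoredData + norm.fit on the logs."""
        for frac in (0.1, 0.3, 0.5):
            x = rng.lognormal(1.0, 0.5, 400)
            cut = np.quantile(x, frac)
            det, lim = x[x >= cut], np.full(int((x < cut).sum()), cut)
            fit = fit_censored_lognormal(det, lim)
            cd = stats.CensoredData(uncensored=np.log(det), left=np.log(lim))
            mu_o, sd_o = stats.norm.fit(cd)
            assert fit.mu == pytest.approx(mu_o, abs=2e-3)
            assert fit.sigma == pytest.approx(sd_o, abs=2e-3)

    def test_degenerate_equal_values_flagged(self):
        fit = fit_censored_lognormal(np.full(5, 2.0))
        assert fit.degenerate
        assert fit.sigma <= 1e-6

    def test_too_few_detected_raises(self):
        with pytest.raises(ValueError):
            fit_censored_lognormal(np.array([1.0, 2.0]))

    @pytest.mark.parametrize("n", [50, 200, 1000])
    def test_bias_shrinks_with_sample_size(self, n):
        """Censored-ML mu/sigma bias goes to zero as n grows (30% censoring)."""
        rng = np.random.default_rng(1234 + n)
        mus, sds = [], []
        for _ in range(30):
            x = rng.lognormal(1.0, 0.5, n)
            cut = np.quantile(x, 0.30)
            fit = fit_censored_lognormal(
                x[x >= cut], np.full(int((x < cut).sum()), cut))
            mus.append(fit.mu)
            sds.append(fit.sigma)
        tol = 2.5 / np.sqrt(n)
        assert abs(np.mean(mus) - 1.0) < tol
        assert abs(np.mean(sds) - 0.5) < tol


class TestReplacements:
    def test_closed_form_quantiles(self):
        # m=2 of n=9 on lnN(0,1): p={0.1,0.2} -> exp(PhiInv(p))
        fit = CensoredFit(0.0, 1.0, 9, 2, 0.0, True)
        got = plotting_position_replacements(fit, 2, 9)
        np.testing.assert_allclose(got, [0.27760624, 0.43101119], atol=1e-6)

    def test_no_censored_records_identity(self):
        df = make_measurements([
            ("A", "Arctic", 2010, f"p{i}", "alpha-HBCDD", 1.0 + i, 0.05, True)
            for i in range(4)])
        fit = CensoredFit(0.0, 1.0, 4, 0, 0.0, True)
        out = impute_nondetects(df, fit)
        np.testing.assert_array_equal(out["conc_final"], df["conc_ng_g_ww"])
        assert (out["provenance"] == "observed").all()

    def test_reference_orders_replacements(self):
        rows = [("A", "Arctic", 2010, f"p{i}", "alpha-HBCDD", 2.0 + i, 0.5, True)
                for i in range(6)]
        rows += [("A", "Arctic", 2011, "x1", "alpha-HBCDD", None, 0.5, False),
                 ("A", "Arctic", 2011, "x2", "alpha-HBCDD", None, 0.5, False)]
        df = make_measurements(rows)
        # reference syn-DP: x2 lower than x1 -> x2 gets the smaller quantile
        ref = pd.DataFrame({
            "year": [2011, 2011], "pool_id": ["x1", "x2"],
            "conc_ng_g_ww": [0.9, 0.2]})
        fit = CensoredFit(0.0, 1.0, 8, 2, 0.0, True)
        out = impute_nondetects(df, fit, ref)
        v1 = out.loc[out["pool_id"] == "x1", "conc_final"].iloc[0]
        v2 = out.loc[out["pool_id"] == "x2", "conc_final"].iloc[0]
        assert v2 < v1
        assert v1 != v2  # uniqueness
        assert (out.loc[~out["detected"], "conc_final"]
                < out.loc[~out["detected"], "mlod_ng_g"]).all()

    def test_replacements_clamped_below_mlod(self):
        rows = [("A", "Arctic", 2010, f"p{i}", "alpha-HBCDD", 50.0 + i, 0.01, True)
                for i in range(5)]
        rows += [("A", "Arctic", 2011, "x1", "alpha-HBCDD", None, 0.01, False),
                 ("A", "Arctic", 2011, "x2", "alpha-HBCDD", None, 0.01, False)]
        df = make_measurements(rows)
        fit = CensoredFit(np.log(40.0), 0.2, 7, 2, 0.0, True)  # poor fit
        out = impute_nondetects(df, fit)
        cens = out[~out["detected"]]
        assert (cens["conc_final"] < cens["mlod_ng_g"]).all()
        assert cens["conc_final"].is_unique
        assert (cens["provenance"] == "imputed-clamped").all()


class TestDetectionPolicy:
    def _group(self, n_det, n_cens, analyte="alpha-HBCDD"):
        rows = [("A", "Arctic", 2010, f"d{i}", analyte, 1.0 + 0.1 * i, 0.05, True)
                for i in range(n_det)]
        rows += [("A", "Arctic", 2011, f"c{i}", analyte, None, 0.05, False)
                 for i in range(n_cens)]
        return make_measurements(rows)

    def test_group_below_half_detection_zeroed(self):
        df = self._group(49, 51)
        out = apply_detection_policy(df)
        cens = out[~out["detected"]]
        assert (cens["conc_final"] == 0.0).all()
        assert (cens["provenance"] == "zeroed").all()

    def test_group_at_exactly_half_imputed(self):
        df = self._group(50, 50)
        out = apply_detection_policy(df)
        cens = out[~out["detected"]]
        assert (cens["conc_final"] > 0).all()
        assert cens["provenance"].str.startswith("imputed").all()

    def test_fully_detected_group_unchanged(self):
        df = self._group(10, 0)
        out = apply_detection_policy(df)
        np.testing.assert_array_equal(out["conc_final"], df["conc_ng_g_ww"])

    def test_detected_values_never_altered(self, small_study):
        _, _, (measurements, _, _) = small_study
        out = apply_detection_policy(measurements)
        det = out[out["detected"]]
        np.testing.assert_array_equal(det["conc_final"],
                                      det["conc_ng_g_ww"])
        assert out["conc_final"].notna().all()
        assert set(out["provenance"]) <= {
            "observed", "imputed", "imputed-clamped", "zeroed"}

    def test_detection_rates_match_generator_truth(self, small_study):
        _, _, (measurements, _, truth) = small_study
        assert int((~measurements["detected"]).sum()) == \
            truth["censoring"]["n_censored"]

    def test_imputed_means_near_truth(self, small_study):
        """Imputing then averaging reproduces colony means of the
        generating distribution for a censored analyte."""
        design, scenarios, (measurements, _, truth) = small_study
        out = apply_detection_policy(measurements)
        raw = truth["true_concentrations"]
        sub = out[out["analyte"] == "BDE-138"]
        if not (~sub["detected"]).any():
            pytest.skip("no censoring drawn for this analyte")
        # groups under 50% detection are zeroed by design; compare only
        # colonies that went through ML imputation
        imputed = sub.groupby("colony_id")["provenance"].apply(
            lambda p: not (p == "zeroed").any())
        sub = sub[sub["colony_id"].isin(imputed[imputed].index)]
        got = sub.groupby("colony_id")["conc_final"].mean()
        want = (raw[raw["analyte"] == "BDE-138"]
                .groupby("colony_id")["conc_ng_g_ww"].mean())
        for colony in got.index:
            n = (sub["colony_id"] == colony).sum()
            sd = raw[(raw["analyte"] == "BDE-138")
                     & (raw["colony_id"] == colony)]["conc_ng_g_ww"].std()
            assert abs(got[colony] - want[colony]) < 2.5 * sd / np.sqrt(n) + 1e-9
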