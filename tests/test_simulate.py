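import numpy as np
import pandas as pd
import pytest

from hfrtrends.simulate import (
    DEFAULT_COLONIES,
    StudyDesign,
    TrendScenario,
    apply_censoring,
    default_design,
    default_scenarios,
    simulate_study,
)
from hfrtrends.io import HFR_CLASSES


def _flat_design(**kw):
    return StudyDesign(
        colonies={"Granite Is": "GreatLakesNiagara", "Kent Is": "Atlantic"},
        region_offsets={"GreatLakesNiagara": 0.0, "Atlantic": 0.0,
                        "StLawrence": 0.0, "Arctic": 0.0},
        year_sd=0.0, pools_per_year=2, **kw)


def _scenarios(design, **kw):
    base = dict(residual_sd=1e-9, pool_sd=0.0)
    base.update(kw)
    return [
        TrendScenario(colony_id=c, hfr_class=cls, intercept_ln=2.0,
                      slope_before=0.3, breakpoint_year=2014,
                      slope_after=-0.2, **base)
        for c in design.colonies for cls in HFR_CLASSES
    ]


class TestGenerativeModel:
    def test_zero_noise_limit_reproduces_piecewise_line(self):
        design = _flat_design()
        meas, _, truth = simulate_study(design, _scenarios(design), seed=3)
        pools = (truth["true_concentrations"]
                 .groupby(["colony_id", "year", "pool_id"])["conc_ng_g_ww"])
        # HBCDD rows carry the class value directly
        hbcdd = truth["true_concentrations"].query("analyte == 'alpha-HBCDD'")
        for colony in design.colonies:
            yrs = np.array(design.colony_years(colony))
            expected = np.where(
                yrs <= 2014, 2.0 + 0.3 * (yrs - yrs.min()),
                2.0 + 0.3 * (2014 - yrs.min()) - 0.2 * (yrs - 2014))
            got = (hbcdd[hbcdd["colony_id"] == colony]
                   .groupby("year")["conc_ng_g_ww"].mean())
            np.testing.assert_allclose(np.log(got.to_numpy()), expected,
                                       atol=1e-6)

    def test_congener_sums_match_class_truth(self):
        design = _flat_design()
        meas, _, truth = simulate_study(design, _scenarios(design), seed=3)
        raw = truth["true_concentrations"]
        pbde = raw[raw["analyte"].str.startswith("BDE-")
                   & (raw["analyte"] != "BDE-209")]
        sums = pbde.groupby(["colony_id", "year", "pool_id"])["conc_ng_g_ww"].sum()
        ln_truth = truth["colony_year_ln_means"].query(
            "hfr_class == 'Sum11PBDE'").set_index(["colony_id", "year"])["ln_mean"]
        for (colony, year, _pool), s in sums.items():
            assert np.isclose(np.log(s), ln_truth.loc[(colony, year)], atol=1e-6)

    def test_fixed_seed_reproduces_tables(self):
        d = default_design()
        sc = default_scenarios(d)
        a = simulate_study(d, sc, seed=9)
        b = simulate_study(d, sc, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = simulate_study(d, sc, seed=10)
        assert not a[0].equals(c[0])

    def test_colony_year_means_track_scenario_means(self):
        """Monte-Carlo check of the stated generative model: across
        replicates the mean ln class value per colony-year sits within 3
        standard errors of the scenario mean."""
        design = StudyDesign(
            colonies={"Granite Is": "GreatLakesNiagara", "Kent Is": "Atlantic",
                      "East Bay": "Arctic"},
            region_offsets={"GreatLakesNiagara": 0.0, "Atlantic": 0.0,
                            "StLawrence": 0.0, "Arctic": 0.0},
            year_sd=0.1, pools_per_year=1,
            years={"Granite Is": (2008, 2010, 2012, 2014, 2016),
                   "Kent Is": (2008, 2010, 2012, 2014, 2016),
                   "East Bay": (2010, 2012, 2014, 2016)})
        scenarios = _scenarios(design, residual_sd=0.3, pool_sd=0.2)
        reps = 200
        acc = []
        for s in range(reps):
            _, _, truth = simulate_study(design, scenarios, seed=1000 + s)
            t = truth["colony_year_ln_means"].query("hfr_class == 'HBCDD'")
            acc.append(t.set_index(["colony_id", "year"])["ln_mean"])
        stacked = pd.concat(acc, axis=1)
        first = {c: min(design.colony_years(c)) for c in design.colonies}
        sd_tot = np.sqrt(0.3 ** 2 + 0.1 ** 2)
        se = sd_tot / np.sqrt(reps)
        scen = {s.colony_id: s for s in scenarios if s.hfr_class == "HBCDD"}
        for (colony, year), row in stacked.iterrows():
            expected = scen[colony].mean_at(year, first[colony])
            assert abs(row.mean() - expected) < 3 * se + 1e-9

    def test_breakpoint_outside_sampled_years_raises(self):
        design = _flat_design()
        bad = [TrendScenario(colony_id=c, hfr_class=cls, intercept_ln=2.0,
                             slope_before=0.1, breakpoint_year=2030,
                             slope_after=-0.1)
               for c in design.colonies for cls in HFR_CLASSES]
        with pytest.raises(ValueError, match="breakpoint"):
            simulate_study(design, bad, seed=1)

    def test_missing_scenario_raises(self):
        design = _flat_design()
        with pytest.raises(ValueError, match="no scenario"):
            simulate_study(design, _scenarios(design)[:-1], seed=1)


class TestCensoring:
    def test_zero_mlod_censors_nothing(self):
        design = _flat_design()
        meas, _, truth = simulate_study(design, _scenarios(design), seed=5)
        sched = {(a, y): 1e-12
                 for a in meas["analyte"].unique()
                 for y in meas["year"].unique()}
        out = apply_censoring(truth["true_concentrations"], sched)
        assert out["detected"].all()

    def test_mlod_above_everything_censors_all(self):
        design = _flat_design()
        _, _, truth = simulate_study(design, _scenarios(design), seed=5)
        sched = {(a, y): 1e9
                 for a in truth["true_concentrations"]["analyte"].unique()
                 for y in truth["true_concentrations"]["year"].unique()}
        out = apply_censoring(truth["true_concentrations"], sched)
        assert not out["detected"].any()
        assert out["conc_ng_g_ww"].isna().all()

    def test_missing_schedule_entry_raises(self):
        design = _flat_design()
        _, _, truth = simulate_study(design, _scenarios(design), seed=5)
        with pytest.raises(KeyError, match="schedule"):
            apply_censoring(truth["true_concentrations"], {("BDE-47", 2008): 1.0})

    def test_quantile_mlod_gives_matching_censored_fraction(self):
        """MLOD at the known 40th percentile of the generating log-normal
        censors about 40% of values."""
        design = StudyDesign(
            colonies=dict(DEFAULT_COLONIES),
            region_offsets={r: 0.0 for r in
                            ("GreatLakesNiagara", "StLawrence",
                             "Atlantic", "Arctic")},
            year_sd=0.0, pools_per_year=5)
        scenarios = [
            TrendScenario(colony_id=c, hfr_class=cls, intercept_ln=2.0,
                          slope_before=0.0, residual_sd=1e-9, pool_sd=0.5)
            for c in design.colonies for cls in HFR_CLASSES
        ]
        _, _, truth = simulate_study(design, scenarios, seed=21)
        raw = truth["true_concentrations"].query("analyte == 'alpha-HBCDD'")
        from scipy.stats import norm
        q40 = float(np.exp(2.0 + 0.5 * norm.ppf(0.40)))
        sched = {("alpha-HBCDD", y): q40 for y in raw["year"].unique()}
        out = apply_censoring(raw, sched)
        frac = 1.0 - out["detected"].mean()
        n = len(out)
        assert n > 1000
        assert abs(frac - 0.40) < 3 * np.sqrt(0.4 * 0.6 / n) + 0.01
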