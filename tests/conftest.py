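import numpy as np
import pandas as pd
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20080101)


def make_measurements(rows):
    """Build a minimal valid measurement frame from (colony, region, year,
    pool, analyte, conc, mlod, detected) tuples."""
    recs = []
    for colony, region, year, pool, analyte, conc, mlod, detected in rows:
        recs.append(dict(
            colony_id=colony, region=region, year=year, pool_id=pool,
            n_eggs=5, analyte=analyte,
            conc_ng_g_ww=(conc if detected else np.nan),
            mlod_ng_g=mlod, mloq_ng_g=mlod * 10 / 3, detected=detected))
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by the slower integration tests."""
    from hfrtrends.simulate import StudyDesign, default_scenarios, simulate_study

    design = StudyDesign(colonies={
        "Granite Is": "GreatLakesNiagara",
        "Snake Is": "GreatLakesNiagara",
        "Toronto H": "GreatLakesNiagara",
        "Strachan Is": "StLawrence",
        "Kent Is": "Atlantic",
        "East Bay": "Arctic",
    })
    scenarios = default_scenarios(design)
    return design, scenarios, simulate_study(design, scenarios, seed=11)


def lmm_table(seed, s2c=0.2, s2y=0.1, s2e=0.7, offsets=None, n_years=12,
              colonies_per_region=None, base=3.0):
    """Colony-year ln-mean table drawn directly from the nested model, the
    closed-form oracle route for mixed-model recovery checks."""
    rng = np.random.default_rng(seed)
    per_region = colonies_per_region or {
        "GreatLakesNiagara": 10, "StLawrence": 3, "Atlantic": 2, "Arctic": 2}
    offsets = offsets if offsets is not None else {
        "GreatLakesNiagara": 0.9, "StLawrence": 1.1,
        "Atlantic": -0.9, "Arctic": -1.1}
    years = list(range(2008, 2008 + n_years))
    vy = {y: rng.normal(0, np.sqrt(s2y)) for y in years}
    rows = []
    for region, nc in per_region.items():
        for j in range(nc):
            u = rng.normal(0, np.sqrt(s2c))
            for y in years:
                rows.append(dict(
                    region=region, colony_id=f"{region}-{j}", year=y,
                    ln_mean=base + offsets[region] + u + vy[y]
                    + rng.normal(0, np.sqrt(s2e))))
    return pd.DataFrame(rows)
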