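"""Synthetic pooled-egg monitoring data with known ground truth.

Emulates the structure of the Canadian herring gull egg monitoring
programs: 17 colonies in four regions sampled 2008-2023 (Arctic colonies
from 2010), annual chemistry for Great Lakes colonies and alternate years
after 2012 elsewhere, one to five pooled-egg homogenates per colony-year
with 2-15 eggs per pool, analyte-level congener measurements, and
year-varying method detection limits.

The generative model for the ln concentration of HFR class c in pool p of
colony j (region r) in year k is additive on the ln scale:

    ln C = piecewise_trend_cj(k) + region_offset_r + v_ck + e_cjk + w_cjkp

with a shared year effect v_ck, a colony-year deviate e_cjk and a pool
deviate w_cjkp.  Class deviates are drawn with correlation ``rho`` between
each reference class and its dependents (Sum11PBDE with BDE-209, whose
non-detects are ordered by BDE-99; SumDP with HBCDD, ordered by syn-DP).
Congener values are fixed shares of the class sum so that class sums match
the scenario mean exactly.  Every drawn parameter is stored in the truth
record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hfrtrends.io import (
    HFR_CLASSES,
    MEASUREMENT_COLUMNS,
    PBDE_SUM_CANDIDATES,
    REGIONS,
)

__all__ = [
    "TrendScenario",
    "StudyDesign",
    "default_design",
    "default_scenarios",
    "simulate_study",
    "apply_censoring",
]

#: colony -> region, the 17 colonies of the monitoring programs.
DEFAULT_COLONIES: dict[str, str] = {
    "Granite Is": "GreatLakesNiagara",
    "Agawa Rocks": "GreatLakesNiagara",
    "Double Is": "GreatLakesNiagara",
    "Chantry Is": "GreatLakesNiagara",
    "Middle Is": "GreatLakesNiagara",
    "Port Colborne": "GreatLakesNiagara",
    "Weseloh Rocks": "GreatLakesNiagara",
    "Hamilton H": "GreatLakesNiagara",
    "Toronto H": "GreatLakesNiagara",
    "Snake Is": "GreatLakesNiagara",
    "Strachan Is": "StLawrence",
    "Ile Deslauriers": "StLawrence",
    "Ile Bellechasse": "StLawrence",
    "Kent Is": "Atlantic",
    "Gull Is": "Atlantic",
    "East Bay": "Arctic",
    "Great Slave Lake": "Arctic",
}

#: fixed congener shares of the lower-brominated PBDE sum (normalised in
#: code).  BDE-47/-99 dominate in gull eggs; BDE-190 is set essentially at
#: trace level so that the study-wide 3% detection rule excludes it.
DEFAULT_PBDE_SHARES: dict[str, float] = {
    "BDE-17": 0.020, "BDE-28": 0.040, "BDE-47": 0.400, "BDE-49": 0.030,
    "BDE-66": 0.015, "BDE-85": 0.015, "BDE-99": 0.280, "BDE-100": 0.100,
    "BDE-138": 0.004, "BDE-153": 0.080, "BDE-183": 0.020, "BDE-190": 2e-5,
}

DEFAULT_DP_SYN_SHARE = 0.33  # syn fraction of the DP isomer sum

#: ln-scale region offsets (St. Lawrence and Great Lakes elevated, remote
#: regions low), approximately sum-to-zero.
DEFAULT_REGION_OFFSETS: dict[str, float] = {
    "GreatLakesNiagara": 0.9,
    "StLawrence": 1.1,
    "Atlantic": -0.9,
    "Arctic": -1.1,
}

#: default MLODs (ng/g) per analyte, within the program's 0.01-1.0 range and
#: placed so the minor congeners and syn-DP show realistic non-detect rates
#: while the major analytes stay nearly fully detected; BDE-209 is 5.0 in
#: three analysis years.
DEFAULT_MLODS: dict[str, float] = {
    **{c: 0.05 for c in PBDE_SUM_CANDIDATES},
    "BDE-17": 0.8, "BDE-66": 0.5, "BDE-85": 0.8, "BDE-138": 0.2,
    "BDE-190": 0.05,
    "BDE-209": 0.5, "alpha-HBCDD": 0.1, "syn-DP": 0.3, "anti-DP": 0.05,
}
BDE209_HIGH_MLOD_YEARS = (2012, 2016, 2020)
BDE209_HIGH_MLOD = 5.0


@dataclass(frozen=True)
class TrendScenario:
    """Ground-truth ln-scale trend of one colony x HFR class.

    ``intercept_ln`` is the ln concentration at the colony's first sampled
    year; slopes are ln-units per year.  ``breakpoint_year`` None means a
    single straight line.
    """

    colony_id: str
    hfr_class: str
    intercept_ln: float
    slope_before: float
    breakpoint_year: int | None = None
    slope_after: float | None = None
    residual_sd: float = 0.3
    pool_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.pool_sd < 0:
            raise ValueError("pool_sd must be >= 0")

    def mean_at(self, year: float, first_year: int) -> float:
        """Piecewise-linear ln-scale mean at a calendar year."""
        if self.breakpoint_year is None:
            return self.intercept_ln + self.slope_before * (year - first_year)
        pre = self.intercept_ln + self.slope_before * (
            min(year, self.breakpoint_year) - first_year)
        post = max(year - self.breakpoint_year, 0.0) * float(self.slope_after)
        return pre + post


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout and shared-variation parameters of a study."""

    colonies: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLONIES))
    years: Mapping[str, tuple[int, ...]] | None = None
    pools_per_year: int | None = None       # None: uniform on 1..5
    eggs_per_pool: tuple[int, int] = (2, 15)
    region_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_OFFSETS))
    year_sd: float = 0.15
    rho: float = 0.7
    pbde_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PBDE_SHARES))
    dp_syn_share: float = DEFAULT_DP_SYN_SHARE
    mlod_schedule: Mapping[tuple[str, int], float] | None = None

    def __post_init__(self) -> None:
        regions = set(self.colonies.values())
        if len(regions) < 2:
            raise ValueError("design needs >= 2 regions")
        unknown = regions - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions {sorted(unknown)}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")

    def colony_years(self, colony: str) -> tuple[int, ...]:
        if self.years is not None and colony in self.years:
            return tuple(self.years[colony])
        region = self.colonies[colony]
        if region == "GreatLakesNiagara":
            return tuple(range(2008, 2024))
        start = 2010 if region == "Arctic" else 2008
        annual = [y for y in range(start, 2013)]
        alternate = [y for y in range(2014, 2024, 2)]
        return tuple(annual + alternate)

    def all_years(self) -> tuple[int, ...]:
        ys: set[int] = set()
        for c in self.colonies:
            ys.update(self.colony_years(c))
        return tuple(sorted(ys))

    def mlod_for(self, analyte: str, year: int) -> float:
        if self.mlod_schedule is not None:
            try:
                return float(self.mlod_schedule[(analyte, year)])
            except KeyError:
                raise KeyError(
                    f"mlod schedule has no entry for ({analyte!r}, {year})")
        if analyte == "BDE-209" and year in BDE209_HIGH_MLOD_YEARS:
            return BDE209_HIGH_MLOD
        return DEFAULT_MLODS[analyte]


def default_design() -> StudyDesign:
    """The 17-colony, 2008-2023 layout with default shared variation."""
    return StudyDesign()


#: class-level default trends: rise-then-decline for HBCDD, BDE-209 and DP
#: around plausible change years; a steady slow decline for the legacy PBDE
#: sum.  Intercepts put class concentrations on realistic ng/g scales
#: (hundreds for the PBDE sum down to a few ng/g for DP).
_CLASS_DEFAULTS: dict[str, dict] = {
    "Sum11PBDE": dict(intercept_ln=5.0, slope_before=-0.05,
                      breakpoint_year=None, slope_after=None),
    "HBCDD": dict(intercept_ln=3.4, slope_before=0.15,
                  breakpoint_year=2013, slope_after=-0.08),
    "BDE209": dict(intercept_ln=2.3, slope_before=0.10,
                   breakpoint_year=2015, slope_after=-0.10),
    "SumDP": dict(intercept_ln=1.6, slope_before=0.08,
                  breakpoint_year=2019, slope_after=-0.05),
}


def default_scenarios(design: StudyDesign, colony_sd: float = 0.4,
                      residual_sd: float = 0.3, pool_sd: float = 0.2,
                      seed: int = 0) -> list[TrendScenario]:
    """One scenario per colony x class with colony-varying intercepts.

    Colony intercept deviates are N(0, colony_sd) on the ln scale, drawn
    deterministically from ``seed`` so a design has one canonical truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC010]))
    out = []
    for colony in sorted(design.colonies):
        dev = float(rng.normal(0.0, colony_sd))
        for cls in HFR_CLASSES:
            base = _CLASS_DEFAULTS[cls]
            yrs = design.colony_years(colony)
            bp = base["breakpoint_year"]
            if bp is not None and not (min(yrs) < bp < max(yrs)):
                bp, sa = None, None
                sb = base["slope_before"]
            else:
                sa = base["slope_after"]
                sb = base["slope_before"]
            out.append(TrendScenario(
                colony_id=colony, hfr_class=cls,
                intercept_ln=base["intercept_ln"] + dev,
                slope_before=sb, breakpoint_year=bp, slope_after=sa,
                residual_sd=residual_sd, pool_sd=pool_sd))
    return out


def _colony_rng(seed: int, colony: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(colony.encode())]))


def _class_correlation(rho: float) -> np.ndarray:
    """4x4 correlation over (Sum11PBDE, BDE209, HBCDD, SumDP): reference
    blocks (Sum11PBDE, BDE209) and (HBCDD, SumDP) correlate at rho."""
    c = np.eye(4)
    c[0, 1] = c[1, 0] = rho
    c[2, 3] = c[3, 2] = rho
    return c


def simulate_study(design: StudyDesign, scenarios: Sequence[TrendScenario],
                   seed: int) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (measurements, covariates, truth) for one study.

    Requires a scenario for every colony x HFR class of the design; raises
    if a scenario's breakpoint falls outside the colony's sampled years.
    The measurement table is already censored against the design's MLOD
    schedule; the truth record carries the pre-censoring values and every
    drawn parameter.
    """
    scen = {(s.colony_id, s.hfr_class): s for s in scenarios}
    for colony in design.colonies:
        for cls in HFR_CLASSES:
            if (colony, cls) not in scen:
                raise ValueError(f"no scenario for ({colony!r}, {cls!r})")
            s = scen[(colony, cls)]
            if s.breakpoint_year is not None:
                yrs = design.colony_years(colony)
                if not (min(yrs) < s.breakpoint_year < max(yrs)):
                    raise ValueError(
                        f"breakpoint {s.breakpoint_year} outside sampled years "
                        f"of {colony!r} ({min(yrs)}-{max(yrs)})")

    chol = np.linalg.cholesky(_class_correlation(design.rho))
    all_years = design.all_years()
    year_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4EA2]))
    year_effects = {
        cls: dict(zip(all_years,
                      year_rng.normal(0.0, design.year_sd, len(all_years))))
        for cls in HFR_CLASSES
    }

    shares = np.array([design.pbde_shares[c] for c in PBDE_SUM_CANDIDATES])
    shares = shares / shares.sum()

    rows: list[dict] = []
    cov_rows: list[dict] = []
    truth_means: list[dict] = []
    for colony in sorted(design.colonies):
        region = design.colonies[colony]
        rng = _colony_rng(seed, colony)
        yrs = design.colony_years(colony)
        first = min(yrs)
        for year in yrs:
            npools = (design.pools_per_year if design.pools_per_year
                      else int(rng.integers(1, 6)))
            eday = rng.normal(0.0, 1.0, 4)  # colony-year deviates, correlated
            eday = chol @ eday
            class_mean = {}
            for ci, cls in enumerate(HFR_CLASSES):
                s = scen[(colony, cls)]
                class_mean[cls] = (
                    s.mean_at(year, first)
                    + design.region_offsets[region]
                    + year_effects[cls][year]
                    + s.residual_sd * eday[ci]
                )
                truth_means.append(dict(colony_id=colony, region=region,
                                        hfr_class=cls, year=year,
                                        ln_mean=class_mean[cls]))
            for p in range(1, npools + 1):
                pool_id = f"{colony}-{year}-P{p}"
                n_eggs = int(rng.integers(design.eggs_per_pool[0],
                                          design.eggs_per_pool[1] + 1))
                wdev = chol @ rng.normal(0.0, 1.0, 4)
                for ci, cls in enumerate(HFR_CLASSES):
                    s = scen[(colony, cls)]
                    ln_pool = class_mean[cls] + s.pool_sd * wdev[ci]
                    total = float(np.exp(ln_pool))
                    if cls == "Sum11PBDE":
                        for cong, w in zip(PBDE_SUM_CANDIDATES, shares):
                            rows.append(dict(
                                colony_id=colony, region=region, year=year,
                                pool_id=pool_id, n_eggs=n_eggs, analyte=cong,
                                conc_ng_g_ww=total * w))
                    elif cls == "SumDP":
                        rows.append(dict(
                            colony_id=colony, region=region, year=year,
                            pool_id=pool_id, n_eggs=n_eggs, analyte="syn-DP",
                            conc_ng_g_ww=total * design.dp_syn_share))
                        rows.append(dict(
                            colony_id=colony, region=region, year=year,
                            pool_id=pool_id, n_eggs=n_eggs, analyte="anti-DP",
                            conc_ng_g_ww=total * (1.0 - design.dp_syn_share)))
                    else:
                        analyte = "BDE-209" if cls == "BDE209" else "alpha-HBCDD"
                        rows.append(dict(
                            colony_id=colony, region=region, year=year,
                            pool_id=pool_id, n_eggs=n_eggs, analyte=analyte,
                            conc_ng_g_ww=total))
            cov_rows.append(dict(
                colony_id=colony, year=year,
                egg_mass_g=float(rng.normal(92.0, 5.0)),
                length_cm=float(rng.normal(7.2, 0.25)),
                breadth_cm=float(rng.normal(5.0, 0.15)),
                pct_lipid=float(np.clip(rng.normal(9.0, 1.5), 3.0, 16.0)),
            ))

    uncensored = pd.DataFrame(rows)
    measurements = apply_censoring(uncensored, design)
    truth = {
        "seed": seed,
        "scenarios": {f"{s.colony_id}|{s.hfr_class}": vars(s).copy()
                      for s in scenarios},
        "region_offsets": dict(design.region_offsets),
        "year_sd": design.year_sd,
        "rho": design.rho,
        "year_effects": {cls: {int(y): float(v) for y, v in d.items()}
                         for cls, d in year_effects.items()},
        "colony_year_ln_means": pd.DataFrame(truth_means),
        "true_concentrations": uncensored,
        "censoring": {
            "n_rows": int(len(measurements)),
            "n_censored": int((~measurements["detected"]).sum()),
        },
    }
    return measurements, pd.DataFrame(cov_rows), truth


def apply_censoring(measurements: pd.DataFrame,
                    schedule: StudyDesign | Mapping[tuple[str, int], float],
                    ) -> pd.DataFrame:
    """Left-censor a measurement table against an MLOD schedule.

    ``schedule`` is either a StudyDesign (whose :meth:`StudyDesign.mlod_for`
    is used) or a mapping (analyte, year) -> MLOD ng/g covering every
    analyte-year present.  Concentrations below their MLOD become
    non-detects with a null concentration; MLOQ is recorded at the 10/3
    signal-to-noise multiple of the MLOD.
    """
    out = measurements.copy()
    if isinstance(schedule, StudyDesign):
        mlod_for = schedule.mlod_for
    else:
        def mlod_for(analyte: str, year: int) -> float:
            try:
                return float(schedule[(analyte, int(year))])
            except KeyError:
                raise KeyError(
                    f"mlod schedule has no entry for ({analyte!r}, {year})")
    mlods = np.array([
        mlod_for(a, y) for a, y in zip(out["analyte"], out["year"])
    ])
    out["mlod_ng_g"] = mlods
    out["mloq_ng_g"] = mlods * (10.0 / 3.0)
    conc = out["conc_ng_g_ww"].to_numpy(dtype=float)
    detected = conc >= mlods
    out["detected"] = detected
    out.loc[~detected, "conc_ng_g_ww"] = np.nan
    return out[MEASUREMENT_COLUMNS].reset_index(drop=True)
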