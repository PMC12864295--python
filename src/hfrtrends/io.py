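"""Reading, writing and validation of long-format monitoring tables.

The canonical unit of data is one pooled-egg homogenate x analyte
observation ("measurement record"), carried as one row of a tidy pandas
DataFrame.  Censoring metadata (method limits of detection/quantification
and the detect flag) travel with every row because limits vary by analyte
and year.  Non-detects carry a null concentration: no numeric value is ever
stored as truth for a censored observation, and ``"<MLOD"`` strings in
input files are parsed to (detected=False, conc=NaN).

Regions follow the four monitoring groups of the Canadian herring gull
programs, with the Niagara River colony folded into the Great Lakes group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hfrtrends")

REGIONS = ("GreatLakesNiagara", "StLawrence", "Atlantic", "Arctic")

#: PBDE congeners eligible for the lower-brominated sum (BDE-209 is always
#: analysed separately as the deca-BDE proxy).
PBDE_SUM_CANDIDATES = (
    "BDE-17", "BDE-28", "BDE-47", "BDE-49", "BDE-66", "BDE-85", "BDE-99",
    "BDE-100", "BDE-138", "BDE-153", "BDE-183", "BDE-190",
)

DEFAULT_ANALYTE_PANEL = PBDE_SUM_CANDIDATES + (
    "BDE-209", "alpha-HBCDD", "syn-DP", "anti-DP",
)

MEASUREMENT_COLUMNS = [
    "colony_id", "region", "year", "pool_id", "n_eggs", "analyte",
    "conc_ng_g_ww", "mlod_ng_g", "mloq_ng_g", "detected",
]

COVARIATE_COLUMNS = [
    "colony_id", "year", "egg_mass_g", "length_cm", "breadth_cm", "pct_lipid",
]

HFR_CLASSES = ("Sum11PBDE", "BDE209", "HBCDD", "SumDP")


class ValidationError(ValueError):
    """A table row violates a stated invariant; names the row and field."""


@dataclass(frozen=True)
class StudyConfig:
    """Tunable analysis settings with the study defaults.

    alpha
        Significance cutoff for every test in the pipeline.
    detection_threshold_colony
        Minimum detected fraction for a colony x analyte group to receive
        maximum-likelihood replacement values; below it non-detects are set
        to zero.  The boundary (exactly at threshold) imputes.
    detection_threshold_sum
        Minimum study-wide detection fraction for a lower-brominated PBDE
        congener to enter the congener sum.
    min_years_breakpoint
        Fewest sampled years for which a breakpoint model is attempted.
    imputation_grouping
        ``"colony"`` pools all years of a colony when fitting the censored
        distribution (the default); ``"colony_year"`` fits per year.
    """

    alpha: float = 0.05
    detection_threshold_colony: float = 0.50
    detection_threshold_sum: float = 0.03
    min_years_breakpoint: int = 6
    min_seg_points: int = 2
    rng_seed: int = 20080101
    imputation_grouping: str = "colony"
    milestones_path: str | None = None
    analyte_panel: tuple[str, ...] = DEFAULT_ANALYTE_PANEL

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("detection_threshold_colony", "detection_threshold_sum"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.imputation_grouping not in ("colony", "colony_year"):
            raise ValidationError(
                f"imputation_grouping must be 'colony' or 'colony_year', "
                f"got {self.imputation_grouping!r}")

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def _err(i, field_, msg) -> ValidationError:
    return ValidationError(f"row {i}: field '{field_}': {msg}")


def validate_measurements(df: pd.DataFrame,
                          config: StudyConfig | None = None) -> pd.DataFrame:
    """Validate and normalise a measurement table.

    Enforces the record invariants row by row and raises
    :class:`ValidationError` naming the first offending row and field;
    rows are never silently dropped.  Returns a normalised copy (sorted
    columns, canonical dtypes, NaN concentration on censored rows).
    """
    config = config or StudyConfig()
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out = df[MEASUREMENT_COLUMNS].copy()

    conc = out["conc_ng_g_ww"]
    if conc.dtype == object:
        is_cens_str = conc.astype(str).str.strip().str.upper().isin(
            {"<MLOD", "<MLOQ", "ND", "ND.", "N.D."})
        conc = pd.to_numeric(conc.where(~is_cens_str), errors="coerce")
        out["conc_ng_g_ww"] = conc
        out.loc[is_cens_str, "detected"] = False
    out["detected"] = out["detected"].astype(bool)
    out["year"] = pd.to_numeric(out["year"], errors="raise").astype(int)
    out["n_eggs"] = pd.to_numeric(out["n_eggs"], errors="raise").astype(int)
    for c in ("conc_ng_g_ww", "mlod_ng_g", "mloq_ng_g"):
        out[c] = pd.to_numeric(out[c], errors="coerce").astype(float)

    panel = set(config.analyte_panel)
    for i, row in out.iterrows():
        if row["analyte"] not in panel:
            raise _err(i, "analyte",
                       f"unknown analyte {row['analyte']!r}; panel is "
                       f"{sorted(panel)}")
        if row["region"] not in REGIONS:
            raise _err(i, "region",
                       f"unknown region {row['region']!r}; expected one of {REGIONS}")
        if not row["n_eggs"] >= 1:
            raise _err(i, "n_eggs", f"must be a positive integer, got {row['n_eggs']}")
        if not (np.isfinite(row["mlod_ng_g"]) and row["mlod_ng_g"] > 0):
            raise _err(i, "mlod_ng_g", f"must be > 0, got {row['mlod_ng_g']}")
        if not (np.isfinite(row["mloq_ng_g"]) and row["mloq_ng_g"] >= row["mlod_ng_g"]):
            raise _err(i, "mloq_ng_g",
                       f"must be >= mlod ({row['mlod_ng_g']}), got {row['mloq_ng_g']}")
        if row["detected"]:
            if not (np.isfinite(row["conc_ng_g_ww"]) and row["conc_ng_g_ww"] >= 0):
                raise _err(i, "conc_ng_g_ww",
                           "detected record needs a non-negative concentration")
    # censored rows carry no numeric concentration
    out.loc[~out["detected"], "conc_ng_g_ww"] = np.nan
    n_cens = int((~out["detected"]).sum())
    logger.info("validate_measurements: %d rows, %d censored", len(out), n_cens)
    return out


def read_measurements(path: str | Path,
                      config: StudyConfig | None = None) -> pd.DataFrame:
    """Read a long-format measurement CSV and validate every row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"colony_id": str, "pool_id": str})
    return validate_measurements(raw, config)


def write_measurements(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement table; censored concentrations emit ``<MLOD``."""
    path = Path(path)
    out = df[MEASUREMENT_COLUMNS].copy()
    conc = out["conc_ng_g_ww"].astype(object)
    conc[~out["detected"].astype(bool)] = "<MLOD"
    out["conc_ng_g_ww"] = conc
    out.to_csv(path, index=False)
    logger.info("write_measurements: %d rows -> %s", len(out), path)
    return path


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    out = df[COVARIATE_COLUMNS].copy()
    out["year"] = out["year"].astype(int)
    for c in COVARIATE_COLUMNS[2:]:
        out[c] = pd.to_numeric(out[c], errors="coerce").astype(float)
        bad = out.index[out[c].notna() & (out[c] <= 0)]
        if len(bad):
            raise _err(bad[0], c, f"must be strictly positive, got {out.loc[bad[0], c]}")
    return out


def read_covariates(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(Path(path), dtype={"colony_id": str})
    return validate_covariates(raw)


def write_covariates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[COVARIATE_COLUMNS].to_csv(path, index=False)
    return path
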