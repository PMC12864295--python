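"""Analysis-ready HFR class series: congener sums, annual means, ln
transform, egg morphometry and covariate screening.

Four HFR classes are analysed: the lower-brominated PBDE congener sum
(Sum11PBDE, the penta/octa commercial-mixture proxy), BDE-209 (the
deca-BDE proxy, always kept separate), total alpha-HBCDD, and the sum of
the two Dechlorane Plus isomers (SumDP).  Congeners detected in less than
3% of all samples study-wide are excluded from the sum; with the default
panel this reproduces the 11-congener sum (BDE-190 out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hfrtrends.io import PBDE_SUM_CANDIDATES, StudyConfig

logger = logging.getLogger("hfrtrends")

__all__ = [
    "select_sum_congeners",
    "class_sums",
    "annual_means",
    "egg_volume",
    "covariate_screen",
    "CovariateScreenResult",
]

RYDER_K = 0.489  # egg-volume constant: volume = k * length * breadth^2


def select_sum_congeners(measurements: pd.DataFrame,
                         threshold: float = 0.03) -> list[str]:
    """Lower-brominated congeners whose study-wide detection >= threshold.

    Operates on the raw (pre-imputation) table, using the detect flags of
    all analysed samples.  BDE-209 is never a candidate: it proxies the
    deca-BDE mixture and is analysed separately.
    """
    present = [c for c in PBDE_SUM_CANDIDATES
               if c in set(measurements["analyte"])]
    if not present:
        raise ValueError("no lower-brominated PBDE congeners in the table")
    keep = []
    for cong in present:
        rate = measurements.loc[measurements["analyte"] == cong,
                                "detected"].astype(bool).mean()
        if rate >= threshold:
            keep.append(cong)
        else:
            logger.info("select_sum_congeners: %s excluded "
                        "(detection %.1f%% < %.0f%%)", cong, 100 * rate,
                        100 * threshold)
    return keep


def class_sums(completed: pd.DataFrame,
               sum_congeners: list[str] | None = None) -> pd.DataFrame:
    """Per-pool HFR class values from completed (imputed) analyte rows.

    Requires a ``conc_final`` column (every value numeric).  Returns one
    row per pool x class with columns colony_id, region, year, pool_id,
    n_eggs, hfr_class, conc; a pool missing a required congener raises.
    """
    if "conc_final" not in completed.columns:
        raise ValueError("class_sums needs imputed data with 'conc_final' "
                         "(run apply_detection_policy first)")
    if sum_congeners is None:
        sum_congeners = select_sum_congeners(completed)

    idx_cols = ["colony_id", "region", "year", "pool_id", "n_eggs"]
    wide = completed.pivot_table(index=idx_cols, columns="analyte",
                                 values="conc_final", aggfunc="first")

    def _need(cols: list[str], cls: str) -> pd.DataFrame:
        missing_cols = [c for c in cols if c not in wide.columns]
        if missing_cols:
            raise ValueError(f"{cls}: analytes {missing_cols} absent from table")
        block = wide[cols]
        nan_rows = block.isna().any(axis=1)
        if nan_rows.any():
            pool = block.index[nan_rows][0][3]
            bad = block.columns[block.loc[block.index[nan_rows][0]].isna()][0]
            raise ValueError(f"{cls}: pool {pool!r} missing value for {bad!r}")
        return block

    parts = {
        "Sum11PBDE": _need(list(sum_congeners), "Sum11PBDE").sum(axis=1),
        "BDE209": _need(["BDE-209"], "BDE209")["BDE-209"],
        "HBCDD": _need(["alpha-HBCDD"], "HBCDD")["alpha-HBCDD"],
        "SumDP": _need(["syn-DP", "anti-DP"], "SumDP").sum(axis=1),
    }
    out = (pd.DataFrame(parts).rename_axis(columns="hfr_class")
           .stack().rename("conc").reset_index())
    return out


def annual_means(pool_values: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic colony-year means of class values, with the ln transform.

    Single-pool years pass the pool value through.  A colony-year whose
    mean is exactly zero (all its pools were zeroed non-detects) gets a
    null ``ln_mean`` and an exclusion flag: it cannot enter ln-scale trend
    fitting.
    """
    g = pool_values.groupby(["colony_id", "region", "hfr_class", "year"],
                            sort=True)
    out = g.agg(mean_conc=("conc", "mean"),
                n_pools=("conc", "size")).reset_index()
    positive = out["mean_conc"] > 0
    out["ln_mean"] = np.where(positive, np.log(out["mean_conc"].where(positive)),
                              np.nan)
    out["flag"] = np.where(positive, "", "zero-mean: excluded from ln trends")
    n_zero = int((~positive).sum())
    if n_zero:
        logger.info("annual_means: %d colony-year(s) with zero mean excluded "
                    "from ln-scale fitting", n_zero)
    return out


def egg_volume(length_cm: float | np.ndarray,
               breadth_cm: float | np.ndarray) -> float | np.ndarray:
    """Egg volume (cm^3) from length and breadth: 0.489 * l * d^2 (Ryder)."""
    l = np.asarray(length_cm, dtype=float)
    d = np.asarray(breadth_cm, dtype=float)
    if np.any(l <= 0) or np.any(d <= 0):
        raise ValueError("egg dimensions must be strictly positive")
    v = RYDER_K * l * d * d
    return float(v) if v.ndim == 0 else v


@dataclass
class CovariateScreenResult:
    method: str          # "pearson" | "spearman"
    coefficient: float
    p_value: float
    n: int
    normality_p: float   # Shapiro-Wilk p of the linear-fit residuals
    flag: str = ""


def covariate_screen(ln_means: np.ndarray, covariate: np.ndarray,
                     alpha_normality: float = 0.05) -> CovariateScreenResult:
    """Correlate a colony's annual ln means with a matched covariate mean.

    Pearson r is used when the residuals of the straight-line fit pass
    Shapiro-Wilk normality at ``alpha_normality``; otherwise the Spearman
    rank correlation.  The decision is a pure function of the data and is
    recorded in the result.
    """
    y = np.asarray(ln_means, dtype=float)
    x = np.asarray(covariate, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = y.size
    if n < 4:
        raise ValueError(f"covariate screening needs >= 4 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CovariateScreenResult("pearson", np.nan, np.nan, n, np.nan,
                                     flag="constant input: coefficient undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    if np.ptp(resid) < 1e-12:
        norm_p = 1.0  # exact line; residuals carry no evidence against normality
    else:
        norm_p = float(stats.shapiro(resid).pvalue)
    if norm_p >= alpha_normality:
        r, p = stats.pearsonr(x, y)
        return CovariateScreenResult("pearson", float(r), float(p), n, norm_p)
    r, p = stats.spearmanr(x, y)
    return CovariateScreenResult("spearman", float(r), float(p), n, norm_p)
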