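"""Non-detect handling: censored log-normal MLE and quantile replacement.

Monitoring labs report an observation only when it exceeds the method limit
of detection (MLOD); below-limit observations are left-censored.  Per
colony and analyte the policy is:

* detection rate >= 50%: fit a log-normal by maximum likelihood in which
  detected values contribute density terms and each censored value a
  cumulative term at its own limit, then replace the m censored values with
  the m smallest plotting-position quantiles exp(mu + sigma * PhiInv(i/(n+1)))
  of the fitted distribution.  Replacements are unique, kept below the
  record's MLOD, and assigned among the censored pools in ascending order of
  a frequently-detected reference analyte measured on the same pools
  (BDE-99 for PBDE congeners; syn-DP for HBCDD and anti-DP).
* detection rate < 50%: no replacement is estimable and censored values are
  set to zero.

Every value leaves this module with a provenance flag: ``observed``,
``imputed`` or ``zeroed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hfrtrends.io import StudyConfig

logger = logging.getLogger("hfrtrends")

__all__ = [
    "CensoredFit",
    "REFERENCE_MAP",
    "detection_rate",
    "fit_censored_lognormal",
    "impute_nondetects",
    "apply_detection_policy",
]

#: dependent analyte -> reference analyte used to order replacement values.
REFERENCE_MAP = {
    **{c: "BDE-99" for c in (
        "BDE-17", "BDE-28", "BDE-47", "BDE-49", "BDE-66", "BDE-85",
        "BDE-100", "BDE-138", "BDE-153", "BDE-183", "BDE-190", "BDE-209")},
    "alpha-HBCDD": "syn-DP",
    "anti-DP": "syn-DP",
}

_SIGMA_FLOOR = 1e-6


@dataclass
class CensoredFit:
    """Maximum-likelihood ln-scale parameters of one colony x analyte group."""

    mu: float
    sigma: float
    n_total: int
    n_censored: int
    log_likelihood: float
    converged: bool
    degenerate: bool = False


def detection_rate(detected: pd.Series | np.ndarray) -> float:
    """Fraction of records with reportable (above-limit) concentrations."""
    d = np.asarray(detected, dtype=bool)
    if d.size == 0:
        raise ValueError("detection_rate needs at least one record")
    return float(d.mean())


def _negloglik(theta: np.ndarray, logs: np.ndarray, loglims: np.ndarray) -> float:
    mu, logsigma = theta
    sigma = np.exp(logsigma)
    ll = np.sum(stats.norm.logpdf(logs, mu, sigma))
    if loglims.size:
        ll += np.sum(stats.norm.logcdf(loglims, mu, sigma))
    return -ll


def fit_censored_lognormal(values: np.ndarray, limits: np.ndarray | None = None) -> CensoredFit:
    """Left-censored log-normal maximum likelihood.

    Parameters
    ----------
    values
        Detected concentrations (> 0), ng/g.
    limits
        Censoring limit of each censored record (> 0), ng/g; may be empty.

    With no censored records the estimate reduces to the ln-scale moment
    MLE.  All-equal detected values give a sigma at the lower bound and a
    ``degenerate`` flag.
    """
    values = np.asarray(values, dtype=float)
    limits = np.asarray([] if limits is None else limits, dtype=float)
    if values.size < 3:
        raise ValueError(f"need >= 3 detected values, got {values.size}")
    if np.any(values <= 0) or np.any(limits <= 0):
        raise ValueError("concentrations and limits must be strictly positive")

    logs = np.log(values)
    loglims = np.log(limits)
    n_tot, n_cen = values.size + limits.size, limits.size

    mu0 = float(logs.mean())
    sd0 = float(logs.std(ddof=0))
    if sd0 < _SIGMA_FLOOR and n_cen == 0:
        ll = float(np.sum(stats.norm.logpdf(logs, mu0, _SIGMA_FLOOR)))
        return CensoredFit(mu0, _SIGMA_FLOOR, n_tot, 0, ll, True, degenerate=True)
    sd0 = max(sd0, 0.1)

    res = optimize.minimize(
        _negloglik, x0=np.array([mu0, np.log(sd0)]), args=(logs, loglims),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    fit = CensoredFit(mu, max(sigma, _SIGMA_FLOOR), n_tot, n_cen,
                      -float(res.fun), bool(res.success),
                      degenerate=sigma <= _SIGMA_FLOOR)
    if not fit.converged:
        logger.warning("censored MLE did not converge (n=%d, censored=%d)",
                       n_tot, n_cen)
    return fit


def plotting_position_replacements(fit: CensoredFit, m: int, n: int) -> np.ndarray:
    """The m smallest quantile-normal replacement values of a fitted group.

    Plotting positions p_i = i/(n+1), i = 1..m, placed on the fitted
    log-normal: exp(mu + sigma * PhiInv(p_i)).  Strictly increasing.
    """
    i = np.arange(1, m + 1, dtype=float)
    p = i / (n + 1.0)
    return np.exp(fit.mu + fit.sigma * stats.norm.ppf(p))


def impute_nondetects(group: pd.DataFrame, fit: CensoredFit,
                      reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Replace censored rows of one colony x analyte group.

    ``reference`` holds rows of the mapped reference analyte for the same
    pools (columns pool_id, conc_ng_g_ww); replacement values are assigned
    among censored records in ascending order of the reference
    concentration, ties and missing references falling back to pool_id
    order.  Detected rows are returned untouched.  Adds/updates ``conc_final``
    and ``provenance`` columns.
    """
    out = group.copy()
    if "conc_final" not in out.columns:
        out["conc_final"] = out["conc_ng_g_ww"].astype(float)
        out["provenance"] = np.where(out["detected"], "observed", "censored")
    cens_idx = out.index[~out["detected"].astype(bool)]
    m, n = len(cens_idx), len(out)
    if m == 0:
        return out

    repl = plotting_position_replacements(fit, m, n)

    # rank censored pools by the reference analyte, pool_id as tie-break
    key = pd.DataFrame(index=cens_idx)
    key["pool"] = out.loc[cens_idx, "pool_id"].astype(str)
    key["year"] = out.loc[cens_idx, "year"]
    if reference is not None and len(reference):
        ref_conc = (reference.set_index(["year", "pool_id"])["conc_ng_g_ww"]
                    .astype(float))
        ref_for = pd.MultiIndex.from_frame(
            out.loc[cens_idx, ["year", "pool_id"]])
        key["ref"] = ref_conc.reindex(ref_for).to_numpy()
        if key["ref"].isna().any():
            logger.warning("impute_nondetects: reference analyte missing for "
                           "%d of %d censored pools; pool_id order used",
                           int(key["ref"].isna().sum()), m)
    else:
        key["ref"] = np.nan
    order = key.sort_values(["ref", "year", "pool"], na_position="last").index

    mlods = out.loc[order, "mlod_ng_g"].to_numpy(dtype=float)
    vals = repl.copy()
    clamp = vals >= mlods
    if clamp.any():
        # keep every replacement strictly below its own limit and unique
        vals[clamp] = mlods[clamp] * (1.0 - 1e-9 * (1.0 + np.arange(clamp.sum())))
        logger.info("impute_nondetects: clamped %d replacement(s) to MLOD",
                    int(clamp.sum()))
    out.loc[order, "conc_final"] = vals
    out.loc[order, "provenance"] = np.where(clamp, "imputed-clamped", "imputed")
    return out


def apply_detection_policy(measurements: pd.DataFrame,
                           config: StudyConfig | None = None) -> pd.DataFrame:
    """Complete every measurement with the 50%-detection policy.

    Groups rows per colony x analyte (per colony x analyte x year when
    ``config.imputation_grouping == "colony_year"``); groups at or above the
    detection threshold get ML replacement values, groups below get zeros
    for their non-detects.  Returns the table with ``conc_final`` and
    ``provenance`` columns; detected values are never altered.
    """
    config = config or StudyConfig()
    df = measurements.copy()
    df["conc_final"] = df["conc_ng_g_ww"].astype(float)
    df["provenance"] = np.where(df["detected"].astype(bool), "observed", "censored")

    group_cols = ["colony_id", "analyte"]
    if config.imputation_grouping == "colony_year":
        group_cols.append("year")

    pieces = []
    for keys, grp in df.groupby(group_cols, sort=True):
        rate = detection_rate(grp["detected"])
        n_cens = int((~grp["detected"].astype(bool)).sum())
        if n_cens == 0:
            pieces.append(grp)
            continue
        if rate < config.detection_threshold_colony:
            grp = grp.copy()
            grp.loc[~grp["detected"].astype(bool), "conc_final"] = 0.0
            grp.loc[~grp["detected"].astype(bool), "provenance"] = "zeroed"
            pieces.append(grp)
            continue
        detected_vals = grp.loc[grp["detected"], "conc_ng_g_ww"].to_numpy(float)
        limits = grp.loc[~grp["detected"].astype(bool), "mlod_ng_g"].to_numpy(float)
        if detected_vals.size < 3:
            fit = None
        else:
            fit = fit_censored_lognormal(detected_vals, limits)
        if fit is None or not fit.converged:
            # keep the pipeline total: treat like the below-threshold case
            logger.warning("apply_detection_policy: censored MLE unusable for "
                           "group %s; zeroing %d non-detects", keys, n_cens)
            grp = grp.copy()
            grp.loc[~grp["detected"].astype(bool), "conc_final"] = 0.0
            grp.loc[~grp["detected"].astype(bool), "provenance"] = "zeroed"
            pieces.append(grp)
            continue
        analyte = grp["analyte"].iloc[0]
        ref_name = REFERENCE_MAP.get(analyte)
        reference = None
        if ref_name is not None:
            colony = grp["colony_id"].iloc[0]
            reference = measurements[
                (measurements["colony_id"] == colony)
                & (measurements["analyte"] == ref_name)
                & measurements["detected"]
            ][["year", "pool_id", "conc_ng_g_ww"]]
        pieces.append(impute_nondetects(grp, fit, reference))
    out = pd.concat(pieces).loc[df.index]
    return out


def imputation_audit(completed: pd.DataFrame) -> pd.DataFrame:
    """Per-group audit table: n, n_censored and provenance counts."""
    g = completed.groupby(["colony_id", "analyte"])
    audit = g.agg(
        n=("conc_final", "size"),
        n_censored=("detected", lambda d: int((~d.astype(bool)).sum())),
        n_imputed=("provenance", lambda p: int(p.str.startswith("imputed").sum())),
        n_zeroed=("provenance", lambda p: int((p == "zeroed").sum())),
    ).reset_index()
    return audit
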