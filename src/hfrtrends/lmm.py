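"""Regional linear mixed model for ln HFR concentrations.

Model, for the ln concentration y_ijk of colony j (nested in region i) in
year k:

    y_ijk = b0 + b_region(i) + u_ij + v_k + e_ijk

with fixed region effects under sum-to-zero contrasts (the intercept is the
overall mean across regions), a random colony intercept u_ij ~ N(0, s2_colony),
a crossed random year intercept v_k ~ N(0, s2_year) shared by all colonies,
and residual e_ijk ~ N(0, s2_resid).

Estimation profiles the (restricted) likelihood over the two ln variance
ratios g_c = s2_colony/s2_resid and g_y = s2_year/s2_resid; fixed effects
come from generalised least squares at the optimum.  The region F test uses
Satterthwaite's moment-matching denominator df; the region likelihood-ratio
test compares maximum-likelihood fits of the full and no-region models.
Marginal means per region back-transform to ng/g (intervals of the median
on the raw scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("hfrtrends")

__all__ = [
    "LMMFit",
    "fit_lmm",
    "lrt",
    "lrt_region",
    "anova_region",
    "variance_pct",
    "region_emmeans",
]

_LOG_RATIO_BOUND = 20.0


@dataclass
class LMMFit:
    """REML or ML fit of the nested region/colony/year model."""

    beta: np.ndarray
    beta_names: list[str]
    vbeta: np.ndarray
    sigma2_colony: float
    sigma2_year: float
    sigma2_resid: float
    log_likelihood: float
    reml: bool
    converged: bool
    boundary: bool
    regions: list[str]
    has_region: bool
    n_obs: int
    # design internals, kept for df computations and marginal means
    X: np.ndarray = field(repr=False, default=None)
    Zc: np.ndarray = field(repr=False, default=None)
    Zy: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.sigma2_colony, self.sigma2_year, self.sigma2_resid])

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vbeta))


def _design(data: pd.DataFrame, response: str, has_region: bool):
    df = data.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError("no usable observations")
    regions = sorted(df["region"].unique())
    colonies = sorted(df["colony_id"].unique())
    years = sorted(df["year"].unique())
    if has_region and len(regions) < 2:
        raise ValueError("region model needs >= 2 regions")
    if len(years) < 2:
        raise ValueError("need >= 2 years")
    n = len(df)
    # sum-to-zero region contrasts: columns for all but the last region
    if has_region:
        X = np.ones((n, len(regions)))
        names = ["intercept"] + [f"region[{r}]" for r in regions[:-1]]
        for k, r in enumerate(regions[:-1]):
            col = np.where(df["region"] == r, 1.0, 0.0)
            col = col - np.where(df["region"] == regions[-1], 1.0, 0.0)
            X[:, k + 1] = col
    else:
        X = np.ones((n, 1))
        names = ["intercept"]
    Zc = pd.get_dummies(pd.Categorical(df["colony_id"], categories=colonies)) \
        .to_numpy(dtype=float)
    Zy = pd.get_dummies(pd.Categorical(df["year"], categories=years)) \
        .to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    return X, Zc, Zy, y, names, regions


def _profiled_nll(lg: np.ndarray, X: np.ndarray, Gc: np.ndarray,
                  Gy: np.ndarray, y: np.ndarray, reml: bool) -> float:
    n, p = X.shape
    V = np.eye(n) + np.exp(lg[0]) * Gc + np.exp(lg[1]) * Gy
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Xi = np.linalg.solve(c, X)
    yi = np.linalg.solve(c, y)
    XtVX = Xi.T @ Xi
    beta = np.linalg.solve(XtVX, Xi.T @ yi)
    r = yi - Xi @ beta
    rss = float(r @ r)
    if reml:
        dof = n - p
        s2 = rss / dof
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + logdetV + logdetXtVX)
    else:
        s2 = rss / n
        ll = -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + logdetV)
    return -ll


def _loglik_theta(theta: np.ndarray, X: np.ndarray, Gc: np.ndarray,
                  Gy: np.ndarray, y: np.ndarray, reml: bool) -> float:
    """Unprofiled (restricted) log likelihood at variance components theta."""
    s2c, s2y, s2e = theta
    if s2e <= 0 or s2c < 0 or s2y < 0:
        return -1e10
    n, p = X.shape
    V = s2e * np.eye(n) + s2c * Gc + s2y * Gy
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -1e10
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Xi = np.linalg.solve(c, X)
    yi = np.linalg.solve(c, y)
    XtVX = Xi.T @ Xi
    beta = np.linalg.solve(XtVX, Xi.T @ yi)
    r = yi - Xi @ beta
    ll = -0.5 * (n * np.log(2 * np.pi) + logdetV + float(r @ r))
    if reml:
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        ll += 0.5 * (p * np.log(2 * np.pi) - logdetXtVX)
    return ll


def fit_lmm(data: pd.DataFrame, response: str = "ln_mean", reml: bool = True,
            has_region: bool = True) -> LMMFit:
    """Fit the region/colony/year model to one HFR class.

    ``data`` needs columns region, colony_id, year and the response (NaN
    responses are dropped).  ``has_region=False`` fits the null model with
    the same random structure, for likelihood-ratio comparisons.  Variance
    ratios at the optimisation boundary (for example a single colony per
    region everywhere, which pins the colony variance to zero) set the
    ``boundary`` flag.
    """
    X, Zc, Zy, y, names, regions = _design(data, response, has_region)
    Gc, Gy = Zc @ Zc.T, Zy @ Zy.T
    # one colony per region everywhere makes the colony effect collinear
    # with the fixed design: the colony variance is unidentified and gets
    # pinned at the zero boundary
    confounded = (np.linalg.matrix_rank(np.hstack([X, Zc]))
                  == np.linalg.matrix_rank(X))
    if confounded:
        def objective(lgy):
            return _profiled_nll(np.array([-_LOG_RATIO_BOUND, lgy[0]]),
                                 X, Gc, Gy, y, reml)
        best = None
        for x0 in ([0.0], [-3.0]):
            res = optimize.minimize(
                objective, x0=np.array(x0), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        best.x = np.array([-_LOG_RATIO_BOUND, best.x[0]])
    else:
        best = None
        for x0 in ([0.0, 0.0], [-3.0, -3.0], [2.0, 2.0]):
            res = optimize.minimize(
                _profiled_nll, x0=np.array(x0), args=(X, Gc, Gy, y, reml),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
    lg = np.clip(best.x, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)
    boundary = confounded or bool(
        np.any(np.abs(best.x) >= _LOG_RATIO_BOUND - 1e-3))

    n, p = X.shape
    V = np.eye(n) + np.exp(lg[0]) * Gc + np.exp(lg[1]) * Gy
    c = np.linalg.cholesky(V)
    Xi = np.linalg.solve(c, X)
    yi = np.linalg.solve(c, y)
    XtVX = Xi.T @ Xi
    beta = np.linalg.solve(XtVX, Xi.T @ yi)
    r = yi - Xi @ beta
    s2 = float(r @ r) / ((n - p) if reml else n)
    vbeta = s2 * np.linalg.inv(XtVX)
    fit = LMMFit(
        beta=beta, beta_names=names, vbeta=vbeta,
        sigma2_colony=float(np.exp(lg[0]) * s2),
        sigma2_year=float(np.exp(lg[1]) * s2),
        sigma2_resid=float(s2),
        log_likelihood=-float(best.fun),
        reml=reml, converged=bool(best.success), boundary=boundary,
        regions=regions, has_region=has_region, n_obs=n,
        X=X, Zc=Zc, Zy=Zy, y=y,
    )
    if boundary:
        logger.warning("fit_lmm: variance ratio at optimisation boundary "
                       "(theta=%s)", fit.theta)
    return fit


def lrt(full: LMMFit, null: LMMFit) -> dict:
    """Likelihood-ratio test of two nested fixed-effect specifications.

    Both fits must be by maximum likelihood (REML likelihoods are not
    comparable across fixed-effect structures).  df is the difference in
    fixed-effect dimension.
    """
    if full.reml or null.reml:
        raise ValueError("likelihood-ratio comparison requires ML fits (reml=False)")
    df = len(full.beta) - len(null.beta)
    if df <= 0:
        raise ValueError("full model must nest the null with extra fixed effects")
    chi2 = max(2.0 * (full.log_likelihood - null.log_likelihood), 0.0)
    return {"chi2": float(chi2), "df": int(df),
            "p": float(stats.chi2.sf(chi2, df))}


def lrt_region(data: pd.DataFrame, response: str = "ln_mean") -> dict:
    """Region LRT: ML full (with region) vs ML null (intercept only)."""
    full = fit_lmm(data, response, reml=False, has_region=True)
    null = fit_lmm(data, response, reml=False, has_region=False)
    return lrt(full, null)


def _vbeta_at(theta: np.ndarray, X: np.ndarray, Gc: np.ndarray,
              Gy: np.ndarray) -> np.ndarray:
    s2c, s2y, s2e = theta
    n = X.shape[0]
    V = s2e * np.eye(n) + s2c * Gc + s2y * Gy
    c = np.linalg.cholesky(V)
    Xi = np.linalg.solve(c, X)
    return np.linalg.inv(Xi.T @ Xi)


def _active_components(fit: LMMFit) -> np.ndarray:
    """Variance components treated as free parameters in df computations.

    A component estimated at (or numerically indistinguishable from) the
    zero boundary is pinned: it contributes no sampling uncertainty, which
    recovers the classical OLS residual df in the variance-free limit.
    """
    tol = 1e-5 * fit.sigma2_resid
    return np.array([fit.sigma2_colony > tol, fit.sigma2_year > tol, True])


def _theta_vcov(fit: LMMFit) -> np.ndarray:
    """Asymptotic covariance of the free variance components: inverse
    observed information of the restricted likelihood, by central finite
    differences.  Rows/columns of pinned components are zero."""
    Gc, Gy = fit.Zc @ fit.Zc.T, fit.Zy @ fit.Zy.T
    th = fit.theta
    active = np.flatnonzero(_active_components(fit))
    h = np.maximum(np.abs(th), 1e-4 * fit.sigma2_resid) * 1e-4

    def f(t):
        return _loglik_theta(t, fit.X, Gc, Gy, fit.y, reml=True)

    m = active.size
    H = np.zeros((m, m))
    f0 = f(th)
    for a in range(m):
        i = active[a]
        for b in range(a, m):
            j = active[b]
            ei = np.zeros(3); ei[i] = h[i]
            ej = np.zeros(3); ej[j] = h[j]
            if i == j:
                H[a, a] = (f(th + ei) - 2 * f0 + f(th - ei)) / h[i] ** 2
            else:
                H[a, b] = H[b, a] = (
                    f(th + ei + ej) - f(th + ei - ej)
                    - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        Ar = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        Ar = np.linalg.pinv(-H)
    A = np.zeros((3, 3))
    A[np.ix_(active, active)] = Ar
    return A


def _satterthwaite_1d(contrast: np.ndarray, fit: LMMFit,
                      A: np.ndarray | None = None) -> float:
    """Satterthwaite df of a single contrast c'beta: 2 f^2 / (g' A g) with
    f(theta) = c' Vbeta(theta) c and g its gradient over the free
    variance components."""
    Gc, Gy = fit.Zc @ fit.Zc.T, fit.Zy @ fit.Zy.T
    if A is None:
        A = _theta_vcov(fit)
    th = fit.theta
    active = _active_components(fit)
    h = np.maximum(np.abs(th), 1e-4 * fit.sigma2_resid) * 1e-4

    def f(t):
        return float(contrast @ _vbeta_at(t, fit.X, Gc, Gy) @ contrast)

    g = np.zeros(3)
    for i in range(3):
        if not active[i]:
            continue
        e = np.zeros(3); e[i] = h[i]
        g[i] = (f(th + e) - f(th - e)) / (2 * h[i])
    denom = float(g @ A @ g)
    f0 = f(th)
    if denom <= 0:
        return float(fit.n_obs - len(fit.beta))
    return max(2.0 * f0 * f0 / denom, 1.0)


def anova_region(fit: LMMFit) -> dict:
    """Wald F test of the region effect with Satterthwaite denominator df.

    Follows the moment-matching construction for multi-df contrasts: the
    contrast covariance is eigen-decomposed into independent 1-df
    contrasts, each with its own Satterthwaite df, and the denominators
    combine through E = sum nu_i/(nu_i - 2), ddf = 2E/(E - q).  Boundary
    variance estimates make the ddf approximate (flagged).
    """
    if not fit.has_region:
        raise ValueError("fit has no region effect")
    p = len(fit.beta)
    q = p - 1
    L = np.zeros((q, p))
    L[:, 1:] = np.eye(q)
    M = L @ fit.vbeta @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(M, Lb) / q)
    eigval, eigvec = np.linalg.eigh(M)
    A = _theta_vcov(fit)
    nus = []
    for i in range(q):
        c = eigvec[:, i] @ L
        nus.append(_satterthwaite_1d(c, fit, A))
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if E > q:
        ddf = 2.0 * E / (E - q)
    else:
        ddf = float(fit.n_obs - p)
    return {
        "F": F, "ndf": q, "ddf": float(ddf),
        "p": float(stats.f.sf(F, q, ddf)),
        "ddf_approximate": bool(fit.boundary),
    }


def variance_pct(fit: LMMFit) -> dict:
    """Random-effect variance shares of the total random variation (%)."""
    tot = fit.sigma2_colony + fit.sigma2_year + fit.sigma2_resid
    if tot <= 0:
        raise ValueError("all variance components are zero")
    return {
        "colony_pct": 100.0 * fit.sigma2_colony / tot,
        "year_pct": 100.0 * fit.sigma2_year / tot,
        "residual_pct": 100.0 * fit.sigma2_resid / tot,
    }


def region_emmeans(fit: LMMFit, alpha: float = 0.05,
                   adjust: str = "holm") -> pd.DataFrame:
    """Estimated marginal mean per region, back-transformed to ng/g.

    The ln-scale EMM of region i is b0 + b_region(i) (the last region's
    effect is minus the sum of the others under sum-to-zero contrasts).
    Intervals are Wald on the ln scale with per-contrast Satterthwaite df,
    exponentiated (so they are intervals of the median on the raw scale).
    Each region effect is also compared to zero - that is, each region to
    the overall mean - with unadjusted and Holm-adjusted p-values.
    """
    if not fit.has_region:
        raise ValueError("fit has no region effect")
    p = len(fit.beta)
    R = len(fit.regions)
    A = _theta_vcov(fit)
    rows = []
    for i, region in enumerate(fit.regions):
        c_emm = np.zeros(p); c_emm[0] = 1.0
        c_eff = np.zeros(p)
        if i < R - 1:
            c_eff[1 + i] = 1.0
        else:
            c_eff[1:] = -1.0
        c_emm = c_emm + c_eff
        est = float(c_emm @ fit.beta)
        se = float(np.sqrt(c_emm @ fit.vbeta @ c_emm))
        df = _satterthwaite_1d(c_emm, fit, A)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        eff = float(c_eff @ fit.beta)
        se_eff = float(np.sqrt(c_eff @ fit.vbeta @ c_eff))
        df_eff = _satterthwaite_1d(c_eff, fit, A)
        t_eff = eff / se_eff if se_eff > 0 else np.nan
        p_eff = float(2 * stats.t.sf(abs(t_eff), df_eff))
        rows.append({
            "region": region,
            "emm_ln": est, "se_ln": se, "df": df,
            "emm_ng_g": float(np.exp(est)),
            "ci_low_ng_g": float(np.exp(est - tcrit * se)),
            "ci_high_ng_g": float(np.exp(est + tcrit * se)),
            "effect_ln": eff, "t_vs_overall": float(t_eff),
            "p_vs_overall": p_eff,
        })
    out = pd.DataFrame(rows)
    # Holm step-down adjustment of the region-vs-overall comparisons
    if adjust == "holm":
        m = len(out)
        order = np.argsort(out["p_vs_overall"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_vs_overall"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_vs_overall_holm"] = adj
    return out
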