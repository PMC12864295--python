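"""One-breakpoint segmented regression of ln concentration on year.

Fits, per colony x HFR class, the piecewise-linear mean

    y = b0 + b1 * year + delta * (year - psi)_+

by Gaussian maximum likelihood, where ``psi`` is the breakpoint year and
``delta`` the change in slope at the breakpoint.  Estimation follows the
iterative-linearisation scheme of Muggeo (2003): at a working breakpoint the
model is linear in the covariates U = (year - psi)_+ and V = -1[year > psi],
and the coefficient ratio gamma/delta of V and U updates psi.  A profile
grid search over admissible breakpoints backs the iteration up and doubles
as an independent optimality oracle.

A plain linear fit is the fallback whenever a breakpoint is inadmissible,
the series is too short, or the segmented fit does not improve on the line.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SegmentedFit",
    "davies_test",
    "fit_linear",
    "fit_segmented",
    "oracle_profile_fit",
    "select_trend_fit",
    "sup_t_test",
]

# Convergence tolerance on the breakpoint update (years) and on gamma.
_PSI_TOL = 1e-8
_MAX_ITER = 60


@dataclass
class SegmentedFit:
    """Result of a per-series trend fit.

    ``fit_type`` is ``"segmented"``, ``"linear"`` or ``"failed"``.  Slopes
    are in ln-units per calendar year.  For a linear fit ``slope_before``
    carries the single slope and the breakpoint fields are None.  ``t_value``
    / ``p_value`` follow the reporting convention of monitoring summaries:
    the t test of the first-segment slope (segmented) or of the slope
    (linear).
    """

    fit_type: str
    n_years: int
    intercept: float = np.nan
    slope_before: float = np.nan
    se_before: float = np.nan
    slope_after: float | None = None
    se_after: float | None = None
    delta: float | None = None
    se_delta: float | None = None
    psi: float | None = None
    psi_se: float | None = None
    t_slope1: float = np.nan
    p_slope1: float = np.nan
    t_delta: float | None = None
    p_delta: float | None = None
    df_resid: int = 0
    ssr: float = np.nan
    log_likelihood: float = np.nan
    aic: float = np.nan
    converged: bool = False
    admissible: bool = False
    selection_note: str = ""

    @property
    def t_value(self) -> float:
        return self.t_slope1

    @property
    def p_value(self) -> float:
        return self.p_slope1


def _as_xy(years: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(years, dtype=float)
    v = np.asarray(y, dtype=float)
    if x.shape != v.shape or x.ndim != 1:
        raise ValueError("years and y must be 1-d sequences of equal length")
    if np.unique(x).size != x.size:
        raise ValueError("duplicate years in series; aggregate to one value per year first")
    order = np.argsort(x)
    return x[order], v[order]


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares returning (beta, cov(beta), ssr). cov uses df = n - p."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df = n - p
    if df <= 0 or rank < p:
        cov = np.full((p, p), np.nan)
    else:
        s2 = ssr / df
        cov = s2 * np.linalg.pinv(X.T @ X)
    return beta, cov, ssr


def _gauss_loglik(ssr: float, n: int) -> float:
    s2 = max(ssr / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_linear(years: Sequence[float], y: Sequence[float]) -> SegmentedFit:
    """Ordinary least-squares line with a two-sided t test of the slope."""
    x, v = _as_xy(years, y)
    n = x.size
    if n < 3:
        raise ValueError(f"linear trend fit needs >= 3 years, got {n}")
    X = np.column_stack([np.ones(n), x])
    beta, cov, ssr = _ols(X, v)
    se = float(np.sqrt(cov[1, 1]))
    df = n - 2
    if se > 0:
        t = float(beta[1] / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:  # exact line: slope known without error
        t, p = (np.inf * np.sign(beta[1]) if beta[1] != 0 else 0.0), (0.0 if beta[1] != 0 else 1.0)
    ll = _gauss_loglik(ssr, n)
    return SegmentedFit(
        fit_type="linear", n_years=n, intercept=float(beta[0]),
        slope_before=float(beta[1]), se_before=se,
        t_slope1=t, p_slope1=p, df_resid=df, ssr=ssr,
        log_likelihood=ll, aic=2 * 3 - 2 * ll, converged=True, admissible=True,
    )


def _admissible(x: np.ndarray, psi: float, min_seg_points: int) -> bool:
    return (
        np.sum(x < psi) >= min_seg_points
        and np.sum(x > psi) >= min_seg_points
        and x.min() < psi < x.max()
    )


def _finalize_segmented(x: np.ndarray, v: np.ndarray, psi: float,
                        min_seg_points: int) -> SegmentedFit | None:
    """Build the full fit (SEs, tests) for the continuous model at fixed psi.

    Point estimates, SSR and likelihood come from the continuous piecewise
    fit y ~ [1, x, (x - psi)_+] — candidates are ranked and the AIC formed
    on the model that is actually continuous.  Standard errors come from
    the augmented working model that adds the breakpoint-score column
    V = -1[x > psi]: V is the derivative of the mean with respect to psi,
    so its covariance contribution propagates first-order breakpoint
    uncertainty into the slope SEs (and gives psi's delta-method SE,
    SE(gamma)/|delta|).  The residual variance charges a df for the
    estimated breakpoint (mean structure b0, b1, delta, psi): without both
    of these the slope intervals are anti-conservative.
    """
    n = x.size
    U = np.clip(x - psi, 0.0, None)
    X = np.column_stack([np.ones(n), x, U])
    beta, _, ssr = _ols(X, v)
    b0, b1, dl = beta
    df = n - 5
    if df <= 0:
        return None
    Xw = np.column_stack([np.ones(n), x, U, -(x > psi).astype(float)])
    _, covw, _ = _ols(Xw, v)
    if not np.isfinite(covw).all():
        return None
    cov = covw * (n - 4) / df
    se_b1 = float(np.sqrt(cov[1, 1]))
    se_dl = float(np.sqrt(cov[2, 2]))
    slope_after = float(b1 + dl)
    var_after = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
    se_after = float(np.sqrt(max(var_after, 0.0)))
    psi_se = (float(np.sqrt(cov[3, 3]) / abs(dl)) if dl != 0 else np.nan)

    def _test(est: float, se: float) -> tuple[float, float]:
        if se > 0:
            t = est / se
            return float(t), float(2.0 * stats.t.sf(abs(t), df))
        return (np.inf * np.sign(est) if est != 0 else 0.0), (0.0 if est != 0 else 1.0)

    t1, p1 = _test(float(b1), se_b1)
    td, pd_ = _test(float(dl), se_dl)
    ll = _gauss_loglik(ssr, n)
    # k = 5: intercept, two slopes, breakpoint, residual variance.
    return SegmentedFit(
        fit_type="segmented", n_years=n, intercept=float(b0),
        slope_before=float(b1), se_before=se_b1,
        slope_after=slope_after, se_after=se_after,
        delta=float(dl), se_delta=se_dl,
        psi=float(psi), psi_se=psi_se,
        t_slope1=t1, p_slope1=p1, t_delta=td, p_delta=pd_,
        df_resid=df, ssr=ssr, log_likelihood=ll, aic=2 * 5 - 2 * ll,
        converged=True, admissible=_admissible(x, psi, min_seg_points),
    )


def _iterate_psi(x: np.ndarray, v: np.ndarray, psi0: float) -> float | None:
    """Muggeo update loop from one starting breakpoint; None on failure."""
    psi = float(psi0)
    lo, hi = x.min(), x.max()
    span = hi - lo
    for _ in range(_MAX_ITER):
        U = np.clip(x - psi, 0.0, None)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        try:
            beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
        except np.linalg.LinAlgError:
            return None
        _, _, dl, gm = beta
        if abs(dl) < 1e-12:
            return None
        step = gm / dl
        # damp wild steps so the iteration stays inside the data range
        step = float(np.clip(step, -span / 2, span / 2))
        new = psi + step
        new = float(np.clip(new, lo + 1e-9, hi - 1e-9))
        if abs(new - psi) < _PSI_TOL:
            return new
        psi = new
    return psi  # ran out of iterations; caller checks the fit


def _interval_optima(x: np.ndarray, v: np.ndarray, min_seg_points: int) -> list[float]:
    """Profile-SSR minimisers within each admissible inter-observation gap."""
    from scipy.optimize import minimize_scalar

    ones = np.ones_like(x)

    def ssr_at(psi: float) -> float:
        X = np.column_stack([ones, x, np.clip(x - psi, 0.0, None)])
        return _ols(X, v)[2]

    xs = np.sort(np.unique(x))
    out: list[float] = []
    eps = 1e-6
    for a, b in zip(xs[:-1], xs[1:]):
        mid = 0.5 * (a + b)
        if not _admissible(x, mid, min_seg_points):
            continue
        res = minimize_scalar(ssr_at, bounds=(a + eps, b - eps), method="bounded",
                              options={"xatol": 1e-8})
        # SSR can be monotone across the interval: its infimum then sits at
        # an open endpoint, which the bracketing minimiser cannot reach
        out.extend((float(res.x), a + eps, b - eps))
    return out


def fit_segmented(
    years: Sequence[float],
    y: Sequence[float],
    min_years: int = 6,
    min_seg_points: int = 2,
    starts: Sequence[float] | None = None,
    grid_fallback: bool = True,
) -> SegmentedFit:
    """Fit the one-breakpoint model by iterative linearisation.

    Starts the iteration at the observed-year tertiles (deterministic order)
    and keeps the admissible converged solution with the best likelihood,
    ties broken toward the earlier breakpoint.  When no start converges to
    an admissible breakpoint, a profile grid over admissible candidate
    breakpoints is searched instead; if that too is inadmissible the result
    has ``fit_type="failed"`` and callers fall back to :func:`fit_linear`.
    """
    x, v = _as_xy(years, y)
    n = x.size
    if n < min_years:
        return SegmentedFit(fit_type="failed", n_years=n,
                            selection_note=f"fewer than {min_years} years")
    if starts is None:
        starts = list(np.quantile(x, [1.0 / 3.0, 0.5, 2.0 / 3.0]))

    candidates: list[float] = []
    for psi0 in starts:
        psi = _iterate_psi(x, v, float(psi0))
        if psi is not None:
            candidates.append(psi)
    # The iteration is only locally convergent and noisy series have local
    # optima; complement it with an exact per-interval profile: between two
    # adjacent observed years the partition of points does not change, so
    # SSR(psi) is smooth there and a bounded scalar minimisation finds the
    # interval's optimum.  Observed years themselves are kink points of the
    # profile and enter as candidates directly.
    candidates.extend(_interval_optima(x, v, min_seg_points))
    candidates.extend(float(t) for t in np.unique(x)
                      if _admissible(x, float(t), min_seg_points))

    best: SegmentedFit | None = None
    for psi in candidates:
        fit = _finalize_segmented(x, v, psi, min_seg_points)
        if fit is None or not fit.admissible:
            continue
        if (
            best is None
            or fit.log_likelihood > best.log_likelihood + 1e-9
            or (abs(fit.log_likelihood - best.log_likelihood) <= 1e-9 and fit.psi < best.psi)
        ):
            best = fit
    if best is None and grid_fallback:
        best = oracle_profile_fit(x, v, min_seg_points=min_seg_points)
        if best.fit_type == "failed":
            best = None
        else:
            best.selection_note = "profile-grid fallback"
    if best is None:
        return SegmentedFit(fit_type="failed", n_years=n,
                            selection_note="no admissible breakpoint")
    return best


def oracle_profile_fit(
    years: Sequence[float],
    y: Sequence[float],
    grid: Sequence[float] | None = None,
    min_seg_points: int = 2,
    step: float = 0.05,
) -> SegmentedFit:
    """Exhaustive least-squares profile over candidate breakpoints.

    Slower than the iterative fit but free of convergence questions; the
    default grid covers the admissible breakpoint range at ``step``-year
    resolution and includes every interior observed year exactly.
    """
    x, v = _as_xy(years, y)
    if grid is None:
        xs = np.sort(np.unique(x))
        if xs.size < 2 * min_seg_points + 1:
            return SegmentedFit(fit_type="failed", n_years=x.size,
                                selection_note="series too short for any admissible breakpoint")
        lo = xs[min_seg_points - 1]
        hi = xs[-min_seg_points]
        eps = 1e-6  # open admissibility boundaries, probed just inside
        cand = np.arange(lo + step, hi, step)
        cand = np.union1d(cand, xs[(xs > lo) & (xs < hi)])
        cand = cand[(cand > lo + eps) & (cand < hi - eps)]
        grid = np.union1d(cand, [lo + eps, hi - eps])
    grid = [g for g in np.asarray(grid, dtype=float) if _admissible(x, g, min_seg_points)]
    if not len(grid):
        return SegmentedFit(fit_type="failed", n_years=x.size,
                            selection_note="empty admissible grid")
    best_psi, best_ssr = None, np.inf
    ones = np.ones_like(x)
    for psi in grid:
        U = np.clip(x - psi, 0.0, None)
        X = np.column_stack([ones, x, U])
        _, _, ssr = _ols(X, v)
        if ssr < best_ssr - 1e-12:
            best_ssr, best_psi = ssr, psi
    fit = _finalize_segmented(x, v, float(best_psi), min_seg_points)
    if fit is None:
        return SegmentedFit(fit_type="failed", n_years=x.size,
                            selection_note="degenerate profile optimum")
    return fit


def _grid_t_stats(x: np.ndarray, v: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """t statistic of the slope-change coefficient at each fixed breakpoint."""
    ts = np.empty(grid.size)
    ones = np.ones_like(x)
    for i, psi in enumerate(grid):
        X = np.column_stack([ones, x, np.clip(x - psi, 0.0, None)])
        beta, cov, _ = _ols(X, v)
        se = np.sqrt(cov[2, 2])
        ts[i] = beta[2] / se if se > 0 else 0.0
    return ts


def _candidate_grid(x: np.ndarray, k: int, min_seg_points: int) -> np.ndarray | None:
    xs = np.sort(np.unique(x))
    if xs.size < 2 * min_seg_points + 1:
        return None
    lo, hi = xs[min_seg_points - 1], xs[-min_seg_points]
    return np.linspace(lo + 1e-6, hi - 1e-6, k)


# Monte-Carlo null tables for sup_t_test, keyed by year design and grid.
_SUP_T_NULL_CACHE: dict[tuple, np.ndarray] = {}


def sup_t_test(
    years: Sequence[float],
    y: Sequence[float],
    k: int = 10,
    n_null: int = 999,
    min_seg_points: int = 2,
) -> float:
    """Exact Monte-Carlo supremum test for the existence of a slope change.

    The statistic is the largest |t| of the slope-change coefficient over
    ``k`` fixed candidate breakpoints.  Under the no-breakpoint Gaussian
    null the statistic is pivotal — invariant to the intercept, the slope
    and the error scale — so its null distribution depends only on the
    observation years and the grid, and is simulated once per design
    (``n_null`` standard-normal draws, cached, deterministically seeded
    from the design).  The returned p-value (1 + exceedances)/(n_null + 1)
    is calibrated at the nominal level up to Monte-Carlo discreteness.
    """
    x, v = _as_xy(years, y)
    grid = _candidate_grid(x, k, min_seg_points)
    if grid is None:
        return 1.0
    ts = _grid_t_stats(x, v, grid)
    if not np.isfinite(ts).all():
        return 1.0
    stat = float(np.max(np.abs(ts)))

    key = (x.tobytes(), k, n_null)
    table = _SUP_T_NULL_CACHE.get(key)
    if table is None:
        seed = np.random.SeedSequence([0x5B9, zlib.crc32(x.tobytes()), k, n_null])
        rng = np.random.default_rng(seed)
        table = np.empty(n_null)
        for b in range(n_null):
            ts0 = _grid_t_stats(x, rng.standard_normal(x.size), grid)
            table[b] = np.max(np.abs(ts0))
        table.sort()
        _SUP_T_NULL_CACHE[key] = table
    n_ge = table.size - np.searchsorted(table, stat, side="left")
    return float((1.0 + n_ge) / (n_null + 1.0))


def davies_test(
    years: Sequence[float],
    y: Sequence[float],
    k: int = 10,
    min_seg_points: int = 2,
) -> float:
    """Supremum test for the existence of a slope change (Davies' bound).

    The t statistic of the slope-change coefficient is evaluated at ``k``
    fixed candidate breakpoints spread over the admissible range; because
    the breakpoint is a nuisance parameter absent under the null, the naive
    t test at the best-fitting breakpoint is anti-conservative, and the
    returned p-value instead applies Davies' (1987) upper bound for the
    supremum of the statistic process,

        p = 2 * [Phi(-M) + V * exp(-M^2/2) / sqrt(8 pi)],

    with M the largest |t| over the grid and V the total variation of the
    t process.  Returns a p-value in (0, 1].
    """
    x, v = _as_xy(years, y)
    grid = _candidate_grid(x, k, min_seg_points)
    if grid is None:
        return 1.0
    ts = _grid_t_stats(x, v, grid)
    if not np.isfinite(ts).all():
        return 1.0
    m = float(np.max(np.abs(ts)))
    vtot = float(np.sum(np.abs(np.diff(ts))))
    s = x.size - 3  # residual df of the fixed-breakpoint fit
    tail = stats.t.sf(m, s)
    corr = vtot * (1.0 + m * m / s) ** (-0.5 * (s - 1)) / np.sqrt(8.0 * np.pi)
    return float(min(2.0 * (tail + corr), 1.0))


def select_trend_fit(
    years: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    min_years_breakpoint: int = 6,
    min_seg_points: int = 2,
    require_aic: bool = True,
    require_delta_test: bool = True,
    delta_gate: str = "supt",
) -> SegmentedFit:
    """Choose between the segmented and linear descriptions of a series.

    The segmented fit is retained only when it is admissible and improves
    on the straight line under the configured criterion (by default: lower
    AIC *and* a significant slope-change test); otherwise the linear fit is
    returned.  The slope-change gate defaults to :func:`sup_t_test`
    (``delta_gate="supt"``), exact under the no-breakpoint null;
    ``delta_gate="davies"`` uses the analytic Davies bound (conservative),
    and ``delta_gate="conditional"`` the t test of delta at the estimated
    breakpoint (anti-conservative, since the breakpoint is chosen by the
    fit).  The decision is recorded in ``selection_note``.
    """
    x, v = _as_xy(years, y)
    lin = fit_linear(x, v)
    if x.size < min_years_breakpoint:
        lin.selection_note = "linear: series shorter than breakpoint minimum"
        return lin
    seg = fit_segmented(x, v, min_years=min_years_breakpoint,
                        min_seg_points=min_seg_points)
    if seg.fit_type != "segmented" or not seg.admissible:
        lin.selection_note = f"linear: {seg.selection_note or 'segmented fit failed'}"
        return lin
    reasons = []
    if require_aic and not seg.aic < lin.aic:
        reasons.append("AIC does not improve")
    if require_delta_test:
        if delta_gate == "supt":
            p_gate = sup_t_test(x, v, min_seg_points=min_seg_points)
        elif delta_gate == "davies":
            p_gate = davies_test(x, v, min_seg_points=min_seg_points)
        elif delta_gate == "conditional":
            p_gate = seg.p_delta if seg.p_delta is not None else 1.0
        else:
            raise ValueError(f"unknown delta_gate {delta_gate!r}")
        if not p_gate <= alpha:
            reasons.append("slope-change test not significant")
    if reasons:
        lin.selection_note = "linear: " + "; ".join(reasons)
        return lin
    seg.selection_note = "segmented: improves AIC and slope-change test significant"
    return seg
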