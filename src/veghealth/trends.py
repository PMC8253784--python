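"""Trend machinery: OLS fit, Mann–Kendall test, Sen's slope.

The linear model is y_t = a + b t + e_t with t in years, so slopes are
reported per year; weekly series are annualized by expressing t in
fractional years. The Mann–Kendall test is the two-sided normal
approximation with tie-corrected variance and ±1 continuity correction;
Sen's slope is the median of all pairwise slopes (Theil–Sen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cube import WeeklyCube


@dataclass
class TrendResult:
    """OLS, Mann–Kendall and Sen's-slope summary for one series."""

    ols_slope: float
    ols_intercept: float
    residuals_sd: float
    mk_s: int
    mk_z: float
    mk_p: float
    significant_5pct: bool
    sens_slope: float


def linear_trend(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept) of y on t."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct times")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept)


def _mk_s_and_var(y: np.ndarray) -> tuple[int, float]:
    n = y.size
    diffs = np.sign(y[None, :] - y[:, None])
    s = int(np.triu(diffs, k=1).sum())
    # tie-corrected variance
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var)


def mann_kendall(y: np.ndarray, alpha: float = 0.05,
                 min_n: int = 8) -> TrendResult:
    """Two-sided Mann–Kendall trend test (normal approximation).

    S = Σ_{i<j} sign(y_j − y_i); Var(S) carries the tie correction; the
    standardized statistic uses a ±1 continuity correction. Below
    `min_n` points the normal approximation is unreliable and a
    ValueError is raised (lower `min_n` explicitly to override).

    Only the ``mk_*``/``significant_5pct`` fields of the returned
    :class:`TrendResult` are populated (others are NaN); use
    :func:`trend_result` for the full summary.
    """
    y = np.asarray(y, dtype=float)
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} points for the normal "
                         "approximation")
    s, var = _mk_s_and_var(y)
    if var <= 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(np.nan, np.nan, np.nan, s, float(z), p,
                       bool(p < alpha), np.nan)


def sens_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise slopes (y_j − y_i)/(t_j − t_i), i < j."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    return float(stats.theilslopes(y, t).slope)


def trend_result(t: np.ndarray, y: np.ndarray,
                 alpha: float = 0.05, min_n: int = 8) -> TrendResult:
    """Full trend summary: OLS + Mann–Kendall + Sen's slope."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = linear_trend(t, y)
    resid = y - (intercept + slope * t)
    mk = mann_kendall(y, alpha=alpha, min_n=min_n)
    return TrendResult(
        ols_slope=slope,
        ols_intercept=intercept,
        residuals_sd=float(resid.std(ddof=2)) if y.size > 2 else np.nan,
        mk_s=mk.mk_s,
        mk_z=mk.mk_z,
        mk_p=mk.mk_p,
        significant_5pct=mk.significant_5pct,
        sens_slope=sens_slope(t, y),
    )


def trend_map(cube: WeeklyCube, alpha: float = 0.05,
              fdr: bool = False) -> dict[str, np.ndarray]:
    """Per-pixel trends of a weekly cube (t in fractional years).

    Returns 2-D arrays ``ols_slope``, ``sens_slope``, ``mk_z``, ``mk_p``
    and boolean ``significant``. By default each pixel is tested at
    `alpha` with no multiple-testing correction (per-grid significance
    maps); ``fdr=True`` switches to Benjamini–Hochberg across pixels.
    """
    t = cube.time_years
    v = cube.masked_values()
    ny, nx = cube.grid_shape
    out = {k: np.full((ny, nx), np.nan) for k in
           ("ols_slope", "sens_slope", "mk_z", "mk_p")}
    for iy in range(ny):
        for ix in range(nx):
            series = v[:, iy, ix]
            ok = np.isfinite(series)
            if ok.sum() < 8:
                continue
            res = trend_result(t[ok], series[ok], alpha=alpha)
            out["ols_slope"][iy, ix] = res.ols_slope
            out["sens_slope"][iy, ix] = res.sens_slope
            out["mk_z"][iy, ix] = res.mk_z
            out["mk_p"][iy, ix] = res.mk_p
    p = out["mk_p"]
    sig = np.zeros((ny, nx), dtype=bool)
    finite = np.isfinite(p)
    if fdr and finite.any():
        pv = p[finite]
        order = np.argsort(pv)
        m = pv.size
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = pv[order] <= thresh
        k = np.flatnonzero(passed).max() + 1 if passed.any() else 0
        crit = pv[order][k - 1] if k else -1.0
        sig[finite] = pv <= crit
    else:
        sig[finite] = p[finite] < alpha
    out["significant"] = sig
    return out
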