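"""Univariable two-sample MR estimators.

Wald ratio, inverse-variance weighted (IVW), Egger regression, weighted
median, and mode-based estimators (simple and weighted), plus a driver that
runs the full suite including IVW on the Steiger-filtered variant subset.

Conventions (documented so differences from other dialects are
explainable): random-effects variance inflation is multiplicative and
floored at 1 (no under-dispersion); p-values and confidence intervals are
two-sided normal throughout; bootstrap standard errors use parametric
resampling of the observed betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.gwas_data import HarmonizedSet
from mrscreen.instruments import steiger_filter

__all__ = [
    "MRResult",
    "egger",
    "ivw",
    "mode_estimator",
    "run_all_methods",
    "wald_ratio",
    "weighted_median",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal estimate."""

    method: str
    estimate: float = float("nan")
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    pval: float = float("nan")
    n_snp: int = 0
    q: float | None = None
    q_df: int | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    estimable: bool = True
    note: str = ""

    @staticmethod
    def not_estimable(method: str, n_snp: int, note: str) -> "MRResult":
        return MRResult(method=method, n_snp=n_snp, estimable=False, note=note)


def _finish(method, estimate, se, n_snp, q=None, q_df=None, note="", **kw) -> MRResult:
    if se > 0 and np.isfinite(se):
        pval = float(2 * stats.norm.sf(abs(estimate) / se))
        lo, hi = estimate - _Z95 * se, estimate + _Z95 * se
    else:
        pval, lo, hi = 1.0, estimate, estimate
    return MRResult(
        method=method, estimate=float(estimate), se=float(se),
        ci_low=float(lo), ci_high=float(hi), pval=pval, n_snp=int(n_snp),
        q=q, q_df=q_df, note=note, **kw,
    )


def _arrays(h: HarmonizedSet | pd.DataFrame):
    t = h.table if isinstance(h, HarmonizedSet) else h
    return (
        t["beta_x"].to_numpy(float),
        t["se_x"].to_numpy(float),
        t["beta_y"].to_numpy(float),
        t["se_y"].to_numpy(float),
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MRResult:
    """Single-variant ratio estimate with first-order delta-method SE."""
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    est = beta_y / beta_x
    se = abs(se_y / beta_x)
    return _finish("wald_ratio", est, se, 1)


def ivw(h: HarmonizedSet | pd.DataFrame) -> MRResult:
    """Inverse-variance weighted estimate (origin-constrained WLS).

    Weighted least squares of beta_y on beta_x through the origin with
    weights 1/se_y^2. The variance is inflated multiplicatively by
    max(1, Q/(J-1)) where Q is Cochran's heterogeneity statistic.
    With a single SNP, falls back to the Wald ratio (noted).
    """
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j == 0:
        return MRResult.not_estimable("ivw", 0, "empty instrument")
    if j == 1:
        res = wald_ratio(bx[0], sx[0], by[0], sy[0])
        res.method = "ivw"
        res.note = "single SNP: wald_ratio fallback"
        return res
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    est = np.sum(w * bx * by) / sxx
    q = float(np.sum(w * (by - est * bx) ** 2))
    infl = max(1.0, q / (j - 1))
    se = np.sqrt(infl / sxx)
    return _finish("ivw", est, se, j, q=q, q_df=j - 1)


def egger(h: HarmonizedSet | pd.DataFrame) -> MRResult:
    """MR-Egger regression: WLS of beta_y on beta_x with an intercept.

    Pairs are first oriented so all beta_x >= 0; the intercept estimates
    the average directional pleiotropy. Variance inflation as in IVW with
    J - 2 degrees of freedom.
    """
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        return MRResult.not_estimable("egger", j, "needs >= 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    w = 1.0 / sy**2
    sw = w.sum()
    mx = np.sum(w * bx) / sw
    my = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    if sxx <= 0 or not np.isfinite(sxx):
        return MRResult.not_estimable("egger", j, "collinear: no spread in beta_x")
    slope = np.sum(w * (bx - mx) * (by - my)) / sxx
    inter = my - slope * mx
    resid = by - inter - slope * bx
    q = float(np.sum(w * resid**2))
    infl = max(1.0, q / (j - 2))
    se_slope = np.sqrt(infl / sxx)
    se_inter = np.sqrt(infl * (1.0 / sw + mx**2 / sxx))
    p_inter = float(2 * stats.norm.sf(abs(inter) / se_inter))
    return _finish(
        "egger", slope, se_slope, j, q=q, q_df=j - 2,
        intercept=float(inter), intercept_se=float(se_inter),
        intercept_pval=p_inter,
    )


def _wmedian_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    ww = w[order] / w[order].sum()
    s = np.cumsum(ww) - ww / 2
    return float(np.interp(0.5, s, th))


def weighted_median(
    h: HarmonizedSet | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MRResult:
    """Weighted median of per-SNP ratio estimates.

    Ratio estimates theta_j = beta_y/beta_x receive weights
    (beta_x/se_y)^2; the estimate interpolates theta across the centred
    cumulative weights at 0.5. The SE is the standard deviation of the
    estimate over ``n_boot`` parametric bootstrap draws.
    """
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        return MRResult.not_estimable("weighted_median", j, "needs >= 3 SNPs")
    theta = by / bx
    w = (bx / sy) ** 2
    est = _wmedian_point(theta, w)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = _wmedian_point(bys[b] / bxs[b], (bxs[b] / sy) ** 2)
    se = float(np.std(draws, ddof=1))
    return _finish("weighted_median", est, se, j)


def _mode_point(theta: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    j = len(theta)
    s = np.std(theta, ddof=1) if j > 1 else 0.0
    mad = np.median(np.abs(theta - np.median(theta))) / 0.6745
    widths = [v for v in (s, mad) if v > 0]
    if not widths:
        return float(theta[0])  # all ratios identical
    hband = bandwidth_factor * 0.9 * min(widths) * j ** (-1 / 5)
    grid = np.linspace(theta.min() - 3 * hband, theta.max() + 3 * hband, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / hband) ** 2) @ w
    return float(grid[int(np.argmax(dens))])  # argmax returns first => lowest mode


def mode_estimator(
    h: HarmonizedSet | pd.DataFrame,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MRResult:
    """Mode of the kernel-smoothed density of per-SNP ratio estimates.

    Normal kernel with modified-Silverman bandwidth
    ``bandwidth_factor * 0.9 * min(sd, mad/0.6745) * J^(-1/5)`` evaluated on
    a 512-point grid spanning min-3h to max+3h; density ties break to the
    smallest grid value. Weights are uniform (simple mode) or the inverse
    approximate variance of theta_j (weighted mode). Bootstrap SE as in
    :func:`weighted_median`.
    """
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    name = "weighted_mode" if weighted else "simple_mode"
    if j < 3:
        return MRResult.not_estimable(name, j, "needs >= 3 SNPs")
    theta = by / bx

    def weights_for(bx_, sy_):
        if weighted:
            return (bx_ / sy_) ** 2
        return np.full(len(bx_), 1.0 / len(bx_))

    est = _mode_point(theta, weights_for(bx, sy), bandwidth_factor)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = _mode_point(bys[b] / bxs[b], weights_for(bxs[b], sy),
                               bandwidth_factor)
    se = float(np.std(draws, ddof=1))
    return _finish(name, est, se, j)


def run_all_methods(
    h: HarmonizedSet,
    seed: int = 0,
    n_boot: int = 1000,
) -> list[MRResult]:
    """Run the full estimator suite on a harmonized set.

    For multi-SNP instruments: IVW (primary), Egger, weighted median,
    simple mode, weighted mode, and IVW on the Steiger-filtered subset
    (``ivw_steiger``); methods inapplicable at the SNP count are recorded
    as not-estimable rather than omitted. A single-SNP instrument yields
    the Wald ratio plus its Steiger-filtered counterpart only. Bootstrap
    seeds fan out from ``seed`` so the call is deterministic.
    """
    j = h.n_snp
    if j == 0:
        return []
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    results: list[MRResult] = []
    filtered, _ = steiger_filter(h)

    def steiger_ivw() -> MRResult:
        if filtered.n_snp == 0:
            return MRResult.not_estimable(
                "ivw_steiger", 0, "no SNPs survive steiger filtering")
        res = ivw(filtered)
        res.method = "ivw_steiger"
        return res

    if j == 1:
        row = h.table.iloc[0]
        results.append(wald_ratio(row.beta_x, row.se_x, row.beta_y, row.se_y))
        results.append(steiger_ivw())
        return results

    results.append(ivw(h))
    results.append(egger(h))
    results.append(
        weighted_median(h, n_boot=n_boot, seed=np.random.default_rng(kids[0])))
    results.append(mode_estimator(h, weighted=False, n_boot=n_boot,
                                  seed=np.random.default_rng(kids[1])))
    results.append(mode_estimator(h, weighted=True, n_boot=n_boot,
                                  seed=np.random.default_rng(kids[2])))
    results.append(steiger_ivw())
    return results
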