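"""Multivariable MR on summary statistics.

Weighted least-squares direct effects, conditional instrument-strength (F)
diagnostics, and the staged category -> pooled -> refit model builder.
Cross-exposure sampling covariance is set to zero throughout (no overlap
information is available from summary data); every fit notes this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.gwas_data import LDReference
from mrscreen.instruments import clump

__all__ = [
    "MVMRFit",
    "MVMRModel",
    "StagedResult",
    "build_mvmr_inputs",
    "conditional_f",
    "mvmr_fit",
    "staged_model_builder",
]

_COND_LIMIT = 1e8


@dataclass
class MVMRFit:
    """Direct-effect estimates from one multivariable fit."""

    exposure_ids: list[str]
    estimates: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    q: float
    q_df: int
    n_snp: int
    estimable: bool = True
    note: str = "cross-exposure sampling covariance assumed zero"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure_id": self.exposure_ids,
            "estimate": self.estimates,
            "se": self.se,
            "pval": self.pval,
        })


@dataclass
class MVMRModel:
    """A fitted multivariable model plus instrument-strength diagnostics."""

    exposure_ids: list[str]
    instrument_ids: list[str]
    fit: MVMRFit
    conditional_f: np.ndarray
    univariable_f: np.ndarray


def mvmr_fit(B_x: np.ndarray, b_y: np.ndarray, se_y: np.ndarray,
             exposure_ids: list[str] | None = None) -> MVMRFit:
    """Weighted least squares of b_y on the exposure-beta columns.

    No intercept; weights 1/se_y^2; per-exposure variance inflated
    multiplicatively by max(1, Q/(J-K)). Requires J > K and non-collinear
    columns (condition number of the weighted design below 1e8).
    """
    B_x = np.atleast_2d(np.asarray(B_x, float))
    if B_x.shape[0] == 1 and B_x.shape[1] > 1 and len(b_y) == B_x.shape[1]:
        B_x = B_x.T
    b_y = np.asarray(b_y, float)
    se_y = np.asarray(se_y, float)
    j, k = B_x.shape
    ids = exposure_ids or [f"x{i}" for i in range(k)]
    if j <= k:
        return MVMRFit(ids, np.full(k, np.nan), np.full(k, np.nan),
                       np.full(k, np.nan), np.nan, 0, j, estimable=False,
                       note="needs more instruments than exposures")
    w = 1.0 / se_y**2
    sw = np.sqrt(w)
    xw = B_x * sw[:, None]
    if np.linalg.cond(xw) > _COND_LIMIT:
        return MVMRFit(ids, np.full(k, np.nan), np.full(k, np.nan),
                       np.full(k, np.nan), np.nan, 0, j, estimable=False,
                       note="collinear exposure-beta columns")
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ (b_y * sw))
    resid = b_y - B_x @ beta
    q = float(np.sum(w * resid**2))
    df = j - k
    infl = max(1.0, q / df)
    cov = infl * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    pval = 2 * stats.norm.sf(np.abs(beta) / se)
    return MVMRFit(ids, beta, se, pval, q, df, j)


def conditional_f(B_x: np.ndarray, se_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional and univariable instrument-strength F per exposure.

    For exposure k, its instrument betas are regressed (weights 1/se_xk^2)
    on the other exposures' betas; the weighted residual sum of squares Q_k
    gives conditional F_k = Q_k / (J - K + 1). The univariable F is the
    mean per-SNP (beta/se)^2, reported alongside for comparison.
    """
    B_x = np.atleast_2d(np.asarray(B_x, float))
    se_x = np.atleast_2d(np.asarray(se_x, float))
    if B_x.shape != se_x.shape:
        raise ValueError("B_x and se_x must have matching shapes")
    j, k = B_x.shape
    if j <= k:
        raise ValueError("needs more instruments than exposures")
    cond = np.empty(k)
    uni = np.empty(k)
    for ki in range(k):
        y = B_x[:, ki]
        w = 1.0 / se_x[:, ki] ** 2
        others = [c for c in range(k) if c != ki]
        if others:
            x = B_x[:, others]
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
            resid = y - x @ coef
        else:
            resid = y
        qk = float(np.sum(w * resid**2))
        cond[ki] = qk / (j - k + 1)
        uni[ki] = float(np.mean((y / se_x[:, ki]) ** 2))
    return cond, uni


# ---------------------------------------------------------------------------
# Instrument assembly from per-exposure summary statistics
# ---------------------------------------------------------------------------


@dataclass
class MVMRInputs:
    exposure_ids: list[str]
    instrument_ids: list[str]
    B_x: np.ndarray
    se_x: np.ndarray
    b_y: np.ndarray
    se_y: np.ndarray
    n_dropped: int = 0


def _align_to_reference(row, ref_ea, ref_oa):
    """Return beta oriented to the reference effect allele, or None."""
    if (row["effect_allele"], row["other_allele"]) == (ref_ea, ref_oa):
        return row["beta"]
    if (row["effect_allele"], row["other_allele"]) == (ref_oa, ref_ea):
        return -row["beta"]
    return None


def build_mvmr_inputs(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDReference,
    p_index: float = 5e-8,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
) -> MVMRInputs:
    """Assemble the joint instrument matrix for a multivariable model.

    Instruments are the union of each exposure's clumped hits, re-clumped
    jointly at the same r^2 threshold (each union SNP scored by its smallest
    p across exposures). SNPs must be present in every exposure table and
    the outcome table; betas are oriented to the alleles of the first
    exposure listing each SNP.
    """
    ex_ids = list(exposures)
    union_rows: dict[str, dict] = {}
    for eid in ex_ids:
        df = exposures[eid]
        for vid in clump(df, ld, p_index=p_index, r2_max=r2_max, window_bp=window_bp):
            row = df.loc[df["variant_id"] == vid].iloc[0]
            rec = union_rows.get(vid)
            if rec is None or row["pval"] < rec["pval"]:
                union_rows[vid] = {
                    "variant_id": vid, "chrom": row["chrom"],
                    "pos": row["pos"], "pval": row["pval"],
                }
    if not union_rows:
        return MVMRInputs(ex_ids, [], np.zeros((0, len(ex_ids))),
                          np.zeros((0, len(ex_ids))), np.zeros(0), np.zeros(0))
    union_df = pd.DataFrame(list(union_rows.values()))
    joint_ids = clump(union_df, ld, p_index=1.0, r2_max=r2_max, window_bp=window_bp)

    indexed = {eid: df.set_index("variant_id") for eid, df in exposures.items()}
    out_idx = outcome.set_index("variant_id")
    keep: list[str] = []
    bx_rows, sx_rows, by_vals, sy_vals = [], [], [], []
    n_dropped = 0
    for vid in joint_ids:
        if vid not in out_idx.index or any(vid not in t.index for t in indexed.values()):
            n_dropped += 1
            continue
        ref = next(t.loc[vid] for t in indexed.values() if vid in t.index)
        ref_ea, ref_oa = ref["effect_allele"], ref["other_allele"]
        bx, sx = [], []
        ok = True
        for eid in ex_ids:
            row = indexed[eid].loc[vid]
            b = _align_to_reference(row, ref_ea, ref_oa)
            if b is None:
                ok = False
                break
            bx.append(b)
            sx.append(row["se"])
        if not ok:
            n_dropped += 1
            continue
        orow = out_idx.loc[vid]
        by = _align_to_reference(orow, ref_ea, ref_oa)
        if by is None:
            n_dropped += 1
            continue
        keep.append(vid)
        bx_rows.append(bx)
        sx_rows.append(sx)
        by_vals.append(by)
        sy_vals.append(orow["se"])
    return MVMRInputs(
        ex_ids, keep,
        np.asarray(bx_rows, float).reshape(len(keep), len(ex_ids)),
        np.asarray(sx_rows, float).reshape(len(keep), len(ex_ids)),
        np.asarray(by_vals, float), np.asarray(sy_vals, float),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Staged model building
# ---------------------------------------------------------------------------


@dataclass
class StageRecord:
    stage: str
    exposure_ids: list[str]
    fit: MVMRFit | None
    survivors: list[str]


@dataclass
class StagedResult:
    stages: list[StageRecord] = field(default_factory=list)
    final: MVMRModel | None = None
    stopped_at: str | None = None


def _fit_group(group: list[str], exposures, outcome, ld, **clump_kw):
    inputs = build_mvmr_inputs({e: exposures[e] for e in group}, outcome, ld,
                               **clump_kw)
    if len(inputs.instrument_ids) <= len(group):
        return None, inputs
    fit = mvmr_fit(inputs.B_x, inputs.b_y, inputs.se_y, exposure_ids=group)
    return fit, inputs


def staged_model_builder(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    categories: dict[str, list[str]],
    singletons: list[str] | None = None,
    ld: LDReference | None = None,
    p_survive: float = 0.05,
    **clump_kw,
) -> StagedResult:
    """Staged multivariable model building.

    Within each category a multivariable model is fitted and exposures with
    p < ``p_survive`` (strict) survive. Survivors from all categories are
    pooled with any listed singleton factors and fitted jointly; the final
    model refits on that pool's survivors. An empty survivor set at any
    stage stops the procedure with the audit trail intact.
    """
    singletons = singletons or []
    ld = ld if ld is not None else LDReference.identity([])
    result = StagedResult()

    pooled: list[str] = []
    for name, group in categories.items():
        fit, _ = _fit_group(group, exposures, outcome, ld, **clump_kw)
        if fit is None or not fit.estimable:
            result.stages.append(StageRecord(f"category:{name}", group, fit, []))
            continue
        surv = [e for e, p in zip(group, fit.pval) if p < p_survive]
        result.stages.append(StageRecord(f"category:{name}", group, fit, surv))
        pooled.extend(surv)
    if not pooled and not singletons:
        result.stopped_at = "category"
        return result

    pool = pooled + [s for s in singletons if s not in pooled]
    fit_c, _ = _fit_group(pool, exposures, outcome, ld, **clump_kw)
    if fit_c is None or not fit_c.estimable:
        result.stages.append(StageRecord("pooled", pool, fit_c, []))
        result.stopped_at = "pooled"
        return result
    surv_c = [e for e, p in zip(pool, fit_c.pval) if p < p_survive]
    result.stages.append(StageRecord("pooled", pool, fit_c, surv_c))
    if not surv_c:
        result.stopped_at = "pooled"
        return result

    fit_d, inputs_d = _fit_group(surv_c, exposures, outcome, ld, **clump_kw)
    if fit_d is None or not fit_d.estimable:
        result.stages.append(StageRecord("final", surv_c, fit_d, []))
        result.stopped_at = "final"
        return result
    surv_d = [e for e, p in zip(surv_c, fit_d.pval) if p < p_survive]
    result.stages.append(StageRecord("final", surv_c, fit_d, surv_d))
    cf, uf = conditional_f(inputs_d.B_x, inputs_d.se_x)
    result.final = MVMRModel(surv_c, inputs_d.instrument_ids, fit_d, cf, uf)
    return result
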