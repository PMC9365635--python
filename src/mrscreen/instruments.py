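"""Instrument selection and qualification.

Greedy LD clumping, proxy substitution, cis-window selection for protein
traits, per-variant variance explained, directionality (Steiger) filtering
and instrument-strength (F) diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.gwas_data import HarmonizedSet, LDReference

__all__ = [
    "InstrumentSet",
    "ProxyResult",
    "clump",
    "find_proxy",
    "instrument_strength",
    "select_cis_instruments",
    "steiger_filter",
    "variance_explained",
]

#: distance within which a variant missing from the LD panel is treated as
#: fully linked to an index (conservative absorption)
MISSING_LD_ABSORB_BP = 1_000_000


@dataclass
class InstrumentSet:
    """A qualified instrument for one trait."""

    trait_id: str
    variant_ids: list[str]
    per_snp: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_f: float = float("nan")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    s = str(chrom)
    try:
        return (int(s), "")
    except ValueError:
        return (10**6, s)


def clump(
    assocs: pd.DataFrame,
    ld: LDReference,
    p_index: float = 5e-8,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[str]:
    """Greedy LD clumping of a summary-statistics table.

    Repeatedly takes the unassigned SNP with smallest p as an index and
    absorbs every unassigned SNP on the same chromosome within ``window_bp``
    whose r^2 with the index is >= ``r2_max``. SNPs with p above ``p_index``
    never participate. Ties on p break by chromosome, then position, then
    variant id, so output is independent of input row order.

    A SNP pair with either member absent from the LD panel is treated as
    fully linked when within 1 Mb of the index and unlinked beyond.

    Returns index variant ids in selection order.
    """
    df = assocs.loc[assocs["pval"] <= p_index,
                    ["variant_id", "chrom", "pos", "pval"]].copy()
    if df.empty:
        return []
    df["_ck"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["pval", "_ck", "pos", "variant_id"], kind="mergesort")

    ids = df["variant_id"].to_numpy()
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    assigned = np.zeros(len(df), dtype=bool)
    indexes: list[str] = []
    for i in range(len(df)):
        if assigned[i]:
            continue
        assigned[i] = True
        indexes.append(ids[i])
        same = (~assigned) & (chroms == chroms[i])
        near = same & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.flatnonzero(near):
            r2 = ld.r2(ids[i], ids[j])
            if r2 is None:
                linked = abs(int(pos[j]) - int(pos[i])) <= MISSING_LD_ABSORB_BP
            else:
                linked = r2 >= r2_max
            if linked:
                assigned[j] = True
    return indexes


@dataclass
class ProxyResult:
    variant_id: str | None
    r: float = float("nan")
    reason: str = ""


def find_proxy(
    target: str,
    candidates: pd.DataFrame,
    ld: LDReference,
    r2_min: float = 0.8,
) -> ProxyResult:
    """Best LD proxy for ``target`` among ``candidates`` (an assoc table).

    Returns the candidate with maximal r^2 exceeding ``r2_min``; exact ties
    break by smaller p, then variant id. The signed r is reported so the
    proxy's alleles can be oriented to the target.
    """
    if target not in ld:
        return ProxyResult(None, reason="target_not_in_ld_reference")
    best: tuple[float, float, str] | None = None  # (-r2, pval, id) minimised
    best_r = np.nan
    for row in candidates.itertuples(index=False):
        vid = row.variant_id
        if vid == target:
            continue
        rv = ld.r_value(target, vid)
        if rv is None:
            continue
        r2 = rv * rv
        if r2 <= r2_min:
            continue
        key = (-r2, float(row.pval), vid)
        if best is None or key < best:
            best = key
            best_r = rv
    if best is None:
        return ProxyResult(None, reason="no_proxy_above_threshold")
    return ProxyResult(best[2], r=float(best_r))


def variance_explained(beta, se, n):
    """Variance in the trait explained by one variant: t^2 / (t^2 + n - 2)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("sample size must exceed 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(
    h: HarmonizedSet,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Directionality filter: keep SNPs explaining more exposure variance.

    Per SNP, r_x = sign(beta_x) * sqrt(r2_x) (and likewise r_y); the
    direction is accepted iff r2_x > r2_y (strict). A two-sample z-test on
    Fisher-transformed |r| gives the per-SNP p-value:
    z = (atanh|r_x| - atanh|r_y|) / sqrt(1/(n_x-3) + 1/(n_y-3)).

    SNPs with n <= 3 on either side are dropped with reason ``small_n``.
    Returns the filtered set and a per-SNP diagnostics table.
    """
    t = h.table
    rows = []
    keep_ids = []
    for row in t.itertuples(index=False):
        if row.n_x <= 3 or row.n_y <= 3:
            rows.append({
                "variant_id": row.variant_id, "r2_x": np.nan, "r2_y": np.nan,
                "direction": False, "steiger_p": np.nan, "reason": "small_n",
            })
            continue
        r2x = float(variance_explained(row.beta_x, row.se_x, row.n_x))
        r2y = float(variance_explained(row.beta_y, row.se_y, row.n_y))
        rx = abs(np.sqrt(r2x))
        ry = abs(np.sqrt(r2y))
        denom = np.sqrt(1.0 / (row.n_x - 3) + 1.0 / (row.n_y - 3))
        z = (np.arctanh(min(rx, 1 - 1e-15)) - np.arctanh(min(ry, 1 - 1e-15))) / denom
        p = 2 * stats.norm.sf(abs(z))
        direction = r2x > r2y
        rows.append({
            "variant_id": row.variant_id, "r2_x": r2x, "r2_y": r2y,
            "direction": direction, "steiger_p": p, "reason": "",
        })
        if direction:
            keep_ids.append(row.variant_id)
    diag = pd.DataFrame(
        rows,
        columns=["variant_id", "r2_x", "r2_y", "direction", "steiger_p", "reason"],
    )
    return h.subset(keep_ids), diag


def instrument_strength(assocs: pd.DataFrame) -> tuple[float, pd.Series]:
    """Per-SNP F = (beta/se)^2 and their arithmetic mean."""
    if len(assocs) == 0:
        raise ValueError("empty instrument")
    f = (assocs["beta"] / assocs["se"]) ** 2
    return float(f.mean()), f


def select_cis_instruments(
    protein_assocs: pd.DataFrame,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    harmonized: HarmonizedSet,
    ld: LDReference,
    flank_bp: int = 100_000,
    p_max: float = 5e-8,
    r2_max: float = 0.001,
) -> InstrumentSet:
    """Select cis instruments for a protein trait.

    Qualifying SNPs lie within ``[gene_start - flank_bp, gene_end + flank_bp]``
    on the coding gene's chromosome, reach ``p <= p_max`` for the protein,
    and explain more variance in the protein than in the outcome (computed
    from the harmonized pairs). Survivors are LD-clumped within the window.
    Returns an empty set when nothing qualifies.
    """
    lo = gene_start - flank_bp
    hi = gene_end + flank_bp
    window = protein_assocs[
        (protein_assocs["chrom"].astype(str) == str(gene_chrom))
        & (protein_assocs["pos"] >= lo)
        & (protein_assocs["pos"] <= hi)
        & (protein_assocs["pval"] <= p_max)
    ]
    if window.empty:
        return InstrumentSet("", [])
    ht = harmonized.table.set_index("variant_id")
    rows = []
    for row in window.itertuples(index=False):
        if row.variant_id not in ht.index:
            continue
        hrow = ht.loc[row.variant_id]
        r2x = float(variance_explained(hrow["beta_x"], hrow["se_x"], hrow["n_x"]))
        r2y = float(variance_explained(hrow["beta_y"], hrow["se_y"], hrow["n_y"]))
        if r2x > r2y:
            rows.append({
                "variant_id": row.variant_id, "chrom": row.chrom,
                "pos": row.pos, "pval": row.pval,
                "r2_exposure": r2x, "r2_outcome": r2y,
            })
    if not rows:
        return InstrumentSet("", [])
    qual = pd.DataFrame(rows)
    idx = clump(qual, ld, p_index=p_max, r2_max=r2_max, window_bp=hi - lo + 1)
    per_snp = qual.set_index("variant_id").loc[idx].reset_index()
    sub = harmonized.subset(idx).table.set_index("variant_id").loc[idx]
    f = (sub["beta_x"] / sub["se_x"]) ** 2
    per_snp["f_stat"] = f.to_numpy()
    return InstrumentSet("", idx, per_snp, mean_f=float(f.mean()))
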