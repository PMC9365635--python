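"""Bidirectional phenome-wide screening with the three-stage verdict.

Orchestrates eligibility filtering, instrument construction, the estimator
suite, Bonferroni control, the three-stage robustness verdict and the
cis-protein arm with colocalization. All randomness derives from the
config seed; verdict tables are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mrscreen import coloc as coloc_mod
from mrscreen.estimators import MRResult, ivw, run_all_methods, wald_ratio
from mrscreen.gwas_data import (
    HarmonizedSet,
    LDReference,
    harmonize,
    scale_binary_table,
)
from mrscreen.instruments import clump, find_proxy, select_cis_instruments

__all__ = [
    "ScreenConfig",
    "ScreenOutput",
    "ScreenVerdict",
    "bonferroni_threshold",
    "eligibility_filter",
    "forward_screen",
    "plot_screen",
    "protein_screen",
    "reverse_screen",
    "three_stage_verdict",
]


@dataclass
class ScreenConfig:
    """Every tunable threshold of the screening pipeline."""

    p_clump: float = 5e-8
    r2_clump: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.8
    palindrome_maf_limit: float = 0.42
    alpha: float = 0.05
    bonferroni_round_sig: int = 1
    min_n: int = 3000
    min_variants: int = 1_000_000
    ancestry: str = "European"
    cis_flank_bp: int = 100_000
    cis_p_max: float = 5e-8
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_flank_bp: int = 100_000
    coloc_strong_pp4: float = 0.8
    n_boot: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenVerdict:
    """Per exposure-outcome pair: the three-stage trail and final call."""

    exposure_id: str
    outcome_id: str
    method: str = ""
    estimate: float = float("nan")
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    pval: float = float("nan")
    n_snp: int = 0
    stage1_pass: bool = False
    stage1_reason: str = ""
    stage2_pass: bool = False
    stage2_reason: str = ""
    stage3_pass: bool = False
    stage3_reason: str = ""
    final_pass: bool = False
    screen_threshold: float = float("nan")
    stage3_threshold: float = float("nan")
    n_snp_steiger: int = 0
    arm: str = "complex"  # complex | protein
    pp4: float = float("nan")
    note: str = ""


def eligibility_filter(
    meta: pd.DataFrame,
    min_n: int = 3000,
    min_variants: int = 1_000_000,
    ancestry: str = "European",
) -> tuple[list[str], dict[str, int]]:
    """Screen-eligibility rules: strict n > min_n, variants > min_variants,
    matching ancestry label. Returns eligible ids and per-rule fail counts."""
    if meta.empty:
        return [], {"ancestry": 0, "sample_size": 0, "variant_count": 0}
    fails = {
        "ancestry": meta["ancestry"] != ancestry,
        "sample_size": ~(meta["n"] > min_n),
        "variant_count": ~(meta["n_variants"] > min_variants),
    }
    counts = {k: int(v.sum()) for k, v in fails.items()}
    ok = ~(fails["ancestry"] | fails["sample_size"] | fails["variant_count"])
    return meta.loc[ok, "trait_id"].tolist(), counts


def bonferroni_threshold(
    n_tests: int, alpha: float = 0.05, round_sig: int | None = 1
) -> float:
    """alpha/n_tests, rounded to ``round_sig`` significant figures.

    ``round_sig=None`` returns full precision. The 1-significant-figure
    default matches heuristic screen-threshold use (e.g. 0.05/5048 -> 1e-5).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    value = alpha / n_tests
    if round_sig is None:
        return value
    if round_sig < 1:
        raise ValueError("round_sig must be >= 1 (or None)")
    return float(f"{value:.{round_sig - 1}e}")


# ---------------------------------------------------------------------------
# Verdict machinery
# ---------------------------------------------------------------------------


def _by_method(results: list[MRResult]) -> dict[str, MRResult]:
    return {r.method: r for r in results}


def _primary(results: list[MRResult]) -> MRResult | None:
    methods = _by_method(results)
    for name in ("ivw", "wald_ratio"):
        res = methods.get(name)
        if res is not None and res.estimable:
            return res
    return None


def _stage12(
    results: list[MRResult], screen_threshold: float
) -> tuple[bool, str, bool, str]:
    methods = _by_method(results)
    primary = _primary(results)
    if primary is None:
        return False, "no primary estimate", False, "no primary estimate"
    if primary.n_snp < 4:
        s1, r1 = False, f"n_snp={primary.n_snp} < 4"
    elif not (primary.pval < screen_threshold):
        s1, r1 = False, f"primary p={primary.pval:.3g} >= {screen_threshold:.3g}"
    else:
        s1, r1 = True, ""
    med = methods.get("weighted_median")
    if med is None or not med.estimable:
        s2, r2 = False, "weighted median not estimable"
    elif np.sign(med.estimate) != np.sign(primary.estimate):
        s2, r2 = False, "weighted median sign discordant"
    elif not (med.pval < 0.05):
        s2, r2 = False, f"weighted median p={med.pval:.3g} >= 0.05"
    else:
        s2, r2 = True, ""
    return s1, r1, s2, r2


def three_stage_verdict(
    results: list[MRResult],
    steiger_result: MRResult | None,
    screen_threshold: float,
    n_stage12_passers: int,
) -> ScreenVerdict:
    """Three-stage robustness verdict for one exposure-outcome pair.

    Stage 1: >= 4 SNPs and primary (IVW) p below the screen threshold.
    Stage 2: weighted-median estimate directionally concordant with the
    primary and median p < 0.05. Stage 3: Steiger-filtered IVW concordant
    with the primary and its p < alpha / n_stage12_passers. The final call
    requires all three.
    """
    v = ScreenVerdict("", "", screen_threshold=screen_threshold)
    primary = _primary(results)
    if primary is not None:
        v.method = primary.method
        v.estimate = primary.estimate
        v.se = primary.se
        v.ci_low = primary.ci_low
        v.ci_high = primary.ci_high
        v.pval = primary.pval
        v.n_snp = primary.n_snp
    v.stage1_pass, v.stage1_reason, v.stage2_pass, v.stage2_reason = _stage12(
        results, screen_threshold)
    if steiger_result is None:
        steiger_result = _by_method(results).get("ivw_steiger")
    stage3_threshold = 0.05 / max(1, n_stage12_passers)
    v.stage3_threshold = stage3_threshold
    if steiger_result is None or not steiger_result.estimable or primary is None:
        v.stage3_pass, v.stage3_reason = False, "steiger IVW not estimable"
    else:
        v.n_snp_steiger = steiger_result.n_snp
        if np.sign(steiger_result.estimate) != np.sign(primary.estimate):
            v.stage3_pass, v.stage3_reason = False, "steiger IVW sign discordant"
        elif not (steiger_result.pval < stage3_threshold):
            v.stage3_pass = False
            v.stage3_reason = (
                f"steiger IVW p={steiger_result.pval:.3g} >= {stage3_threshold:.3g}")
        else:
            v.stage3_pass, v.stage3_reason = True, ""
    v.final_pass = v.stage1_pass and v.stage2_pass and v.stage3_pass
    return v


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def _trait_seed(global_seed: int, trait_id: str) -> int:
    ss = np.random.SeedSequence([global_seed, zlib.crc32(trait_id.encode())])
    return int(ss.generate_state(1)[0])


def _scale_if_linear(df: pd.DataFrame, meta_row: pd.Series | None) -> pd.DataFrame:
    if meta_row is not None and str(meta_row.get("units", "")) == "linear":
        tbl = df.copy()
        if tbl["n_case"].isna().any():
            tbl["n_case"] = float(meta_row["n_case"])
            tbl["n_control"] = float(meta_row["n_control"])
        return scale_binary_table(tbl)
    return df


def _outcome_subset_with_proxies(
    instrument_ids: list[str],
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDReference,
    proxy_r2: float,
) -> tuple[pd.DataFrame, int, int]:
    """Outcome rows for the instrument ids, substituting LD proxies.

    A proxy's beta is translated to the target SNP's alleles via the sign
    of r; failed proxy searches drop the SNP (counted, not fatal).
    """
    out_idx = outcome.set_index("variant_id")
    exp_idx = exposure.set_index("variant_id")
    present = [v for v in instrument_ids if v in out_idx.index]
    missing = [v for v in instrument_ids if v not in out_idx.index]
    rows = out_idx.loc[present].reset_index()
    n_proxied = n_dropped = 0
    proxy_rows = []
    if missing:
        candidates = outcome[[c in ld for c in outcome["variant_id"]]]
        for vid in missing:
            pr = find_proxy(vid, candidates, ld, r2_min=proxy_r2)
            if pr.variant_id is None:
                n_dropped += 1
                continue
            src = out_idx.loc[pr.variant_id]
            ex = exp_idx.loc[vid]
            sign = 1.0 if pr.r >= 0 else -1.0
            proxy_rows.append({
                "variant_id": vid,
                "chrom": ex["chrom"], "pos": ex["pos"],
                "effect_allele": ex["effect_allele"],
                "other_allele": ex["other_allele"],
                "eaf": src["eaf"] if sign > 0 else 1 - src["eaf"],
                "beta": sign * src["beta"], "se": src["se"],
                "pval": src["pval"], "n": src["n"],
                "n_case": src.get("n_case", np.nan),
                "n_control": src.get("n_control", np.nan),
                "proxy_used": True,
            })
            n_proxied += 1
    if proxy_rows:
        rows = pd.concat([rows, pd.DataFrame(proxy_rows)], ignore_index=True)
    return rows, n_proxied, n_dropped


@dataclass
class ScreenOutput:
    verdicts: pd.DataFrame
    coloc: dict[str, coloc_mod.ColocResult] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _verdicts_frame(verdicts: list[ScreenVerdict]) -> pd.DataFrame:
    return pd.DataFrame([asdict(v) for v in verdicts])


# ---------------------------------------------------------------------------
# Forward screen (phenome -> outcome)
# ---------------------------------------------------------------------------


def forward_screen(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    meta: pd.DataFrame,
    ld: LDReference,
    config: ScreenConfig | None = None,
) -> ScreenOutput:
    """Screen every exposure trait against one outcome.

    Pipeline per complex trait: clump -> proxy-substitute -> harmonize ->
    rescale linear binary traits -> six-method estimation -> three-stage
    verdict (stage 3 thresholds computed in a second pass over the stage-1/2
    passers). Protein traits are routed through :func:`protein_screen`.
    """
    config = config or ScreenConfig()
    meta_idx = meta.set_index("trait_id")
    ids = sorted(exposures)
    sub_meta = meta[meta["trait_id"].isin(ids)]
    eligible, elig_counts = eligibility_filter(
        sub_meta, config.min_n, config.min_variants, config.ancestry)
    threshold = bonferroni_threshold(
        max(1, len(eligible)), config.alpha, config.bonferroni_round_sig)

    outcome_id = "outcome"
    outcome_meta = None
    out_ids = set(meta_idx.index) - set(ids)
    if len(out_ids) == 1:
        outcome_id = next(iter(out_ids))
        outcome_meta = meta_idx.loc[outcome_id]
    outcome = _scale_if_linear(outcome, outcome_meta)

    protein_ids = [t for t in eligible
                   if str(meta_idx.loc[t, "trait_type"]) == "protein"]
    complex_ids = [t for t in eligible if t not in set(protein_ids)]

    trait_results: dict[str, list[MRResult]] = {}
    trait_info: dict[str, dict] = {}
    verdicts: list[ScreenVerdict] = []

    for tid in complex_ids:
        exp_df = _scale_if_linear(exposures[tid], meta_idx.loc[tid])
        inst = clump(exp_df, ld, config.p_clump, config.r2_clump,
                     config.clump_window_bp)
        info = {"n_clumped": len(inst), "n_proxied": 0, "n_proxy_dropped": 0}
        if not inst:
            v = ScreenVerdict(tid, outcome_id, screen_threshold=threshold,
                              note="no instruments after clumping")
            verdicts.append(v)
            trait_info[tid] = info
            continue
        out_sub, n_prox, n_drop = _outcome_subset_with_proxies(
            inst, exp_df, outcome, ld, config.proxy_r2)
        info["n_proxied"], info["n_proxy_dropped"] = n_prox, n_drop
        exp_sub = exp_df[exp_df["variant_id"].isin(inst)]
        h = harmonize(exp_sub, out_sub, config.palindrome_maf_limit)
        info["n_harmonized"] = h.n_snp
        if h.n_snp == 0:
            verdicts.append(ScreenVerdict(
                tid, outcome_id, screen_threshold=threshold,
                note="no SNPs survive harmonization"))
            trait_info[tid] = info
            continue
        results = run_all_methods(h, seed=_trait_seed(config.seed, tid),
                                  n_boot=config.n_boot)
        trait_results[tid] = results
        trait_info[tid] = info

    # two-pass: count stage-1/2 passers, then issue full verdicts
    n12 = sum(
        1 for res in trait_results.values()
        if all(_stage12(res, threshold)[i] for i in (0, 2))
    )
    for tid, results in trait_results.items():
        v = three_stage_verdict(results, None, threshold, max(1, n12))
        v.exposure_id = tid
        v.outcome_id = outcome_id
        verdicts.append(v)

    coloc_results: dict[str, coloc_mod.ColocResult] = {}
    if protein_ids:
        pout = protein_screen(
            {t: exposures[t] for t in protein_ids}, outcome, meta, ld,
            config, screen_threshold=threshold, outcome_id=outcome_id)
        verdicts.extend(
            ScreenVerdict(**row) for row in pout.verdicts.to_dict("records"))
        coloc_results.update(pout.coloc)

    vdf = _verdicts_frame(verdicts).sort_values("exposure_id").reset_index(drop=True)
    manifest = {
        "direction": "forward",
        "outcome_id": outcome_id,
        "seed": config.seed,
        "config": config.to_dict(),
        "screen_threshold": threshold,
        "n_eligible": len(eligible),
        "eligibility_fail_counts": elig_counts,
        "n_stage12_passers": n12,
        "traits": trait_info,
    }
    return ScreenOutput(vdf, coloc_results, manifest)


# ---------------------------------------------------------------------------
# Protein arm
# ---------------------------------------------------------------------------


def protein_screen(
    proteins: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    meta: pd.DataFrame,
    ld: LDReference,
    config: ScreenConfig | None = None,
    screen_threshold: float | None = None,
    outcome_id: str = "outcome",
) -> ScreenOutput:
    """cis-instrument MR plus colocalization for protein traits.

    Per protein: cis selection inside the coding-gene window (no proxy
    search in this arm), Wald ratio or IVW as the primary estimate,
    thresholding at the exposure-screen Bonferroni value, and
    colocalization of survivors in the region 100 kb either side of the
    leading cis-pQTL. Survivors whose colocalization favours two distinct
    causal variants (PP3 > PP4) are flagged discordant.
    """
    config = config or ScreenConfig()
    meta_idx = meta.set_index("trait_id")
    if screen_threshold is None:
        screen_threshold = bonferroni_threshold(
            max(1, len(proteins)), config.alpha, config.bonferroni_round_sig)
    verdicts: list[ScreenVerdict] = []
    coloc_results: dict[str, coloc_mod.ColocResult] = {}
    for tid in sorted(proteins):
        row = meta_idx.loc[tid] if tid in meta_idx.index else None
        if row is None or pd.isna(row.get("gene_start")):
            verdicts.append(ScreenVerdict(
                tid, outcome_id, arm="protein",
                screen_threshold=screen_threshold,
                note="skipped: no gene locus metadata"))
            continue
        prot = proteins[tid]
        out_idx = outcome.set_index("variant_id")
        shared = [v for v in prot["variant_id"] if v in out_idx.index]
        out_sub = out_idx.loc[shared].reset_index()
        h = harmonize(prot, out_sub, config.palindrome_maf_limit)
        inst = select_cis_instruments(
            prot, str(row["gene_chrom"]), int(row["gene_start"]),
            int(row["gene_end"]), h, ld,
            flank_bp=config.cis_flank_bp, p_max=config.cis_p_max,
            r2_max=config.r2_clump)
        v = ScreenVerdict(tid, outcome_id, arm="protein",
                          screen_threshold=screen_threshold)
        if inst.n_snp == 0:
            v.note = "no qualifying cis instruments"
            verdicts.append(v)
            continue
        h_sub = h.subset(inst.variant_ids)
        if h_sub.n_snp == 1:
            r = h_sub.table.iloc[0]
            res = wald_ratio(r.beta_x, r.se_x, r.beta_y, r.se_y)
        else:
            res = ivw(h_sub)
        v.method = res.method
        v.estimate, v.se = res.estimate, res.se
        v.ci_low, v.ci_high = res.ci_low, res.ci_high
        v.pval, v.n_snp = res.pval, res.n_snp
        v.stage1_pass = v.stage2_pass = v.stage3_pass = True
        v.stage1_reason = v.stage2_reason = v.stage3_reason = "protein arm: n/a"
        v.final_pass = bool(res.pval < screen_threshold)
        if v.final_pass:
            cis_lo = int(row["gene_start"]) - config.cis_flank_bp
            cis_hi = int(row["gene_end"]) + config.cis_flank_bp
            cis = prot[(prot["chrom"].astype(str) == str(row["gene_chrom"]))
                       & (prot["pos"] >= cis_lo) & (prot["pos"] <= cis_hi)]
            lead = cis.loc[cis["pval"].idxmin()]
            lo = lead["pos"] - config.coloc_flank_bp
            hi = lead["pos"] + config.coloc_flank_bp
            region_x = prot[(prot["pos"] >= lo) & (prot["pos"] <= hi)]
            region_y = out_sub[(out_sub["pos"] >= lo) & (out_sub["pos"] <= hi)]
            cres = coloc_mod.colocalize(
                region_x, region_y,
                p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
                prior_sd_x=coloc_mod.PRIOR_SD_QUANTITATIVE,
                prior_sd_y=coloc_mod.PRIOR_SD_BINARY)
            coloc_results[tid] = cres
            if cres.estimable:
                v.pp4 = cres.pp4
                if cres.pp3 > cres.pp4:
                    v.note = "coloc discordant: PP3 > PP4"
        verdicts.append(v)
    vdf = _verdicts_frame(verdicts)
    manifest = {"direction": "protein", "screen_threshold": screen_threshold,
                "seed": config.seed, "config": config.to_dict()}
    return ScreenOutput(vdf, coloc_results, manifest)


# ---------------------------------------------------------------------------
# Reverse screen (one exposure -> phenome of outcomes)
# ---------------------------------------------------------------------------


def reverse_screen(
    exposure: pd.DataFrame,
    outcomes: Mapping[str, pd.DataFrame],
    meta: pd.DataFrame,
    ld: LDReference,
    config: ScreenConfig | None = None,
    exposure_id: str = "exposure",
) -> ScreenOutput:
    """Screen one exposure against many outcomes.

    The exposure instrument is clumped exactly once and reused across all
    outcomes; the Bonferroni threshold divides by the number of eligible
    outcome traits. Binary outcomes on the linear scale are rescaled to
    log odds before estimation.
    """
    config = config or ScreenConfig()
    meta_idx = meta.set_index("trait_id")
    ids = sorted(outcomes)
    sub_meta = meta[meta["trait_id"].isin(ids)]
    eligible, elig_counts = eligibility_filter(
        sub_meta, config.min_n, config.min_variants, config.ancestry)
    threshold = bonferroni_threshold(
        max(1, len(eligible)), config.alpha, config.bonferroni_round_sig)

    exp_meta = meta_idx.loc[exposure_id] if exposure_id in meta_idx.index else None
    exposure = _scale_if_linear(exposure, exp_meta)
    inst = clump(exposure, ld, config.p_clump, config.r2_clump,
                 config.clump_window_bp)
    exp_sub = exposure[exposure["variant_id"].isin(inst)]

    trait_results: dict[str, list[MRResult]] = {}
    trait_info: dict[str, dict] = {}
    verdicts: list[ScreenVerdict] = []
    for tid in eligible:
        if not inst:
            verdicts.append(ScreenVerdict(
                exposure_id, tid, screen_threshold=threshold,
                note="no instruments after clumping"))
            continue
        out_df = _scale_if_linear(outcomes[tid], meta_idx.loc[tid])
        out_sub, n_prox, n_drop = _outcome_subset_with_proxies(
            inst, exposure, out_df, ld, config.proxy_r2)
        h = harmonize(exp_sub, out_sub, config.palindrome_maf_limit)
        trait_info[tid] = {"n_proxied": n_prox, "n_proxy_dropped": n_drop,
                           "n_harmonized": h.n_snp}
        if h.n_snp == 0:
            verdicts.append(ScreenVerdict(
                exposure_id, tid, screen_threshold=threshold,
                note="no SNPs survive harmonization"))
            continue
        trait_results[tid] = run_all_methods(
            h, seed=_trait_seed(config.seed, tid), n_boot=config.n_boot)

    n12 = sum(
        1 for res in trait_results.values()
        if all(_stage12(res, threshold)[i] for i in (0, 2))
    )
    for tid, results in trait_results.items():
        v = three_stage_verdict(results, None, threshold, max(1, n12))
        v.exposure_id = exposure_id
        v.outcome_id = tid
        verdicts.append(v)
    vdf = _verdicts_frame(verdicts).sort_values("outcome_id").reset_index(drop=True)
    manifest = {
        "direction": "reverse",
        "exposure_id": exposure_id,
        "seed": config.seed,
        "config": config.to_dict(),
        "screen_threshold": threshold,
        "n_eligible": len(eligible),
        "eligibility_fail_counts": elig_counts,
        "n_instruments": len(inst),
        "n_stage12_passers": n12,
        "traits": trait_info,
    }
    return ScreenOutput(vdf, {}, manifest)


def plot_screen(
    verdicts: pd.DataFrame,
    threshold: float,
    path: str | Path,
    trait_column: str = "exposure_id",
) -> None:
    """Static -log10(p) vs trait-index summary plot.

    Display convention only: pairs failing every robustness stage are drawn
    at p = 1; stored results are never altered.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = verdicts.sort_values(trait_column).reset_index(drop=True)
    shown_p = df["pval"].copy()
    none_pass = ~(df["stage1_pass"] | df["stage2_pass"] | df["stage3_pass"])
    shown_p[none_pass] = 1.0
    y = -np.log10(shown_p.clip(lower=1e-300))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(np.arange(len(df)), y,
               s=10 + 30 * np.abs(df["estimate"].fillna(0)).clip(upper=2),
               c=np.where(df["final_pass"], "tab:red", "tab:grey"))
    ax.axhline(-np.log10(threshold), color="black", lw=1)
    ax.set_xlabel("trait index")
    ax.set_ylabel("-log10 p (primary MR)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
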