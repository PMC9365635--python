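"""Synthetic two-sample GWAS summary statistics with known ground truth.

Every generator is deterministic given its seed: one global seed fans out
to per-component :class:`numpy.random.SeedSequence` streams, so adding a
trait to a phenome does not perturb the draws of the others. All emitted
tables use the canonical columns of :mod:`mrscreen.gwas_data` and pass its
reader validation with zero drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from mrscreen.gwas_data import LDReference, write_summary_stats

__all__ = [
    "PhenomeSim",
    "SimTruth",
    "make_truth",
    "simulate_binary_linear",
    "simulate_coloc_region",
    "simulate_phenome",
    "simulate_two_sample",
]

# z threshold for two-sided p = 5e-8
_Z_GWAS = stats.norm.isf(2.5e-8)

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


@dataclass
class SimTruth:
    """Ground truth behind one simulated exposure-outcome pair."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    pleiotropy_mode: str  # none | balanced | directional | reverse
    n_x: int
    n_y: int
    maf: np.ndarray
    seed: int

    @property
    def n_snp(self) -> int:
        return len(self.gamma)


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def make_truth(
    n_snp: int,
    theta: float,
    n_x: int = 50_000,
    n_y: int = 100_000,
    seed: int = 0,
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.0,
    pleiotropy_shift: float = 0.0,
    frac_invalid: float = 1.0,
    gamma_sd: float = 0.03,
    gamma_sign: str = "mixed",
    strong: bool = True,
) -> SimTruth:
    """Draw a :class:`SimTruth` configuration.

    MAFs are Uniform(0.05, 0.5); instrument effects gamma ~ N(0, gamma_sd^2),
    forced (when ``strong``) above the effect size needed to pass p < 5e-8
    at n_x so per-SNP F sits near realistic GWAS-significant values.
    ``gamma_sign='positive'`` orients all gammas positive, which is how
    directional pleiotropy stays directional after allele orientation.

    Pleiotropy modes: ``balanced`` draws alpha ~ N(0, pleiotropy_sd^2) for
    all SNPs; ``directional`` sets alpha = pleiotropy_shift for a
    ``frac_invalid`` fraction of SNPs; ``reverse`` marks the pair as
    outcome-first (handled by :func:`simulate_two_sample`).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    maf = rng.uniform(0.05, 0.5, n_snp)
    gamma = rng.normal(0.0, gamma_sd, n_snp)
    if gamma_sign == "positive":
        gamma = np.abs(gamma)
    if strong:
        floor = 1.1 * _Z_GWAS * _se(maf, n_x)
        weak = np.abs(gamma) < floor
        sign = np.where(gamma >= 0, 1.0, -1.0)
        gamma = np.where(weak, sign * floor, gamma)
    alpha = np.zeros(n_snp)
    if pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, pleiotropy_sd, n_snp)
    elif pleiotropy_mode == "directional":
        n_inv = int(round(frac_invalid * n_snp))
        invalid = rng.choice(n_snp, size=n_inv, replace=False)
        alpha[invalid] = pleiotropy_shift
    elif pleiotropy_mode not in ("none", "reverse"):
        raise ValueError(f"unknown pleiotropy mode: {pleiotropy_mode}")
    return SimTruth(theta, gamma, alpha, pleiotropy_mode, n_x, n_y, maf, seed)


def _assoc_table(
    variant_ids, chrom, pos, ea, oa, eaf, beta, se, n,
    n_case=None, n_control=None,
) -> pd.DataFrame:
    z = beta / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": str(chrom),
        "pos": pos,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": float(n),
        "n_case": np.nan if n_case is None else float(n_case),
        "n_control": np.nan if n_control is None else float(n_control),
    })


def simulate_two_sample(
    truth: SimTruth,
    frac_palindromic: float = 0.0,
    frac_swapped: float = 0.0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 1_500_000,
    id_prefix: str = "rs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an (exposure, outcome) pair of summary-statistics tables.

    Per SNP j: se_xj = 1/sqrt(2 maf_j (1-maf_j) n_x) (analogous for y);
    beta_xj ~ N(gamma_j, se_xj^2) and beta_yj ~ N(theta gamma_j + alpha_j,
    se_yj^2); in ``reverse`` mode the variant acts on the outcome first and
    the roles of gamma and theta*gamma are swapped. A ``frac_palindromic``
    fraction of SNPs receive A/T or C/G alleles and a ``frac_swapped``
    fraction have effect/other alleles swapped (beta negated, frequency
    complemented) in the outcome file, to exercise harmonization.
    """
    if np.any((truth.maf <= 0) | (truth.maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if truth.n_x <= 10 or truth.n_y <= 10:
        raise ValueError("sample sizes must exceed 10")
    j = truth.n_snp
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5eed]))
    se_x = _se(truth.maf, truth.n_x)
    se_y = _se(truth.maf, truth.n_y)
    if truth.pleiotropy_mode == "reverse":
        mean_x = truth.theta * truth.gamma
        mean_y = truth.gamma
    else:
        mean_x = truth.gamma
        mean_y = truth.theta * truth.gamma + truth.alpha
    beta_x = rng.normal(mean_x, se_x)
    beta_y = rng.normal(mean_y, se_y)

    ids = [f"{id_prefix}{chrom}_{k:05d}" for k in range(j)]
    pos = pos_start + pos_step * np.arange(j)
    pal = rng.random(j) < frac_palindromic
    pick_np = rng.integers(0, len(_NONPALINDROMIC), j)
    pick_p = rng.integers(0, len(_PALINDROMIC), j)
    ea = np.where(pal,
                  [_PALINDROMIC[i][0] for i in pick_p],
                  [_NONPALINDROMIC[i][0] for i in pick_np])
    oa = np.where(pal,
                  [_PALINDROMIC[i][1] for i in pick_p],
                  [_NONPALINDROMIC[i][1] for i in pick_np])

    exposure = _assoc_table(ids, chrom, pos, ea, oa, truth.maf,
                            beta_x, se_x, truth.n_x)
    swap = rng.random(j) < frac_swapped
    ea_y = np.where(swap, oa, ea)
    oa_y = np.where(swap, ea, oa)
    beta_y_out = np.where(swap, -beta_y, beta_y)
    eaf_y = np.where(swap, 1 - truth.maf, truth.maf)
    outcome = _assoc_table(ids, chrom, pos, ea_y, oa_y, eaf_y,
                           beta_y_out, se_y, truth.n_y)
    return exposure, outcome


def simulate_binary_linear(
    truth: SimTruth,
    n_case: int,
    n_control: int,
    **kwargs: Any,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associations with a binary trait analysed in a linear model.

    The log-odds-scale truth table is generated first; the emitted linear
    table carries betas and SEs multiplied by mu(1-mu) with
    mu = n_case/(n_case+n_control), so
    :func:`mrscreen.gwas_data.scale_linear_to_logodds` inverts the
    construction exactly. Returns (linear table, log-odds truth table).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    n_total = n_case + n_control
    truth = replace(truth, n_y=n_total)
    _, logodds = simulate_two_sample(truth, **kwargs)
    mu = n_case / n_total
    linear = logodds.copy()
    linear["beta"] = linear["beta"] * (mu * (1 - mu))
    linear["se"] = linear["se"] * (mu * (1 - mu))
    linear["n_case"] = float(n_case)
    linear["n_control"] = float(n_control)
    return linear, logodds


def simulate_coloc_region(
    n_snp: int = 60,
    rho: float = 0.9,
    shared: bool = True,
    n_x: int = 10_000,
    n_y: int = 10_000,
    ncp_x: float = 8.0,
    ncp_y: float = 8.0,
    seed: int = 0,
    maf: float = 0.3,
    causal_x: int | None = None,
    causal_y: int | None = None,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 3_000,
    id_prefix: str = "cv",
) -> tuple[pd.DataFrame, pd.DataFrame, LDReference]:
    """Simulate a pair of association regions over AR(1) LD.

    The LD matrix is r(i, j) = rho^|i-j|. Each trait's z-vector is drawn
    from N(R lambda, R), where lambda carries the non-centrality ``ncp`` at
    the causal index (shared, or two distinct indices at n/4 and 3n/4).
    Betas and SEs are back-computed from z and the sample size.
    """
    if n_snp < 20:
        raise ValueError("need at least 20 SNPs in a region")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(n_snp)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(n_snp))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xc010c]))

    cx = n_snp // 4 if causal_x is None else causal_x
    cy = cx if shared else (3 * n_snp // 4 if causal_y is None else causal_y)
    lam_x = np.zeros(n_snp)
    lam_x[cx] = ncp_x
    lam_y = np.zeros(n_snp)
    lam_y[cy] = ncp_y

    z_x = r @ lam_x + chol @ rng.standard_normal(n_snp)
    z_y = r @ lam_y + chol @ rng.standard_normal(n_snp)
    mafs = np.full(n_snp, maf)
    se_x = _se(mafs, n_x)
    se_y = _se(mafs, n_y)
    ids = [f"{id_prefix}{chrom}_{k:04d}" for k in range(n_snp)]
    pos = pos_start + pos_step * idx
    region_x = _assoc_table(ids, chrom, pos, "A", "G", mafs, z_x * se_x, se_x, n_x)
    region_y = _assoc_table(ids, chrom, pos, "A", "G", mafs, z_y * se_y, se_y, n_y)
    ld = LDReference(ids, r, pos)
    return region_x, region_y, ld


# ---------------------------------------------------------------------------
# Full synthetic phenome
# ---------------------------------------------------------------------------


@dataclass
class PhenomeSim:
    """A desk-scale synthetic phenome with its ground-truth ledger."""

    exposures: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    outcome_id: str
    meta: pd.DataFrame
    ld: LDReference
    truths: dict[str, dict] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        """Write all tables (tab-delimited) plus the JSON truth ledger."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tid, df in self.exposures.items():
            write_summary_stats(df, directory / f"{tid}.tsv")
        write_summary_stats(self.outcome, directory / f"{self.outcome_id}.tsv")
        self.meta.to_csv(directory / "meta.tsv", sep="\t", index=False)
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truths, fh, indent=1, default=float)
        if len(self.ld):
            with open(directory / "ld_ids.txt", "w") as fh:
                for vid in self.ld.variant_ids:
                    fh.write(f"{vid}\n")
            np.savetxt(directory / "ld_matrix.txt", self.ld.r, fmt="%.6g")


def simulate_phenome(
    n_traits: int = 100,
    frac_causal: float = 0.05,
    frac_protein: float = 0.10,
    n_snp_per_trait: int = 50,
    seed: int = 0,
    n_x: int = 50_000,
    n_y: int = 100_000,
    outcome_n_case: int = 20_000,
    frac_binary: float = 0.3,
) -> PhenomeSim:
    """Generate a phenome of exposure traits sharing one binary outcome.

    Traits are a mixture of quantitative traits, binary traits analysed on
    the linear scale (carrying case/control counts), and protein traits
    with cis-clustered instruments under AR(1) LD and a gene-locus record.
    Causal traits receive theta ~ Uniform(0.2, 0.35); the ledger records
    per-trait ground truth for end-to-end tests. Outcome associations are
    emitted on the log-odds scale (units ``logodds``, no rescaling needed).
    Each trait lives on its own pseudo-chromosome so instruments of
    different traits are unlinked by construction.
    """
    if n_traits < 10:
        raise ValueError("need at least 10 traits")
    root = np.random.default_rng(np.random.SeedSequence([seed, 0x9e0]))
    n_causal = int(round(frac_causal * n_traits))
    n_protein = int(round(frac_protein * n_traits))
    causal_idx = set(root.choice(n_traits, size=n_causal, replace=False).tolist())
    protein_idx = set(root.choice(n_traits, size=n_protein, replace=False).tolist())

    exposures: dict[str, pd.DataFrame] = {}
    outcome_parts: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    truths: dict[str, dict] = {}
    ld_blocks: list[LDReference] = []
    outcome_n_control = n_y - outcome_n_case

    for i in range(n_traits):
        causal = i in causal_idx
        theta = float(root.uniform(0.2, 0.35)) if causal else 0.0
        child_seed = int(np.random.SeedSequence([seed, 1000 + i]).generate_state(1)[0])
        chrom = f"c{i:03d}"
        if i in protein_idx:
            tid = f"prot_{i:03d}"
            ncp_y = 10.0 if causal else 0.0
            region_x, region_y, ld = simulate_coloc_region(
                n_snp=40, rho=0.8, shared=True, n_x=3301, n_y=n_y,
                ncp_x=16.0, ncp_y=ncp_y, seed=child_seed, chrom=chrom,
                id_prefix=f"p{i:03d}_",
            )
            region_y["n_case"] = float(outcome_n_case)
            region_y["n_control"] = float(outcome_n_control)
            exposures[tid] = region_x
            outcome_parts.append(region_y)
            ld_blocks.append(ld)
            centre = int(region_x["pos"].iloc[len(region_x) // 4])
            meta_rows.append({
                "trait_id": tid, "trait_type": "protein", "units": "SD",
                "n": 3301, "n_variants": 1_200_000, "ancestry": "European",
                "n_case": np.nan, "n_control": np.nan,
                "gene_chrom": chrom, "gene_start": centre - 20_000,
                "gene_end": centre + 20_000,
            })
            truths[tid] = {"causal": causal, "theta": theta,
                           "trait_type": "protein", "seed": child_seed}
            continue

        tid = f"trait_{i:03d}"
        binary = root.random() < frac_binary
        truth = make_truth(
            n_snp_per_trait, theta, n_x=n_x, n_y=n_y, seed=child_seed,
            gamma_sign="mixed", strong=True,
        )
        if binary:
            n_case = int(0.2 * n_x)
            n_control = n_x - n_case
            mu = n_case / n_x
            exp_df, out_df = simulate_two_sample(
                truth, frac_palindromic=0.1, frac_swapped=0.2,
                chrom=chrom, id_prefix=f"t{i:03d}_",
            )
            exp_df = exp_df.copy()
            exp_df["beta"] = exp_df["beta"] * (mu * (1 - mu))
            exp_df["se"] = exp_df["se"] * (mu * (1 - mu))
            exp_df["n_case"] = float(n_case)
            exp_df["n_control"] = float(n_control)
            # p-values recomputed on the emitted scale (z unchanged)
            units, ttype = "linear", "binary"
            ncc = (n_case, n_control)
        else:
            exp_df, out_df = simulate_two_sample(
                truth, frac_palindromic=0.1, frac_swapped=0.2,
                chrom=chrom, id_prefix=f"t{i:03d}_",
            )
            units, ttype = "SD", "quantitative"
            ncc = (np.nan, np.nan)
        out_df = out_df.copy()
        out_df["n_case"] = float(outcome_n_case)
        out_df["n_control"] = float(outcome_n_control)
        exposures[tid] = exp_df
        outcome_parts.append(out_df)
        meta_rows.append({
            "trait_id": tid, "trait_type": ttype, "units": units,
            "n": n_x, "n_variants": 1_200_000, "ancestry": "European",
            "n_case": ncc[0], "n_control": ncc[1],
            "gene_chrom": "", "gene_start": np.nan, "gene_end": np.nan,
        })
        truths[tid] = {"causal": causal, "theta": theta,
                       "trait_type": ttype, "seed": child_seed}

    outcome_id = "outcome"
    outcome = pd.concat(outcome_parts, ignore_index=True)
    meta_rows.append({
        "trait_id": outcome_id, "trait_type": "binary", "units": "logodds",
        "n": n_y, "n_variants": 1_200_000, "ancestry": "European",
        "n_case": outcome_n_case, "n_control": outcome_n_control,
        "gene_chrom": "", "gene_start": np.nan, "gene_end": np.nan,
    })
    meta = pd.DataFrame(meta_rows)
    ld = LDReference.block_concat(ld_blocks) if ld_blocks else LDReference.identity([])
    return PhenomeSim(exposures, outcome, outcome_id, meta, ld, truths)
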