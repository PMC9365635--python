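"""Data model and I/O for GWAS summary statistics and LD references.

Summary statistics are carried as :class:`pandas.DataFrame` objects with a
canonical column set (see :data:`CANONICAL_COLUMNS`). Readers validate each
row against the invariants of a single variant association and report what
was dropped rather than raising, so that large, messy files degrade
gracefully.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "HarmonizedSet",
    "LDReference",
    "ReadReport",
    "harmonize",
    "read_summary_stats",
    "scale_linear_to_logodds",
    "unscale_logodds_to_linear",
    "validate_associations",
    "write_summary_stats",
]

#: canonical (internal) column names for a summary-statistics table
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
)

REQUIRED_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "n",
)

#: default file-header -> canonical mapping (common GWAS header names)
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "SNP": "variant_id",
    "CHR": "chrom",
    "BP": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
    "NCASE": "n_case",
    "NCONTROL": "n_control",
}

_PALINDROMIC_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})


class ConfigurationError(ValueError):
    """A column map or config does not cover the required fields."""


class InputError(ValueError):
    """An input file is unusable (e.g. empty)."""


@dataclass
class ReadReport:
    """Accounting of what a reader kept and dropped."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_duplicates_removed: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def add_drop(self, reason: str, count: int = 1) -> None:
        self.n_dropped += count
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + count


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in _PALINDROMIC_PAIRS


def validate_associations(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Apply per-row invariants, returning (valid rows, report).

    Invariants: ``se > 0``; ``0 < eaf < 1`` when present; ``pval`` in (0, 1];
    ``n > 0``; ``n_case + n_control == n`` when both counts are present;
    effect and other alleles differ. Duplicate ``variant_id`` keeps the row
    with the smallest p-value.
    """
    report = ReadReport(n_read=len(df))
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    numeric = ["pos", "eaf", "beta", "se", "pval", "n", "n_case", "n_control"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    checks = {
        "missing_required": df[list(REQUIRED_COLUMNS)].isna().any(axis=1),
        "nonpositive_se": df["se"] <= 0,
        "bad_pval": (df["pval"] <= 0) | (df["pval"] > 1),
        "bad_eaf": df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)),
        "bad_n": df["n"] <= 0,
        "alleles_equal": df["effect_allele"] == df["other_allele"],
        "case_control_mismatch": (
            df["n_case"].notna()
            & df["n_control"].notna()
            & (np.abs(df["n_case"] + df["n_control"] - df["n"]) > 0.5)
        ),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        mask = mask.fillna(False) & ~bad
        if mask.any():
            report.add_drop(reason, int(mask.sum()))
        bad |= mask
    out = df.loc[~bad].copy()

    # duplicate variant_id: keep the record with the smallest p
    if out["variant_id"].duplicated().any():
        before = len(out)
        out = (
            out.sort_values(["pval", "variant_id"], kind="mergesort")
            .drop_duplicates("variant_id", keep="first")
            .sort_index()
        )
        report.n_duplicates_removed = before - len(out)
    report.n_kept = len(out)
    out = out[list(CANONICAL_COLUMNS)].reset_index(drop=True)
    return out, report


def read_summary_stats(
    path: str | Path | io.IOBase,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        File path (or open text buffer) of a tab-delimited file with header.
    column_map
        Mapping from file header names to canonical names; defaults to
        :data:`DEFAULT_COLUMN_MAP`. Must cover every required field.

    Returns
    -------
    (table, report)
        Validated table in canonical columns and the drop accounting.
    """
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    covered = set(cmap.values())
    missing = set(REQUIRED_COLUMNS) - covered
    if missing:
        raise ConfigurationError(
            f"column map does not cover required fields: {sorted(missing)}"
        )
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    required_missing = set(REQUIRED_COLUMNS) - set(present.values())
    if required_missing:
        raise ConfigurationError(
            f"file lacks columns for required fields: {sorted(required_missing)}"
        )
    df = raw[list(present)].rename(columns=present)
    return validate_associations(df)


def write_summary_stats(
    df: pd.DataFrame,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a canonical table as a tab-delimited file with GWAS headers."""
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    inverse = {dst: src for src, dst in cmap.items()}
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    out = df[cols].rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------


class LDReference:
    """Signed correlation matrix over an ordered variant panel.

    Variants absent from the panel have no LD information; lookups involving
    them return ``None`` and callers apply their own missing-data policy.
    """

    def __init__(
        self,
        variant_ids: list[str],
        r: np.ndarray,
        positions: np.ndarray | None = None,
    ) -> None:
        r = np.asarray(r, dtype=float)
        if r.shape != (len(variant_ids), len(variant_ids)):
            raise ValueError("r must be square and match variant_ids")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("r must have unit diagonal")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("r entries must lie in [-1, 1]")
        self.variant_ids = list(variant_ids)
        self.r = r
        self.positions = (
            np.asarray(positions, dtype=np.int64) if positions is not None else None
        )
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __len__(self) -> int:
        return len(self.variant_ids)

    def r_value(self, a: str, b: str) -> float | None:
        """Signed correlation, or None if either variant is off-panel."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib])

    def r2(self, a: str, b: str) -> float | None:
        rv = self.r_value(a, b)
        return None if rv is None else rv * rv

    @classmethod
    def identity(cls, variant_ids: list[str]) -> "LDReference":
        return cls(variant_ids, np.eye(len(variant_ids)))

    @classmethod
    def from_files(
        cls, ids_path: str | Path, matrix_path: str | Path
    ) -> "LDReference":
        """Load from an id list (one id per line, optional second position
        column) plus a whitespace-delimited dense matrix."""
        ids: list[str] = []
        positions: list[int] = []
        with open(ids_path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(parts[0])
                if len(parts) > 1:
                    positions.append(int(parts[1]))
        r = np.loadtxt(matrix_path)
        if r.ndim == 0:
            r = r.reshape(1, 1)
        pos = np.array(positions) if len(positions) == len(ids) else None
        return cls(ids, r, pos)

    @classmethod
    def from_triplets(cls, triplets: pd.DataFrame | str | Path) -> "LDReference":
        """Build from long-format (id1, id2, r) rows; missing pairs are 0."""
        if not isinstance(triplets, pd.DataFrame):
            triplets = pd.read_csv(triplets, sep=r"\s+", header=None,
                                   names=["id1", "id2", "r"])
        ids = sorted(set(triplets["id1"]) | set(triplets["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for a, b, val in triplets.itertuples(index=False):
            r[idx[a], idx[b]] = val
            r[idx[b], idx[a]] = val
        np.fill_diagonal(r, 1.0)
        return cls(ids, r)

    @classmethod
    def block_concat(cls, refs: list["LDReference"]) -> "LDReference":
        """Block-diagonal concatenation; cross-block correlations are 0."""
        from scipy.linalg import block_diag

        ids: list[str] = []
        for ref in refs:
            ids.extend(ref.variant_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids across blocks")
        r = block_diag(*[ref.r for ref in refs]) if refs else np.zeros((0, 0))
        pos = None
        if refs and all(ref.positions is not None for ref in refs):
            pos = np.concatenate([ref.positions for ref in refs])
        return cls(ids, r, pos)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizedSet:
    """Exposure/outcome associations aligned to a shared effect allele.

    ``table`` has one row per SNP with columns variant_id, effect_allele,
    other_allele, beta_x, se_x, pval_x, eaf_x, n_x, beta_y, se_y, pval_y,
    eaf_y, n_y, flipped, proxy_used, palindromic. ``dropped`` records
    excluded SNPs with machine-readable reasons.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def subset(self, variant_ids) -> "HarmonizedSet":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return HarmonizedSet(
            self.table.loc[keep].reset_index(drop=True), self.dropped.copy()
        )


_H_COLS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_x", "se_x", "pval_x", "eaf_x", "n_x",
    "beta_y", "se_y", "pval_y", "eaf_y", "n_y",
    "flipped", "proxy_used", "palindromic",
]


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align exposure and outcome associations to the exposure effect allele.

    For SNPs where the outcome effect allele equals the exposure other
    allele, the outcome beta sign is flipped and its frequency complemented.
    Palindromic (A/T, C/G) SNPs whose minor-allele frequency exceeds
    ``palindrome_maf_limit`` are dropped as strand-ambiguous; palindromic
    SNPs at lower MAF are kept. Allele pairs that neither match nor swap are
    dropped with reason ``allele_mismatch``. The result covers the
    intersection of variant ids.
    """
    e = exposure.set_index("variant_id")
    o = outcome.set_index("variant_id")
    shared = [v for v in e.index if v in o.index]

    rows = []
    dropped = []
    for vid in shared:
        ex = e.loc[vid]
        ou = o.loc[vid]
        ea, oa = ex["effect_allele"], ex["other_allele"]
        yea, yoa = ou["effect_allele"], ou["other_allele"]
        flipped = False
        if (yea, yoa) == (ea, oa):
            beta_y, eaf_y = ou["beta"], ou.get("eaf", np.nan)
        elif (yea, yoa) == (oa, ea):
            flipped = True
            beta_y = -ou["beta"]
            eaf_y = 1 - ou["eaf"] if pd.notna(ou.get("eaf", np.nan)) else np.nan
        else:
            dropped.append({"variant_id": vid, "reason": "allele_mismatch"})
            continue
        palindromic = _is_palindromic(ea, oa)
        if palindromic:
            eaf = ex.get("eaf", np.nan)
            # ambiguity check requires a frequency; retained when missing
            if pd.notna(eaf) and min(eaf, 1 - eaf) > palindrome_maf_limit:
                dropped.append({"variant_id": vid, "reason": "dropped_palindromic"})
                continue
        rows.append({
            "variant_id": vid,
            "chrom": ex.get("chrom", ""),
            "pos": ex.get("pos", np.nan),
            "effect_allele": ea,
            "other_allele": oa,
            "beta_x": ex["beta"], "se_x": ex["se"],
            "pval_x": ex["pval"], "eaf_x": ex.get("eaf", np.nan),
            "n_x": ex["n"],
            "beta_y": beta_y, "se_y": ou["se"],
            "pval_y": ou["pval"], "eaf_y": eaf_y,
            "n_y": ou["n"],
            "flipped": flipped,
            "proxy_used": bool(ou.get("proxy_used", False)),
            "palindromic": palindromic,
        })
    table = pd.DataFrame(rows, columns=_H_COLS)
    drop_df = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    table = table[table["se_x"].notna() & table["se_y"].notna()].reset_index(drop=True)
    return HarmonizedSet(table, drop_df)


# ---------------------------------------------------------------------------
# Binary-trait rescaling
# ---------------------------------------------------------------------------


def _scaling_factor(n_case: float, n_control: float) -> float:
    if n_case <= 0 or n_control <= 0:
        raise ValueError("n_case and n_control must both be positive")
    mu = n_case / (n_case + n_control)
    return 1.0 / (mu * (1.0 - mu))


def scale_linear_to_logodds(beta, se, n_case, n_control):
    """Rescale linear-model effects on a binary trait to the log-odds scale.

    Multiplies beta and SE by ``1 / (mu * (1 - mu))`` with
    ``mu = n_case / (n_case + n_control)``. Symmetric in mu <-> 1-mu.
    """
    factor = _scaling_factor(n_case, n_control)
    return beta * factor, se * factor


def unscale_logodds_to_linear(beta, se, n_case, n_control):
    """Exact inverse of :func:`scale_linear_to_logodds`."""
    factor = _scaling_factor(n_case, n_control)
    return beta / factor, se / factor


def scale_binary_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply log-odds rescaling to a whole table, at most once.

    Uses per-row case/control counts. Tables already carrying a true
    ``scaled_logodds`` flag are returned unchanged (idempotence).
    """
    if "scaled_logodds" in df.columns and df["scaled_logodds"].all():
        return df
    out = df.copy()
    if out["n_case"].isna().any() or out["n_control"].isna().any():
        raise ValueError("case/control counts required to rescale a binary trait")
    mu = out["n_case"] / (out["n_case"] + out["n_control"])
    factor = 1.0 / (mu * (1.0 - mu))
    out["beta"] = out["beta"] * factor
    out["se"] = out["se"] * factor
    out["scaled_logodds"] = True
    return out
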