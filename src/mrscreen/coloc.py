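"""Bayesian colocalization of two association regions.

Per-SNP approximate Bayes factors under a single-causal-variant assumption,
combined into posterior probabilities for the five hypotheses: no
association (H0), trait-1-only (H1), trait-2-only (H2), two distinct causal
variants (H3), one shared causal variant (H4). All sums are carried in log
space so extreme z-scores cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocResult", "colocalize", "log_abf"]

#: default prior SD of a true effect for a quantitative trait
PRIOR_SD_QUANTITATIVE = 0.15
#: default prior SD on the log-odds scale for a case-control trait
PRIOR_SD_BINARY = 0.2

MIN_SHARED_SNPS = 10


@dataclass
class ColocResult:
    """Posterior probabilities H0..H4 for one locus."""

    pp: np.ndarray  # length 5: pp0..pp4
    n_snp: int
    p1: float
    p2: float
    p12: float
    per_snp: pd.DataFrame = field(default_factory=pd.DataFrame)
    estimable: bool = True
    note: str = ""

    @property
    def pp0(self) -> float:
        return float(self.pp[0])

    @property
    def pp1(self) -> float:
        return float(self.pp[1])

    @property
    def pp2(self) -> float:
        return float(self.pp[2])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for a single association.

    With V = se^2, W = prior_sd^2 and z = beta/se:
    log ABF = 0.5 * [log(V/(V+W)) + z^2 * W/(V+W)].
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def colocalize(
    region_x: pd.DataFrame,
    region_y: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_x: float = PRIOR_SD_QUANTITATIVE,
    prior_sd_y: float = PRIOR_SD_QUANTITATIVE,
) -> ColocResult:
    """Colocalize two regional association tables.

    Tables must share at least 10 variant ids after intersection; the
    intersection (by ``variant_id``) is used. Hypothesis weights are
    accumulated with log-sum-exp and normalized, so the returned posteriors
    sum to one exactly up to floating-point rounding.
    """
    xi = region_x.set_index("variant_id")
    yi = region_y.set_index("variant_id")
    shared = [v for v in xi.index if v in yi.index]
    if len(shared) < MIN_SHARED_SNPS:
        return ColocResult(
            np.full(5, np.nan), len(shared), p1, p2, p12,
            estimable=False,
            note=f"only {len(shared)} shared SNPs (need >= {MIN_SHARED_SNPS})",
        )
    lx = np.asarray(log_abf(xi.loc[shared, "beta"], xi.loc[shared, "se"], prior_sd_x))
    ly = np.asarray(log_abf(yi.loc[shared, "beta"], yi.loc[shared, "se"], prior_sd_y))

    sum_x = logsumexp(lx)
    sum_y = logsumexp(ly)
    sum_xy = logsumexp(lx + ly)
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + sum_x
    log_h[2] = np.log(p2) + sum_y
    # H3: all ordered distinct pairs = (sum_x * sum_y - sum_xy) in log space
    cross = sum_x + sum_y
    if sum_xy >= cross:
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(p1) + np.log(p2) + cross + np.log1p(-np.exp(sum_xy - cross))
    log_h[4] = np.log(p12) + sum_xy
    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    per_snp = pd.DataFrame({"variant_id": shared, "log_abf_x": lx, "log_abf_y": ly})
    return ColocResult(pp, len(shared), p1, p2, p12, per_snp=per_snp)
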