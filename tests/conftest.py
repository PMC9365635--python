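import numpy as np
import pandas as pd
import pytest

from mrscreen import gwas_data, simulate


def make_assoc_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical association table from partial row dicts."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-10,
        "n": 10_000,
        "n_case": np.nan,
        "n_control": np.nan,
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["variant_id"] = f"rs{i}"
        rec["pos"] = 1000 + i * 2_000_000
        rec.update(row)
        full.append(rec)
    return pd.DataFrame(full, columns=list(gwas_data.CANONICAL_COLUMNS))


@pytest.fixture
def assoc_frame_factory():
    return make_assoc_frame


@pytest.fixture
def harmonized_factory():
    """Harmonized set straight from arrays (identical alleles both sides)."""

    def build(beta_x, se_x, beta_y, se_y, n_x=50_000, n_y=100_000):
        beta_x = np.asarray(beta_x, float)
        j = len(beta_x)
        table = pd.DataFrame({
            "variant_id": [f"rs{i}" for i in range(j)],
            "chrom": "1",
            "pos": 1000 + 2_000_000 * np.arange(j),
            "effect_allele": "A",
            "other_allele": "G",
            "beta_x": beta_x,
            "se_x": np.broadcast_to(np.asarray(se_x, float), (j,)).copy(),
            "pval_x": 1e-10,
            "eaf_x": 0.3,
            "n_x": float(n_x),
            "beta_y": np.asarray(beta_y, float),
            "se_y": np.broadcast_to(np.asarray(se_y, float), (j,)).copy(),
            "pval_y": 0.5,
            "eaf_y": 0.3,
            "n_y": float(n_y),
            "flipped": False,
            "proxy_used": False,
            "palindromic": False,
        })
        return gwas_data.HarmonizedSet(
            table, pd.DataFrame(columns=["variant_id", "reason"]))

    return build


@pytest.fixture
def simulated_pair():
    """One strong 50-SNP simulated exposure/outcome pair, harmonized."""
    truth = simulate.make_truth(50, 0.3, seed=424242)
    exp, out = simulate.simulate_two_sample(truth)
    return truth, gwas_data.harmonize(exp, out)
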