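import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import HarmonizedSet, SumStatTable


def make_table(trait_id="X", trait_type="continuous", **overrides):
    """Small valid 3-record table; columns overridable per test."""
    base = {
        "variant_id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "2"],
        "pos": [1000, 2000, 3000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.2, 0.5, 0.7],
        "beta": [0.10, -0.05, 0.20],
        "se": [0.01, 0.02, 0.03],
        "pval": [1e-8, 0.01, 1e-6],
        "n": [10000, 10000, 10000],
    }
    base.update(overrides)
    return SumStatTable(trait_id, trait_type, pd.DataFrame(base))


def make_harmonized(beta_exp, beta_out, se_exp=None, se_out=None, n=50_000) -> HarmonizedSet:
    """Harmonized set straight from effect arrays (exposure frame assumed)."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(k, 0.02) if se_out is None else np.asarray(se_out, float)
    ids = [f"rs{i + 1}" for i in range(k)]
    rows = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": 1 + 2_000_000 * np.arange(k),
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": 0.3,
            "n_exp": n,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": 0.3,
            "n_out": n,
        }
    )
    audit = pd.DataFrame({"variant_id": ids, "action": "kept"})
    return HarmonizedSet("X", "Y", rows, audit)


def random_harmonized(rng, k=None) -> HarmonizedSet:
    """Randomized small instance for oracle-equivalence checks."""
    k = k if k is not None else int(rng.integers(3, 12))
    beta_exp = rng.uniform(0.05, 0.4, k) * rng.choice([-1.0, 1.0], k)
    beta_out = rng.normal(0.2 * beta_exp, 0.03)
    se_exp = rng.uniform(0.005, 0.03, k)
    se_out = rng.uniform(0.01, 0.05, k)
    return make_harmonized(beta_exp, beta_out, se_exp, se_out)


@pytest.fixture
def rng():
    return np.random.default_rng(20250912)
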