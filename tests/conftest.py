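import numpy as np
import pytest

from mrgrip import SummaryDataset, synthetic_base_effects


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def toy_ds():
    """Small hand-sized dataset with mixed signs and unequal precision."""
    return SummaryDataset(
        snp_id=np.array(["rs1", "rs2", "rs3", "rs4", "rs5"], dtype=object),
        beta_exp=np.array([0.12, -0.08, 0.25, 0.05, -0.30]),
        se_exp=np.array([0.01, 0.012, 0.02, 0.008, 0.015]),
        beta_out=np.array([0.03, -0.01, 0.06, 0.02, -0.05]),
        se_out=np.array([0.015, 0.02, 0.03, 0.012, 0.025]),
        effect_allele=np.array(list("ACGTA"), dtype=object),
        other_allele=np.array(list("GTACC"), dtype=object),
    )


def random_dataset(rng, m=20):
    """Random strong-instrument dataset with mixed allele orientation."""
    base = synthetic_base_effects(m, rng)
    beta = 0.2
    g = rng.normal(base.gamma, base.se_exp)
    G = rng.normal(beta * base.gamma, base.se_out)
    return SummaryDataset(
        snp_id=np.array([f"snp{i}" for i in range(m)], dtype=object),
        beta_exp=g, se_exp=base.se_exp, beta_out=G, se_out=base.se_out,
    )


@pytest.fixture
def make_random_dataset():
    return random_dataset
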