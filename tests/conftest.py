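import numpy as np
import pandas as pd
import pytest

from famgwas.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small family cohort with LD, dominance, indirect effects and
    assortment -- shared across unit tests."""
    cfg = SimConfig(
        n_snps=300, n_blocks=60, within_block_r=0.4, n_founder_pairs=400,
        n_generations=2, h2_add=0.3, h2_dom=0.1, indirect_scale=0.2,
        target_mate_r=0.3, seed=7,
    )
    cohort, arch = simulate_cohort(cfg)
    return cfg, cohort, arch


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_sumstats(**overrides):
    """Three-SNP summary-statistics frame used by meta/clump/pgi tests."""
    base = {
        "snp_id": ["A", "B", "C"],
        "chr": 1,
        "pos": [1, 2, 3],
        "a1": "A",
        "a2": "G",
        "freq_a1": 0.3,
        "n": 100,
        "beta": [0.5, 0.4, 0.3],
        "se": [0.1, 0.1, 0.1],
        "z": [5.0, 4.0, 3.0],
        "p": [1e-6, 1e-5, 1e-4],
        "coding": "additive_012",
    }
    base.update(overrides)
    return pd.DataFrame(base)
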