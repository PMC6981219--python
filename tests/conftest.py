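import numpy as np
import pytest

from consensusde import SimConfig, run_grid, simulate_dataset
from consensusde.data import CountMatrix, StudyDesign


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cm():
    """Deterministic 50-gene x 6-sample count matrix with lengths."""
    rng = np.random.default_rng(7)
    counts = rng.negative_binomial(5, 0.05, size=(50, 6))
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(50)],
        sample_ids=[f"s{j}" for j in range(6)],
        counts=counts,
        gene_lengths_bp=rng.integers(300, 5000, 50),
    )


@pytest.fixture(scope="session")
def design6(small_cm):
    return StudyDesign(small_cm.sample_ids, ["saline"] * 3 + ["cocaine"] * 3)


@pytest.fixture(scope="session")
def planted():
    """Mid-size planted-effect dataset shared by slower tests."""
    cfg = SimConfig(n_genes=1200, n_per_group=6, frac_de=0.1, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_grid(planted):
    cm, design, _ = planted
    return run_grid(cm, design)
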