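import numpy as np
import pytest

from ldsplit import EstimatorConfig, HaplotypePanel, SimConfig, SnpRecord
from ldsplit.simulate import evolve, sample_panels


def make_panel(matrix, positions=None, ids=None, **snp_kwargs) -> HaplotypePanel:
    """Build a panel from a 0/1 matrix with default metadata."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(matrix.shape[1])]
    snps = [
        SnpRecord(f"s{i}", int(p), **snp_kwargs) for i, p in enumerate(positions)
    ]
    return HaplotypePanel(matrix, snps, ids or [])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_estimator():
    return EstimatorConfig(seed=0, n_orderings=2, n_iterations=20)


@pytest.fixture(scope="session")
def sim_sample():
    """One small simulated benchmark sample with a planted causal SNP."""
    cfg = SimConfig(
        pop_size=300,
        generations=200,
        start_hot_freq=1.0,
        end_hot_freq=0.5,
        mutation_rate=0.03,
        init_sites=200,
        seed=7,
    )
    pop, _ = evolve(cfg)
    sample = sample_panels(pop, cfg, rng=8, n_subsets=1, subset_size=25)[0]
    return cfg, sample


@pytest.fixture(scope="session")
def null_panel():
    """A neutral panel: same forward model with the hotspot never active."""
    cfg = SimConfig(
        pop_size=300,
        generations=200,
        start_hot_freq=0.0,
        end_hot_freq=0.0,
        mutation_rate=0.03,
        init_sites=700,
        seed=31,
    )
    pop, _ = evolve(cfg)
    return sample_panels(pop, cfg, rng=32, n_subsets=1, subset_size=25)[0].panel
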