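import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import drivernmf as d

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast cohort for fit-level tests."""
    cfg = d.SimulationConfig(
        n_samples=30,
        n_genes=60,
        n_subtypes=2,
        drivers_per_subtype=5,
        expr_genes=40,
        seed=7,
    )
    return d.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_aligned(tiny_cohort):
    return d.align_datasets(
        tiny_cohort.mutation, tiny_cohort.expression, tiny_cohort.network
    )


@pytest.fixture(scope="session")
def tiny_priors(tiny_aligned):
    return d.build_priors(tiny_aligned)


def random_instance(rng, n=8, p=10, K=3, density=0.3):
    """Random binary matrix with random (but valid) priors, for update tests."""
    X = (rng.random((n, p)) < density).astype(float)
    rho = np.corrcoef(rng.normal(size=(n, max(5, n))))
    sample = d.similarity_from_correlation(rho, sigma=1.0)
    gene_ids = [f"g{j}" for j in range(p)]
    edges = set()
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.2:
                edges.add(frozenset((gene_ids[i], gene_ids[j])))
    net = d.GeneNetwork(gene_ids=gene_ids, edges=edges)
    gene = d.build_network_priors(net, gene_ids)
    return X, d.PriorsBundle(sample=sample, gene=gene)
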