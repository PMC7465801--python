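import numpy as np
import pytest

from pipegrid.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def sim3():
    """Three subpopulations with injected doublets and low-quality cells."""
    return simulate_dataset(
        SimParams(
            n_genes=600,
            n_cells=1000,
            n_subpops=3,
            doublet_rate=0.05,
            lowq_rate=0.05,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def sim2_doublets():
    """Two well-separated subpopulations with 10% heterotypic doublets."""
    return simulate_dataset(
        SimParams(n_genes=600, n_cells=1000, n_subpops=2, doublet_rate=0.1, seed=3)
    )


def planted_rank_nb(
    n_genes=400,
    n_cells=1000,
    d=4,
    base_range=(1.0, 3.0),
    strength=1.0,
    dispersion=0.05,
    seed=0,
):
    """NB counts whose log-mean matrix is exactly rank d plus an intercept.

    Low dispersion keeps the two halves of a binomial count split close to
    independent (the gamma component of NB noise is shared between halves).
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(*base_range, n_genes)
    U = rng.normal(0, strength / np.sqrt(d), (n_genes, d))
    V = rng.normal(0, 1, (d, n_cells))
    mu = np.exp(np.clip(base[:, None] + U @ V, -6, 9))
    size = 1.0 / dispersion
    return rng.poisson(rng.gamma(size, mu / size))
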