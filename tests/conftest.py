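import numpy as np
import pytest

from scatgen.identity import AlleleFrequencies
from scatgen.simulate import SimConfig, simulate_population, simulate_replicate_table


@pytest.fixture(scope="session")
def field_scale_run():
    """One field-scale synthetic dataset shared across read-only tests."""
    cfg = SimConfig(seed=1)
    pop = simulate_population(cfg)
    table, truth = simulate_replicate_table(pop, cfg)
    return cfg, pop, table, truth


@pytest.fixture
def uniform_freqs():
    """Eight 4-allele loci with equal frequencies (theoretical, no counts)."""
    loci = [f"L{i}" for i in range(8)]
    return AlleleFrequencies(
        freqs={l: {100 + 2 * j: 0.25 for j in range(4)} for l in loci},
        n_genes={l: 0 for l in loci})


def random_genotypes(rng, n_ind, n_loci, k=4, prefix="L"):
    """iid Hardy-Weinberg genotypes at independent loci."""
    genos = {f"i{j}": {} for j in range(n_ind)}
    for l in range(n_loci):
        p = rng.dirichlet(np.full(k, 3.0))
        for j in range(n_ind):
            a, b = rng.choice(k, size=2, p=p)
            genos[f"i{j}"][f"{prefix}{l}"] = tuple(
                sorted((int(a) + 100, int(b) + 100)))
    return genos
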