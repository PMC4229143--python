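import numpy as np
import pandas as pd
import pytest

from switchgs.simulate import SimConfig, simulate_genotypes, simulate_panel, simulate_structure


@pytest.fixture(scope="session")
def small_panel():
    """120-genotype structured panel with one h2=0.8 trait (session-cached)."""
    cfg = SimConfig(
        n_populations=20, clones_per_population=6, n_markers=400, n_qtl=50,
        h2_clone_mean=0.8, rng_seed=42,
    )
    matrix, pop_of, trial, truths = simulate_panel(cfg, ["t1"])
    return cfg, matrix, pop_of, trial, truths["t1"]


@pytest.fixture(scope="session")
def structured_genotypes():
    """3-cluster panel for structure/PCA tests: 180 samples, 1200 markers."""
    cfg = SimConfig(
        n_populations=18, clones_per_population=10, n_clusters=3, fst=0.2,
        n_markers=1200, rng_seed=7,
    )
    pop_freqs, labels = simulate_structure(cfg)
    matrix, pop_of = simulate_genotypes(pop_freqs, cfg)
    return cfg, matrix, pop_of, labels
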