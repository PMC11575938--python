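import numpy as np
import pandas as pd
import pytest

import duplipath as dp


@pytest.fixture(scope="session")
def default_config():
    return dp.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def catalog(default_config):
    return dp.generate_catalog(default_config)


@pytest.fixture(scope="session")
def counts_bundle(catalog, default_config):
    counts, metadata, truth = dp.simulate_counts(catalog, default_config)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def fpkm_matrix(catalog, counts_bundle):
    counts, _, _ = counts_bundle
    lengths = pd.Series({r.gene_id: max(r.cds_length, 1) for r in catalog.records})
    return dp.compute_fpkm(counts, lengths)


@pytest.fixture(scope="session")
def panel_bundle(catalog, default_config):
    return dp.simulate_multistress_panel(catalog, default_config)


def null_nb_counts(n_genes: int, dispersion: float, seed: int, n_per_group: int = 3):
    """Null (no-effect) NB count matrix with CK/UV metadata."""
    rng = np.random.default_rng(seed)
    mu = 500 * np.exp(rng.normal(0, 0.6, n_genes))
    if dispersion == 0:
        x = rng.poisson(mu[:, None], size=(n_genes, 2 * n_per_group))
    else:
        r = 1 / dispersion
        x = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, 2 * n_per_group))
    cols = [f"CK_{i}" for i in range(n_per_group)] + [f"UV_{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    metadata = pd.DataFrame(
        {"condition": ["CK"] * n_per_group + ["UV"] * n_per_group}, index=counts.columns
    )
    return counts, metadata
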