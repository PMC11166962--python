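import logging

import pytest

from crosstrait.synthetic import SimulationConfig, generate_dataset

# silence expected per-row warnings from recovery fixtures
logging.getLogger("crosstrait.enrichment").setLevel(logging.ERROR)
logging.getLogger("crosstrait.coexpression").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study conditions for fast unit tests."""
    return SimulationConfig(
        seed=7,
        n_snps_per_trait=60,
        frac_significant=0.5,
        n_decoy_snps=10,
        universe_size=500,
        n_eqtl_pairs_a=20,
        n_eqtl_pairs_b=30,
        n_genes_a=15,
        n_genes_b=25,
        planted_shared_genes=4,
        frac_trans=0.1,
        n_nonsig_eqtl_rows=40,
        n_decoy_eqtl_rows=10,
        n_samples=100,
        module_spec=((12, 0.85), (10, 0.8)),
        n_background_genes=40,
        n_terms=25,
        term_size_range=(5, 25),
        planted_enriched_terms=2,
        n_annotation_universe=400,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_inputs(small_dataset, tmp_path_factory):
    """The small dataset written to disk as the four input files."""
    out = tmp_path_factory.mktemp("inputs")
    return small_dataset.write(out)
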