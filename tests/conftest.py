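import pytest

from matrisome_atlas import SimConfig, generate_all, infer_all_signatures


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: 3 tumors x 80 samples, 5 planted modules each."""
    return SimConfig(
        n_tumor_types=3,
        samples_per_tumor=80,
        healthy_per_tissue=30,
        n_genes=120,
        n_matrisome=30,
        n_tfs=20,
        planted_modules_per_tumor=5,
        signature_genes_per_tumor=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def small_signatures(small_data):
    return infer_all_signatures(
        small_data["expr"], small_data["annot"], small_data["catalog"]
    )
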