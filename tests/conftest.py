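import pytest

from tesplice import synthetic_data


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (both haplotypes), generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return synthetic_data.generate_dataset(out, seed=1)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced bundle for tests that only need structure, not scale."""
    cfg = synthetic_data.SyntheticConfig(
        n_genes=24,
        n_forward_intronic=10,
        n_reverse_intronic=4,
        n_exonic=3,
        n_intergenic=3,
        n_intergenic_secondary=2,
        smallrna_reads_per_family=500,
        cluster_len=20000,
        cluster_region=(2000, 18000),
        cluster_n_rearranged=3,
    )
    out = tmp_path_factory.mktemp("small_bundle")
    return synthetic_data.generate_dataset(out, seed=11, config=cfg)


@pytest.fixture(scope="session")
def l3():
    return synthetic_data.make_l3_fixture()
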