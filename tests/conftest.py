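import numpy as np
import pytest

from virome import catalog, synthgen


@pytest.fixture(scope="session")
def small_study() -> synthgen.SimulatedStudy:
    """A compact but complete synthetic study shared across test modules."""
    cfg = synthgen.SimulationConfig(
        seed=3, n_species=30, members_per_species=2, n_decoys=10,
        n_hosts=12, n_samples_group_a=15, n_samples_group_b=15,
        depth=50_000, n_diff=6, n_planted_edges=4, n_crispr_links=8,
        n_prophage_links=4, n_bacteria=20,
        genome_length_range=(5_000, 10_000))
    return synthgen.simulate(cfg)


@pytest.fixture(scope="session")
def small_catalog(small_study):
    records = catalog.records_from_evidence(
        small_study.evidence, small_study.contigs)
    return catalog.build_catalog(small_study.contigs, records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
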