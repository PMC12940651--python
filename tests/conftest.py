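import pytest

import famscan as fs

#: compact study conditions for unit tests: 3 chromosomes x 120 genes,
#: 12 family genes, tandem arrays of 2 and 3, segmental blocks with 5 and 8
#: anchors (5 sits exactly at the rejection boundary of the >5 rule)
SMALL_CONFIG = dict(
    n_chromosomes=3,
    genes_per_chromosome=120,
    n_family=12,
    n_tandem_arrays=2,
    array_sizes=(2, 3),
    n_segmental_blocks=2,
    anchors_per_block=(5, 8),
    window=10,
    seed=101,
)


@pytest.fixture(scope="session")
def table():
    return fs.load_family_table()


@pytest.fixture(scope="session")
def profiles():
    """Packaged profiles, calibrated once per session."""
    return fs.default_profiles(n_shuffles=300, seed=11)


@pytest.fixture(scope="session")
def small_genome():
    cfg = fs.GenomeConfig(**SMALL_CONFIG)
    models, proteins, truth = fs.generate_genome(cfg)
    return cfg, models, proteins, truth
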