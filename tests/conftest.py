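import numpy as np
import pytest

from msq import SyntheticParams, build_all_R, generate_synthetic


def small_dataset(seed=0, **overrides):
    """A small validated synthetic dataset for unit tests."""
    params = dict(
        n_individuals=8,
        n_chromosomes=2,
        markers_per_chrom=10,
        morgans_per_chrom=1.0,
        allele_freq=0.4,
        n_traits=2,
        n_families=0,
    )
    params.update(overrides)
    return generate_synthetic(SyntheticParams(**params), seed=seed)


@pytest.fixture(scope="session")
def dataset():
    return small_dataset()


@pytest.fixture(scope="session")
def bundle(dataset):
    return dataset.bundle()


@pytest.fixture(scope="session")
def R_haldane(bundle):
    return build_all_R(bundle.gmap, "haldane")


def random_parent(rng, L):
    """Random phased haplotype pair guaranteed at least one heterozygous locus."""
    while True:
        haps = rng.integers(0, 2, size=(2, L), dtype=np.uint8)
        if np.any(haps[0] != haps[1]):
            return haps
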