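import numpy as np
import pytest

from divabc.simulate import MISSING, HaplotypeMatrix
from divabc.synthetic_data import generate_masks


@pytest.fixture
def rng():
    return np.random.default_rng(20130942)


def random_species_matrix(
    rng, n_rows=None, n_sites=None, missing_prob=0.15, length=None
):
    """A random haploid 0/1 matrix with scattered missingness."""
    n_rows = n_rows or int(rng.integers(4, 12))
    n_sites = n_sites or int(rng.integers(1, 15))
    alleles = rng.integers(0, 2, size=(n_rows, n_sites)).astype(np.int8)
    miss = rng.random((n_rows, n_sites)) < missing_prob
    alleles[miss] = MISSING
    return alleles


@pytest.fixture(scope="session")
def desk_locus_set():
    """The desk-scale study stand-in: 20 loci x 500 bp, 10+10 individuals."""
    rng = np.random.default_rng(777)
    return generate_masks(n_loci=20, length=500, rng=rng)


@pytest.fixture(scope="session")
def tiny_locus_set():
    """A very small locus set for smoke-level pipeline runs."""
    rng = np.random.default_rng(778)
    return generate_masks(n_loci=6, length=300, rng=rng)


@pytest.fixture(scope="session")
def rmasc_desk_table(desk_locus_set):
    """Desk-scale RMASC reference table shared by the calibration tests.

    2e4 rows at 20 loci x 500 bp; built once per session (several
    minutes) and reused by the acceptance-level calibration checks.
    """
    from divabc.simulate import simulate_reference_table

    return simulate_reference_table(
        "RMASC", desk_locus_set, 20_000, root_seed=424242
    )
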