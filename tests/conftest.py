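import numpy as np
import pytest

from breedopt import FounderSpec, generate_founders, scenario_trait_model
from breedopt.genome import PhasedGenomeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """20 individuals x 50 markers over 5 chromosomes, common alleles."""
    genomes, gmap = generate_founders(
        FounderSpec(n_individuals=20, n_markers=50, n_chromosomes=5, min_maf=0.1),
        rng,
    )
    return genomes, gmap


@pytest.fixture
def tiny_ocs_instance(rng):
    """12-candidate, J=4 instance small enough to enumerate exhaustively."""
    genomes, _ = generate_founders(
        FounderSpec(n_individuals=12, n_markers=50, n_chromosomes=5, min_maf=0.1),
        rng,
    )
    model = scenario_trait_model(genomes.n_markers, rng)
    return genomes, model


def make_genomes(alleles, chrom=None, pos=None):
    """Build a PhasedGenomeMatrix from a raw (n, p, 2) allele array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, p, _ = alleles.shape
    if chrom is None:
        chrom = np.array(["chr1"] * p, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    if pos is None:
        pos = np.arange(1, p + 1) * 100
    return PhasedGenomeMatrix(
        alleles,
        [f"i{i}" for i in range(n)],
        [f"m{k}" for k in range(p)],
        chrom,
        pos,
    )
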