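import numpy as np
import pytest

from famada.famsim import three_generation_template
from famada.pedio import HaplotypeSet, Individual, Pedigree, Site


@pytest.fixture
def trio_ped() -> Pedigree:
    """Father, mother, child."""
    return Pedigree([
        Individual("T", "1", None, None, 1),
        Individual("T", "2", None, None, 2),
        Individual("T", "3", "1", "2", 1),
    ])


@pytest.fixture
def nuclear_ped() -> Pedigree:
    """Two parents, two full sibs."""
    return Pedigree([
        Individual("N", "1", None, None, 1),
        Individual("N", "2", None, None, 2),
        Individual("N", "3", "1", "2", 1),
        Individual("N", "4", "1", "2", 2),
    ])


@pytest.fixture
def family12_ped() -> Pedigree:
    """The three-generation 12-member family template."""
    return three_generation_template()


def make_haps(ped: Pedigree, hap_by_iid: dict[str, tuple]) -> HaplotypeSet:
    """Build a HaplotypeSet from per-individual (hap0, hap1) allele tuples."""
    L = len(next(iter(hap_by_iid.values()))[0])
    haps = np.zeros((ped.n, 2, L), dtype=np.uint8)
    for i, m in enumerate(ped.members):
        h0, h1 = hap_by_iid[m.iid]
        haps[i, 0] = h0
        haps[i, 1] = h1
    sites = [Site(f"s{l}", l + 1) for l in range(L)]
    return HaplotypeSet(sites, haps)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(key=20240101))
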