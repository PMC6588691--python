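import pytest

from ystrped.registry import default_registry
from ystrped.types import Haplotype, Pedigree


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_pair_pedigree(lineage="L1", depth_a=4, depth_b=5, years=None):
    """Simple two-leaf pedigree: root with two descending branches."""
    ped = Pedigree(lineage)
    ped.birth_year["R"] = 1800.0
    for branch, depth in (("a", depth_a), ("b", depth_b)):
        node = "R"
        for i in range(depth):
            child = f"{branch}{i + 1}"
            ped.father[child] = node
            if years is not None:
                ped.birth_year[child] = ped.birth_year[node] + years
            node = child
        ped.sample_of[node] = f"{lineage}.{branch}"
    return ped


def make_trio_pedigree(lineage="T1", depth_a=5, depth_c=2, depth_b=4, depth_d=4):
    """Three-leaf pedigree: outgroup branch a, inner ancestor c with
    branches b and d."""
    ped = Pedigree(lineage)

    def grow(branch, start, depth):
        node = start
        for i in range(depth):
            child = f"{branch}{i + 1}"
            ped.father[child] = node
            node = child
        return node

    leaf_a = grow("a", "R", depth_a)
    inner = grow("c", "R", depth_c)
    leaf_b = grow("b", inner, depth_b)
    leaf_d = grow("d", inner, depth_d)
    for leaf, name in ((leaf_a, "a"), (leaf_b, "b"), (leaf_d, "d")):
        ped.sample_of[leaf] = f"{lineage}.{name}"
    return ped


def make_haplotype(sample_id, alleles, lineage="L1", haplogroup="R-M269>U152"):
    return Haplotype(sample_id, lineage, haplogroup, alleles)


@pytest.fixture
def pair_pedigree():
    return make_pair_pedigree()


@pytest.fixture
def trio_pedigree():
    return make_trio_pedigree()
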