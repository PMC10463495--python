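import numpy as np
import pytest

from ccs.datasets import cleaner_fish_tree, cleaner_fish_traits
from ccs.io import AminoAlignment, TraitMap
from ccs.model import SubstitutionModel
from ccs.tree import Phylogeny


@pytest.fixture(scope="session")
def jtt():
    return SubstitutionModel.jtt(alpha=0.7, n_categories=4)


@pytest.fixture(scope="session")
def jtt_k1():
    return SubstitutionModel.jtt(alpha=1.0, n_categories=1)


@pytest.fixture(scope="session")
def fish_tree():
    return cleaner_fish_tree()


@pytest.fixture(scope="session")
def fish_traits():
    return cleaner_fish_traits()


@pytest.fixture
def quartet():
    return Phylogeny.from_newick(
        "((A:0.10,B:0.20):0.15,(C:0.30,D:0.05):0.20);"
    )


@pytest.fixture
def triplet():
    return Phylogeny.from_newick("((A:0.10,B:0.20):0.15,C:0.30);")


@pytest.fixture
def five_taxon_traits():
    return TraitMap.create(["F1", "F2", "F3"], ["B1", "B2"], "B2")


def make_alignment(seqs: dict[str, str], gene: str = "") -> AminoAlignment:
    return AminoAlignment.from_sequences(seqs, orthogroup_id=gene)
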