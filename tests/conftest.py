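import random

import pytest

from hgtrace import Alignment, CriteriaConfig, PhyloTree, TaxonRecord


@pytest.fixture
def config():
    return CriteriaConfig()


@pytest.fixture
def toy_alignment():
    return Alignment([
        ("a", "ACD-F"),
        ("b", "ACD-F"),
        ("c", "AMDG-"),
        ("d", "A-D--"),
    ])


@pytest.fixture
def five_leaf_tree():
    return PhyloTree.from_string("(((A:1,B:1)90:0.3,C:1)80:1,(D:1,E:1)95:1);")


@pytest.fixture
def mixed_taxa():
    taxa = [TaxonRecord(f"B{i}", f"bact {i}", "bacteria", "", "bsurvey", "genome")
            for i in range(1, 7)]
    taxa += [
        TaxonRecord("E1", "euk 1", "eukaryote", "Amoebozoa", "study_A", "genome"),
        TaxonRecord("E2", "euk 2", "eukaryote", "Amoebozoa", "study_B", "transcriptome"),
        TaxonRecord("E3", "euk 3", "eukaryote", "Rhizaria", "study_A", "genome"),
    ]
    return taxa


def random_tree(rng: random.Random, n_leaves: int, labels=None) -> PhyloTree:
    """A random binary tree built by sequential attachment, with uniform
    random branch lengths — a topology generator for property tests."""
    if labels is None:
        labels = [f"L{i:02d}" for i in range(n_leaves)]
    assert len(labels) == n_leaves and n_leaves >= 2

    def bl():
        return round(rng.uniform(0.1, 2.0), 3)

    subtrees = [f"{labels[0]}:{bl()}", f"{labels[1]}:{bl()}"]
    for label in labels[2:]:
        i = rng.randrange(len(subtrees))
        subtrees[i] = f"({subtrees[i]},{label}:{bl()}):{bl()}"
    return PhyloTree.from_string(f"({','.join(subtrees)});")
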