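"""Shared fixtures: the standard synthetic world and small handmade databases."""

import numpy as np
import pytest

from hogqc.hogdb import HOG, HOGMember, build_database
from hogqc.simulate import generate_world
from hogqc.taxonomy import TaxNode, TaxTree


@pytest.fixture(scope="session")
def world():
    """The standard 24-species / 320-family study world."""
    return generate_world(seed=1)


@pytest.fixture(scope="session")
def query_records(world):
    return world.query_records()


def make_tree(edges, ranks=None):
    """Build a TaxTree from (child, parent) pairs; parent None = root."""
    ranks = ranks or {}
    nodes = {}
    for child, parent in edges:
        nodes[child] = TaxNode(node_id=child, parent=parent,
                               rank=ranks.get(child, "no rank"))
    for child, parent in edges:
        if parent is not None:
            nodes[parent].children.append(child)
    return TaxTree(nodes.values())


@pytest.fixture()
def small_tree():
    """root -> (A -> {s1, s2, s3}, B -> {s4, s5})."""
    return make_tree(
        [
            ("root", None),
            ("A", "root"),
            ("B", "root"),
            ("s1", "A"),
            ("s2", "A"),
            ("s3", "A"),
            ("s4", "B"),
            ("s5", "B"),
        ],
        ranks={"root": "domain", "A": "family", "B": "genus",
               "s1": "species", "s2": "species", "s3": "species",
               "s4": "species", "s5": "species"},
    )


def random_protein(rng, length):
    from hogqc.hogdb import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture()
def tiny_db(small_tree):
    """Two handmade families with sequences, indexed at k=6.

    fam1 spans the whole tree with one sub-HOG at A; fam2 is private to
    B.  Sequences are mutated copies of per-family ancestors, so member
    sequences share most of their k-mers within a family.
    """
    rng = np.random.default_rng(42)
    anc1 = rng.integers(0, 20, size=120)
    anc2 = rng.integers(0, 20, size=80)
    from hogqc.hogdb import AMINO_ACIDS

    def mutate(seq, n):
        out = seq.copy()
        pos = rng.choice(len(seq), size=n, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 20, size=n)) % 20
        return out

    def s(arr):
        return "".join(AMINO_ACIDS[i] for i in arr)

    fam1 = HOG(hog_id="fam1", level="root")
    fam1.members = [
        HOGMember("s4", "s4.f1", 120, s(mutate(anc1, 3))),
        HOGMember("s5", "s5.f1", 120, s(mutate(anc1, 3))),
    ]
    fam1_sub = HOG(hog_id="fam1.A", level="A", parent_hog="fam1")
    fam1_sub.members = [
        HOGMember("s1", "s1.f1", 120, s(mutate(anc1, 6))),
        HOGMember("s2", "s2.f1", 120, s(mutate(anc1, 6))),
        HOGMember("s3", "s3.f1", 120, s(mutate(anc1, 6))),
    ]
    fam2 = HOG(hog_id="fam2", level="B")
    fam2.members = [
        HOGMember("s4", "s4.f2", 80, s(mutate(anc2, 2))),
        HOGMember("s5", "s5.f2", 80, s(mutate(anc2, 2))),
    ]
    return build_database(small_tree, [fam1, fam1_sub, fam2], k=6)
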