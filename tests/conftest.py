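import numpy as np
import pandas as pd
import pytest

from meiodiv import OtuTable, ReferenceTree, SampleMetadata
from meiodiv.jplace import parse_edge_numbered_newick


def make_reference_tree(newick: str, lineages: dict[str, list[tuple[str, str]]]) -> ReferenceTree:
    tree, edge_map = parse_edge_numbered_newick(newick)
    return ReferenceTree(tree=tree, lineages=lineages, edge_map=edge_map)


@pytest.fixture
def two_species_tree() -> ReferenceTree:
    """((A1,A2),(B1,B2)): species X and Y, both in genus G.

    Edge numbers: pendants A1=0, A2=1, B1=2, B2=3; clade stems 4 (X) and
    5 (Y); root edge 6.
    """
    nwk = "((A1:1{0},A2:1{1}):1{4},(B1:1{2},B2:1{3}):1{5}):0{6};"
    lin = {
        "A1": [("genus", "G"), ("species", "X")],
        "A2": [("genus", "G"), ("species", "X")],
        "B1": [("genus", "G"), ("species", "Y")],
        "B2": [("genus", "G"), ("species", "Y")],
    }
    return make_reference_tree(nwk, lin)


@pytest.fixture
def interleaved_tree() -> ReferenceTree:
    """((A1,B1),(A2,B2)): species X's leaves do not form a clade."""
    nwk = "((A1:1{0},B1:1{1}):1{4},(A2:1{2},B2:1{3}):1{5}):0{6};"
    lin = {
        "A1": [("genus", "G"), ("species", "X")],
        "A2": [("genus", "G"), ("species", "X")],
        "B1": [("genus", "G"), ("species", "Y")],
        "B2": [("genus", "G"), ("species", "Y")],
    }
    return make_reference_tree(nwk, lin)


@pytest.fixture
def three_family_tree() -> ReferenceTree:
    """Three two-leaf families with no taxon shared above family rank."""
    nwk = "((F1a:1{0},F1b:1{1}):1{6},((F2a:1{2},F2b:1{3}):1{7},(F3a:1{4},F3b:1{5}):1{8}):1{9}):0{10};"
    lin = {}
    for fam, leaves in (("Fam1", "F1"), ("Fam2", "F2"), ("Fam3", "F3")):
        for suffix in "ab":
            lin[f"{leaves}{suffix}"] = [
                ("family", fam),
                ("genus", f"{fam}_gen"),
                ("species", f"{fam}_sp_{suffix}"),
            ]
    return make_reference_tree(nwk, lin)


def make_table(counts, samples, otus, marker="18S") -> OtuTable:
    return OtuTable(
        counts=pd.DataFrame(np.asarray(counts), index=samples, columns=otus),
        marker=marker,
    )


@pytest.fixture
def small_community():
    """Two localities x two samples, four OTUs."""
    table = make_table(
        [[5, 0, 1, 2], [3, 0, 2, 0], [0, 4, 1, 0], [0, 6, 1, 1]],
        samples=["L1_r1", "L1_r2", "L2_r1", "L2_r2"],
        otus=["o1", "o2", "o3", "o4"],
    )
    meta = SampleMetadata(
        localities={"L1_r1": "L1", "L1_r2": "L1", "L2_r1": "L2", "L2_r2": "L2"},
        replicates={"L1_r1": 1, "L1_r2": 2, "L2_r1": 1, "L2_r2": 2},
    )
    return table, meta
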