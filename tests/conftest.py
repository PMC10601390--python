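"""Shared fixtures and independent brute-force oracles.

The oracles walk dendropy node paths directly and never touch the package's
vectorized internals, so they are an independent route to the same
quantities.
"""

from __future__ import annotations

import numpy as np
import pytest

from ethnophylo.phylo_io import Phylogeny
from ethnophylo.synthetic_data import simulate_tree

FOUR_TIP = "((A:1,B:1):1,(C:1,D:1):1);"
PIPER = "((Piper_a:2,Piper_b:2):3,Ocotea_c:5);"


@pytest.fixture
def four_tip() -> Phylogeny:
    return Phylogeny.from_newick(FOUR_TIP)


@pytest.fixture
def piper_tree() -> Phylogeny:
    return Phylogeny.from_newick(PIPER)


@pytest.fixture(scope="session")
def tree300() -> Phylogeny:
    """A mid-sized Yule tree reused by the calibration tests."""
    return simulate_tree(300, seed=20260925)


def random_tree(n_tips: int, seed: int, random_lengths: bool = False) -> Phylogeny:
    """Random Yule tree; optionally with iid uniform (non-ultrametric) lengths."""
    phy = simulate_tree(n_tips, seed=seed)
    if random_lengths:
        rng = np.random.default_rng(seed + 1)
        tree = phy.tree
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = float(rng.uniform(0.05, 2.0))
        phy = Phylogeny(tree)
    return phy


# ---------------------------------------------------------------------------
# brute-force oracles (path walking on dendropy nodes)
# ---------------------------------------------------------------------------


def root_path(phy: Phylogeny, label: str):
    """List of nodes from a tip up to (and including) the root."""
    (leaf,) = [l for l in phy.tree.leaf_node_iter() if l.taxon.label == label]
    path = [leaf]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def patristic_oracle(phy: Phylogeny, a: str, b: str) -> float:
    pa = root_path(phy, a)
    pb = root_path(phy, b)
    ids_b = {id(n): i for i, n in enumerate(pb)}
    for i, n in enumerate(pa):
        if id(n) in ids_b:
            da = sum(x.edge.length for x in pa[:i])
            db = sum(x.edge.length for x in pb[: ids_b[id(n)]])
            return da + db
    raise AssertionError("no common ancestor found")


def mrca_oracle(phy: Phylogeny, labels):
    """Deepest node whose root-path is shared by all labels."""
    paths = [root_path(phy, lab) for lab in labels]
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= {id(n) for n in p}
    for n in paths[0]:  # tip-to-root order: first common hit is the MRCA
        if id(n) in common:
            return n
    raise AssertionError("no common ancestor")


def pd_oracle(phy: Phylogeny, taxa, include_root: bool = True) -> float:
    """Faith PD by explicit union of root-to-tip path edges."""
    taxa = list(taxa)
    union: dict[int, float] = {}
    per_path = []
    for lab in taxa:
        nodes = root_path(phy, lab)[:-1]  # exclude root: edge keyed by child
        per_path.append({id(n) for n in nodes})
        for n in nodes:
            union[id(n)] = n.edge.length
    keep = set(union)
    if not include_root:
        shared = set.intersection(*per_path) if per_path else set()
        keep -= shared
    return sum(union[i] for i in keep)


def branch_partition_oracle(phy: Phylogeny, setA, setB, include_root=True):
    """(a, b, c) by classifying every edge on subtended-tip intersections."""
    a = b = c = 0.0
    for nd in phy.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = {l.taxon.label for l in nd.leaf_iter()}
        inA = bool(below & set(setA))
        inB = bool(below & set(setB))
        if not include_root:
            inA = inA and not set(setA) <= below
            inB = inB and not set(setB) <= below
        if inA and inB:
            a += nd.edge.length
        elif inA:
            b += nd.edge.length
        elif inB:
            c += nd.edge.length
    return a, b, c


def clade_counts_oracle(phy: Phylogeny, trait: dict):
    """{frozenset(descendant tips): (size, positive count)} for every node."""
    out = {}
    for nd in phy.tree.postorder_node_iter():
        tips = frozenset(l.taxon.label for l in nd.leaf_iter())
        out[tips] = (len(tips), sum(trait[t] for t in tips))
    return out


def bipartitions_with_lengths(phy: Phylogeny):
    """{frozenset(tips below edge): edge length} — topology + length identity."""
    out = {}
    for nd in phy.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in nd.leaf_iter())
        out[tips] = out.get(tips, 0.0) + nd.edge.length
    return out
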