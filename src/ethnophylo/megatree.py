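"""Grafting missing species onto a dated megatree and pruning to a study set.

Follows the genus-crown placement rule of megatree assembly tools: a species
missing from the backbone is attached as a new child of the basal (crown)
node of its genus — the most recent common ancestor of all congeneric tips,
or the tip's parent when the genus is monotypic — with a pendant branch equal
to that node's age, which keeps an ultrametric backbone ultrametric.  When
the genus is absent entirely, the species drops to the crown node of its
family (membership supplied via a tip-to-family map).  Species with neither
genus nor family in the tree are reported as unplaced and excluded.

Grafts deliberately create polytomies rather than bisecting edges: the
crown-node rule gives every added congener the same attachment point, and no
stem ages need to be invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import Phylogeny, PhyloIOError, TaxonRecord

__all__ = [
    "GraftError",
    "GenusAbsentError",
    "GraftReport",
    "genus_basal_node",
    "graft_species",
    "prune_to",
]

log = logging.getLogger(__name__)


class GraftError(PhyloIOError):
    pass


class GenusAbsentError(GraftError):
    """Signal that a genus has no tip in the tree (caller falls back to family)."""


@dataclass
class GraftReport:
    """Audit trail of a grafting run."""

    n_requested: int
    n_already_present: int = 0
    n_grafted_to_genus: int = 0
    n_grafted_to_family: int = 0
    unplaced: list[str] = field(default_factory=list)
    placements: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        total = (
            self.n_already_present
            + self.n_grafted_to_genus
            + self.n_grafted_to_family
            + len(self.unplaced)
        )
        if total != self.n_requested:
            raise GraftError(
                f"graft accounting broken: {total} accounted for, "
                f"{self.n_requested} requested"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.placements)


def _genus_of(label: str) -> str:
    return label.split("_")[0]


def genus_basal_node(phy: Phylogeny, genus: str) -> dendropy.Node:
    """Crown node of a genus: MRCA of its tips (tip's parent if monotypic).

    Raises :class:`GenusAbsentError` when no tip belongs to the genus.
    """
    tree = phy.tree
    tips = [l for l in tree.leaf_node_iter() if _genus_of(l.taxon.label) == genus]
    if not tips:
        raise GenusAbsentError(f"genus {genus!r} has no tips in the tree")
    if len(tips) == 1:
        return tips[0].parent_node
    return tree.mrca(taxa=[l.taxon for l in tips])


def _family_basal_node(tree: dendropy.Tree, family: str, family_map) -> dendropy.Node:
    tips = [
        l
        for l in tree.leaf_node_iter()
        if family_map.get(l.taxon.label) == family
    ]
    if not tips:
        raise GenusAbsentError(f"family {family!r} has no mapped tips in the tree")
    if len(tips) == 1:
        return tips[0].parent_node
    return tree.mrca(taxa=[l.taxon for l in tips])


def _node_ages(phy: Phylogeny) -> dict[int, float]:
    """Age of every node (mean path length to descendant tips)."""
    ages: dict[int, float] = {}
    counts: dict[int, int] = {}
    for nd in phy.tree.postorder_node_iter():
        if nd.is_leaf():
            ages[id(nd)] = 0.0
            counts[id(nd)] = 1
        else:
            tot = 0.0
            cnt = 0
            for ch in nd.child_nodes():
                tot += (ages[id(ch)] + ch.edge.length) * counts[id(ch)]
                cnt += counts[id(ch)]
            ages[id(nd)] = tot / cnt
            counts[id(nd)] = cnt
    return ages


def graft_species(
    phy: Phylogeny,
    taxa: Sequence[TaxonRecord],
    family_map: Mapping[str, str] | None = None,
    tol: float = 1e-6,
) -> tuple[Phylogeny, GraftReport]:
    """Attach every placeable species in ``taxa`` to the megatree.

    The input tree must be ultrametric within ``tol`` (attachment ages are
    otherwise undefined).  Returns the enlarged tree and a
    :class:`GraftReport`; species with neither genus nor family present are
    listed as unplaced and left out of the tree.
    """
    if not phy.is_ultrametric(tol):
        raise GraftError(
            f"input tree is not ultrametric within tol={tol}; node ages undefined"
        )
    family_map = dict(family_map or {})
    work = phy.copy()
    tree = work.tree
    ages = _node_ages(work)
    report = GraftReport(n_requested=len(taxa))
    present = set(work.tip_labels)

    for rec in taxa:
        if rec.species in present:
            report.n_already_present += 1
            report.placements.append(
                {"species": rec.species, "how": "already_present",
                 "attachment": rec.species, "age": 0.0}
            )
            continue
        try:
            node = genus_basal_node(work, rec.genus)
            how = "genus"
        except GenusAbsentError:
            try:
                node = _family_basal_node(tree, rec.family, family_map)
                how = "family"
            except GenusAbsentError:
                report.unplaced.append(rec.species)
                report.placements.append(
                    {"species": rec.species, "how": "unplaced",
                     "attachment": "", "age": float("nan")}
                )
                continue
        age = ages.get(id(node))
        if age is None:
            # attachment at a node created by an earlier graft's parent lookup
            age = _node_ages(work)[id(node)]
        taxon = dendropy.Taxon(label=rec.species)
        tree.taxon_namespace.add_taxon(taxon)
        new_tip = node.new_child(taxon=taxon, edge_length=age)
        ages[id(new_tip)] = 0.0
        present.add(rec.species)
        if how == "genus":
            report.n_grafted_to_genus += 1
        else:
            report.n_grafted_to_family += 1
            family_map[rec.species] = rec.family
        attach_desc = f"{how}-crown age {age:.6g}"
        report.placements.append(
            {"species": rec.species, "how": how,
             "attachment": attach_desc, "age": float(age)}
        )
        log.info("grafted %s at %s node (age %.4g)", rec.species, how, age)

    report.validate()
    out = Phylogeny(tree)
    if not out.is_ultrametric(tol):
        raise GraftError("grafting broke ultrametricity beyond tolerance (bug)")
    return out, report


def prune_to(phy: Phylogeny, keep) -> Phylogeny:
    """Restrict the tree to ``keep``, suppressing unbranched internal nodes.

    Edge lengths of suppressed nodes are summed, so root-to-tip depths of the
    surviving tips are unchanged.
    """
    keep = set(keep)
    tips = set(phy.tip_labels)
    missing = sorted(keep - tips)
    if missing:
        raise GraftError(f"species not in tree, cannot prune to them: {missing[:10]}")
    if keep == tips:
        return phy.copy()
    pruned = phy.tree.extract_tree_with_taxa_labels(labels=keep)
    return Phylogeny(pruned)
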