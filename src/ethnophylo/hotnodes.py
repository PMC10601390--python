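"""Per-clade enrichment scan for a binary use trait ("hot nodes").

The number of trait-positive tips descending from every internal node is
compared against a null built by shuffling trait values across the tips of
the phylogeny; a clade is "hot" when its SES exceeds a one-sided threshold
(default 1.96).  Only clades of at least ``min_clade`` tips (default 10) are
evaluated — enrichment scores for very small lineages are statistically
unstable.  Each shuffle scores all nodes simultaneously, so nested clades
share the same null replicates.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._treemath import tree_arrays
from .phylo_io import Phylogeny
from .signal_d import _binary_trait

__all__ = [
    "HotNodeResult",
    "HotNodeError",
    "clade_counts",
    "hot_node_scan",
    "annotate_tree",
    "results_frame",
]

log = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^HOT_ses_(?P<ses>[-+0-9.eE]+)$")


class HotNodeError(ValueError):
    pass


def _tip_hash(tips) -> str:
    return hashlib.md5(",".join(sorted(tips)).encode("utf-8")).hexdigest()[:12]


@dataclass
class HotNodeResult:
    """Enrichment score for one evaluated clade."""

    node_id: int  # stable postorder index over all nodes
    tip_hash: str  # digest of the sorted descendant tip list
    clade_size: int
    focal_count: int
    null_mean: float
    null_sd: float
    ses: float
    is_hot: bool
    example_tips: tuple[str, ...] = ()


def clade_counts(phy: Phylogeny, trait) -> pd.DataFrame:
    """Descendant tip count and trait-positive count for every node.

    Indexed by postorder node id; tips included (clade_size 1).
    """
    arrays = tree_arrays(phy)
    x = _binary_trait(arrays, trait)
    focal = arrays.clade_f @ x
    return pd.DataFrame(
        {
            "clade_size": arrays.clade_sizes,
            "focal_count": focal.astype(int),
        },
        index=pd.RangeIndex(arrays.n_nodes, name="node_id"),
    )


def hot_node_scan(
    phy: Phylogeny,
    trait,
    min_clade: int = 10,
    n_perm: int = 999,
    ses_threshold: float = 1.96,
    seed=None,
    rng=None,
    maximal_only: bool = False,
) -> list[HotNodeResult]:
    """Scan all internal clades of at least ``min_clade`` tips for enrichment.

    Results are sorted by decreasing SES (undefined SES last).  With
    ``maximal_only`` only outermost hot clades are kept (hot nodes without a
    hot ancestor), plus all non-hot evaluated clades.
    """
    arrays = tree_arrays(phy)
    x = _binary_trait(arrays, trait)
    if rng is None:
        rng = np.random.default_rng(seed)
    if x.sum() in (0, arrays.n_tips):
        log.warning(
            "trait is constant: every clade's null has zero spread; "
            "all SES values undefined"
        )
    evaluated = np.flatnonzero((~arrays.is_tip) & (arrays.clade_sizes >= min_clade))
    obs = arrays.clade_f[evaluated] @ x
    null = arrays.clade_f[evaluated] @ arrays.shuffle_matrix(x, n_perm, rng)
    mean = null.mean(axis=1)
    sd = null.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(sd > 0, (obs - mean) / sd, np.nan)
    hot = np.where(np.isfinite(ses), ses > ses_threshold, False)

    results = []
    for j, i in enumerate(evaluated):
        tips = [arrays.tip_labels[t] for t in np.flatnonzero(arrays.clade[i])]
        results.append(
            HotNodeResult(
                node_id=int(i),
                tip_hash=_tip_hash(tips),
                clade_size=int(arrays.clade_sizes[i]),
                focal_count=int(obs[j]),
                null_mean=float(mean[j]),
                null_sd=float(sd[j]),
                ses=float(ses[j]),
                is_hot=bool(hot[j]),
                example_tips=tuple(sorted(tips)[:3]),
            )
        )
    if maximal_only:
        hot_ids = {r.node_id for r in results if r.is_hot}
        keep = []
        for r in results:
            if r.is_hot:
                p = arrays.parent[r.node_id]
                has_hot_ancestor = False
                while p >= 0:
                    if p in hot_ids:
                        has_hot_ancestor = True
                        break
                    p = arrays.parent[p]
                if has_hot_ancestor:
                    continue
            keep.append(r)
        results = keep
    results.sort(key=lambda r: (np.isnan(r.ses), -r.ses if np.isfinite(r.ses) else 0))
    return results


def annotate_tree(phy: Phylogeny, results: list[HotNodeResult]) -> Phylogeny:
    """Copy of the tree with hot nodes labeled ``HOT_ses_<value>``.

    Raises when a result's tip set no longer matches the node it names
    (stale results from a different tree).
    """
    out = phy.copy()
    arrays = tree_arrays(out)
    for r in results:
        if r.node_id >= arrays.n_nodes or arrays.is_tip[r.node_id]:
            raise HotNodeError(f"node_id {r.node_id} is not an internal node")
        tips = [arrays.tip_labels[t] for t in np.flatnonzero(arrays.clade[r.node_id])]
        if _tip_hash(tips) != r.tip_hash:
            raise HotNodeError(
                f"node {r.node_id}: descendant tips changed since the scan "
                "(stale results?)"
            )
        if r.is_hot:
            arrays.nodes[r.node_id].label = f"HOT_ses_{r.ses:.4f}"
    return out


def read_annotations(phy: Phylogeny) -> dict[int, float]:
    """Parse ``HOT_ses_`` labels back to {postorder node id: ses}."""
    arrays = tree_arrays(phy)
    out = {}
    for i, nd in enumerate(arrays.nodes):
        label = getattr(nd, "label", None)
        if label:
            m = _LABEL_RE.match(label)
            if m:
                out[i] = float(m.group("ses"))
    return out


def results_frame(results: list[HotNodeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "node_id": r.node_id,
                "clade_size": r.clade_size,
                "focal_count": r.focal_count,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "ses": r.ses,
                "is_hot": r.is_hot,
                "example_tips": ";".join(r.example_tips),
            }
        )
    return pd.DataFrame(rows)
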