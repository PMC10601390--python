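"""Cached numeric tree structures shared by the statistics modules.

A :class:`TreeArrays` flattens a :class:`~ethnophylo.phylo_io.Phylogeny` into
postorder-indexed numpy arrays once, so that permutation nulls over traits and
guild memberships reduce to dense matrix products:

* ``clade`` — node-by-tip incidence (tip j descends from node i), which doubles
  as the edge-by-tip incidence used for Faith PD and PhyloSor branch
  partitions (every non-root node owns the edge above it);
* a contrast operator for the sister-clade-difference kernel of the
  Fritz-Purvis D statistic (node values are linear in tip values, so the sum
  of absolute sister differences is ``sum(abs(C @ x))``);
* a Brownian path operator mapping i.i.d. standard-normal edge increments to
  tip values of a Brownian motion run along the tree.

Trait shuffles are drawn over the *sorted* tip-label order, so permutation
nulls are invariant to the order in which a Newick file happens to list tips.
"""

from __future__ import annotations

import zlib

import numpy as np

from .phylo_io import Phylogeny


def ses_score(obs: float, null: np.ndarray) -> float:
    """(obs - mean) / sd of a null sample; NaN when the null is degenerate.

    Degeneracy is judged on the null's relative spread, not sd == 0 exactly:
    identical replicates can differ by ~1e-16 through non-associative BLAS
    summation.
    """
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    spread = float(null.max() - null.min())
    if sd == 0 or spread <= 1e-9 * max(1.0, abs(mean)):
        return float("nan")
    return (obs - mean) / sd


def membership_rng(seed, *memberships) -> np.random.Generator:
    """Generator keyed on a seed plus one or more species sets.

    Guilds with identical membership get identical null draws under the same
    master seed, independent of the order in which guilds are processed (and,
    for pairs, of the order of the two sets).
    """
    keys = sorted(
        zlib.crc32(",".join(sorted(m)).encode("utf-8")) for m in memberships
    )
    if seed is None:
        seed = int(np.random.SeedSequence().entropy) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


def tree_arrays(phy: Phylogeny) -> "TreeArrays":
    """Return the cached TreeArrays for a Phylogeny, building it on first use."""
    cached = phy._cache.get("arrays")
    if cached is None:
        cached = TreeArrays(phy)
        phy._cache["arrays"] = cached
    return cached


class TreeArrays:
    def __init__(self, phy: Phylogeny):
        tree = phy.tree
        nodes = list(tree.postorder_node_iter())
        self.phy = phy
        self.nodes = nodes
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.node_index = index

        tip_labels: list[str] = []
        tip_col: dict[int, int] = {}
        for nd in nodes:
            if nd.is_leaf():
                tip_col[id(nd)] = len(tip_labels)
                tip_labels.append(nd.taxon.label)
        self.tip_labels = tuple(tip_labels)
        self.n_tips = len(tip_labels)
        self.tip_index = {lab: i for i, lab in enumerate(tip_labels)}

        n, m = self.n_tips, self.n_nodes
        self.parent = np.full(m, -1, dtype=np.int64)
        self.lengths = np.zeros(m, dtype=np.float64)
        self.is_tip = np.zeros(m, dtype=bool)
        self.children: list[list[int]] = [[] for _ in range(m)]
        self.clade = np.zeros((m, n), dtype=bool)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                self.is_tip[i] = True
                self.clade[i, tip_col[id(nd)]] = True
            else:
                for c in self.children[i]:
                    self.clade[i] |= self.clade[c]
        self.root = m - 1  # postorder: root is last
        self.clade_sizes = self.clade.sum(axis=1)
        self.clade_f = self.clade.astype(np.float64)

        # depth of each node measured from the root
        self.node_depth = np.zeros(m, dtype=np.float64)
        for i in range(m - 1, -1, -1):
            p = self.parent[i]
            if p >= 0:
                self.node_depth[i] = self.node_depth[p] + self.lengths[i]
        self.tip_depth = np.zeros(n, dtype=np.float64)
        for i in range(m):
            if self.is_tip[i]:
                self.tip_depth[self.clade[i].argmax()] = self.node_depth[i]

        # canonical (sorted-label) ordering used for permutation nulls
        self.sorted_tip_idx = np.array(
            sorted(range(n), key=lambda j: tip_labels[j]), dtype=np.int64
        )

        self._contrasts = None
        self._brownian_op = None
        self._patristic = None

    # -- trait helpers ------------------------------------------------------

    def trait_array(self, trait) -> np.ndarray:
        """Coerce a tip->value mapping (or aligned array) to tip order."""
        if isinstance(trait, np.ndarray):
            if trait.shape[0] != self.n_tips:
                raise ValueError(
                    f"trait vector length {trait.shape[0]} != {self.n_tips} tips"
                )
            return np.asarray(trait, dtype=np.float64)
        missing = [lab for lab in self.tip_labels if lab not in trait]
        if missing:
            raise KeyError(f"missing trait values for tips: {missing[:5]}")
        return np.array([float(trait[lab]) for lab in self.tip_labels])

    def shuffle_matrix(self, x: np.ndarray, n_perm: int, rng) -> np.ndarray:
        """(n_tips, n_perm) matrix of uniform shuffles of the values of x.

        Shuffles permute the multiset of trait values in sorted-tip-label
        order, making the null invariant to tip ordering in the input file.
        """
        vals = x[self.sorted_tip_idx]
        mat = np.tile(vals[:, None], (1, n_perm))
        mat = rng.permuted(mat, axis=0)
        out = np.empty_like(mat)
        out[self.sorted_tip_idx, :] = mat
        return out

    # -- Fritz-Purvis d kernel ----------------------------------------------

    @property
    def contrasts(self) -> np.ndarray:
        """Rows are (child minus parent) of the linear nodal-value operator.

        Internal node values are the inverse-branch-length weighted averages
        of their children's values (equal weights where a child edge has zero
        length); d(x) = sum of |child - parent| over all internal-node
        children = sum(abs(contrasts @ x)).
        """
        if self._contrasts is None:
            n, m = self.n_tips, self.n_nodes
            A = np.zeros((m, n))
            rows = []
            for i in range(m):
                if self.is_tip[i]:
                    A[i, self.clade[i].argmax()] = 1.0
                    continue
                kids = self.children[i]
                lens = self.lengths[kids]
                if np.any(lens == 0):
                    w = np.full(len(kids), 1.0 / len(kids))
                else:
                    w = (1.0 / lens) / (1.0 / lens).sum()
                for wk, c in zip(w, kids):
                    A[i] += wk * A[c]
                for c in kids:
                    rows.append(A[c] - A[i])
            self._contrasts = np.asarray(rows)
        return self._contrasts

    def d_batch(self, X: np.ndarray) -> np.ndarray:
        """Sum of sister-clade differences for each column of X (tips x B)."""
        return np.abs(self.contrasts @ X).sum(axis=0)

    # -- Brownian motion ----------------------------------------------------

    @property
    def brownian_op(self) -> np.ndarray:
        """(n_tips, n_nodes) operator: tip values = op @ standard normals."""
        if self._brownian_op is None:
            self._brownian_op = self.clade_f.T * np.sqrt(self.lengths)[None, :]
        return self._brownian_op

    def brownian_tips(self, n_sim: int, rng) -> np.ndarray:
        """(n_tips, n_sim) Brownian tip values (root value 0, var = depth)."""
        Z = rng.standard_normal((self.n_nodes, n_sim))
        return self.brownian_op @ Z

    # -- distances ----------------------------------------------------------

    @property
    def patristic(self) -> np.ndarray:
        """Dense tip-by-tip patristic distance matrix."""
        if self._patristic is None:
            n = self.n_tips
            D = np.zeros((n, n))
            for i in range(self.n_nodes):
                if self.is_tip[i]:
                    continue
                kids = self.children[i]
                depth2 = 2.0 * self.node_depth[i]
                for a in range(len(kids)):
                    ta = np.flatnonzero(self.clade[kids[a]])
                    for b in range(a + 1, len(kids)):
                        tb = np.flatnonzero(self.clade[kids[b]])
                        block = (
                            self.tip_depth[ta][:, None]
                            + self.tip_depth[tb][None, :]
                            - depth2
                        )
                        D[np.ix_(ta, tb)] = block
                        D[np.ix_(tb, ta)] = block.T
            self._patristic = D
        return self._patristic

    # -- Faith PD / branch sums ---------------------------------------------

    def member_matrix(self, taxa) -> np.ndarray:
        """0/1 column vector (n_tips, 1) for a species collection."""
        s = np.zeros((self.n_tips, 1))
        for t in taxa:
            if t not in self.tip_index:
                raise KeyError(f"species {t!r} is not a tip of the tree")
            s[self.tip_index[t], 0] = 1.0
        return s

    def pd_batch(self, S: np.ndarray, include_root: bool = True) -> np.ndarray:
        """Faith PD for each membership column of S (tips x B)."""
        counts = self.clade_f @ S
        present = counts > 0
        pd = self.lengths @ present
        if not include_root:
            k = S.sum(axis=0)
            above_mrca = counts == k[None, :]
            pd = pd - self.lengths @ above_mrca
        return pd

    def random_subsets(self, k: int, n_draws: int, rng) -> np.ndarray:
        """(n_tips, n_draws) matrix of uniform k-subsets of the tip pool."""
        u = rng.random((n_draws, self.n_tips))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        S = np.zeros((self.n_tips, n_draws))
        for b in range(n_draws):
            S[idx[b], b] = 1.0
        return S
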