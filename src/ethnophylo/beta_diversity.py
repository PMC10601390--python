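"""PhyloSor beta diversity between guilds, with turnover/nestedness split.

For two guilds A and B, branch length is partitioned into a (shared by both
guilds' root-path unions), b (unique to A) and c (unique to B).  Phylogenetic
beta diversity is PBD = 1 - PhyloSor = (b + c) / (2a + b + c), decomposed
additively (Baselga-style) into

    turnover   pbd_sim = min(b, c) / (a + min(b, c))       (Simpson-derived)
    nestedness pbd_sne = pbd_sor - pbd_sim

SES scores compare each component against a null that reshuffles which tips
carry each guild while holding both guild sizes and their overlap fixed, so
the score isolates *where* on the tree the guilds sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._treemath import membership_rng, ses_score, tree_arrays
from .phylo_io import Phylogeny, UseTraitTable

__all__ = [
    "BetaDivResult",
    "BetaDiversityError",
    "branch_partition",
    "phylosor_pair",
    "ses_phylo_beta",
    "guild_beta_matrix",
    "DEFAULT_PAIRS",
]

# the study's nine guild comparisons
DEFAULT_PAIRS = [
    ("edible", "condiment"),
    ("edible", "wrapping"),
    ("condiment", "wrapping"),
    ("edible", "cultivated"),
    ("edible", "wild"),
    ("condiment", "cultivated"),
    ("condiment", "wild"),
    ("wrapping", "cultivated"),
    ("wrapping", "wild"),
]

SES_FLAG_THRESHOLD = 1.96


class BetaDiversityError(ValueError):
    pass


@dataclass
class BetaDivResult:
    guild_a: str
    guild_b: str
    a: float
    b: float
    c: float
    pbd_sor: float
    pbd_sim: float
    pbd_sne: float
    ses_sor: float = float("nan")
    ses_sim: float = float("nan")
    ses_sne: float = float("nan")
    n_null: int = 0
    seed: int | None = None

    def flags(self, threshold: float = SES_FLAG_THRESHOLD) -> dict[str, bool]:
        """Two-sided |ses| > threshold flags per component (NaN never flags)."""
        out = {}
        for comp in ("sor", "sim", "sne"):
            s = getattr(self, f"ses_{comp}")
            out[comp] = bool(abs(s) > threshold) if np.isfinite(s) else False
        return out


def _member_cols(arrays, setA, setB, include_root):
    SA = arrays.member_matrix(setA)
    SB = arrays.member_matrix(setB)
    return _partition_batch(arrays, SA, SB, include_root)


def _partition_batch(arrays, SA, SB, include_root):
    """(a, b, c) branch-length partition per replicate column."""
    cA = arrays.clade_f @ SA
    cB = arrays.clade_f @ SB
    inA = cA > 0
    inB = cB > 0
    if not include_root:
        inA &= cA < SA.sum(axis=0)[None, :]
        inB &= cB < SB.sum(axis=0)[None, :]
    both = inA & inB
    a = arrays.lengths @ both
    b = arrays.lengths @ (inA & ~both)
    c = arrays.lengths @ (inB & ~both)
    return a, b, c


def branch_partition(phy: Phylogeny, setA, setB, include_root: bool = True):
    """Shared / A-only / B-only branch lengths of two guilds' path unions.

    Satisfies ``a + b + c == faith_pd(A | B)`` under the same include_root
    convention.
    """
    setA, setB = set(setA), set(setB)
    if not setA or not setB:
        raise BetaDiversityError("both species sets must be non-empty")
    arrays = tree_arrays(phy)
    a, b, c = _member_cols(arrays, setA, setB, include_root)
    return float(a[0]), float(b[0]), float(c[0])


def _components(a, b, c):
    bc_min = np.minimum(b, c)
    sor = (b + c) / (2 * a + b + c)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(a + bc_min > 0, bc_min / (a + bc_min), 0.0)
    sne = sor - sim
    return sor, sim, sne


def phylosor_pair(
    phy: Phylogeny,
    setA,
    setB,
    include_root: bool = True,
    guild_a: str = "A",
    guild_b: str = "B",
) -> BetaDivResult:
    """PBD components for one guild pair (no null, no ses)."""
    a, b, c = branch_partition(phy, setA, setB, include_root=include_root)
    sor, sim, sne = _components(np.array([a]), np.array([b]), np.array([c]))
    return BetaDivResult(
        guild_a=guild_a,
        guild_b=guild_b,
        a=a,
        b=b,
        c=c,
        pbd_sor=float(sor[0]),
        pbd_sim=float(sim[0]),
        pbd_sne=float(sne[0]),
    )


def ses_phylo_beta(
    phy: Phylogeny,
    setA,
    setB,
    n_null: int = 999,
    seed=None,
    rng=None,
    include_root: bool = True,
    guild_a: str = "A",
    guild_b: str = "B",
) -> BetaDivResult:
    """PBD components plus SES against a fixed-size, fixed-overlap tip shuffle.

    Each null replicate redraws both memberships uniformly from the tip pool
    holding |A|, |B| and |A & B| at their observed values.  ses is NaN when
    the null distribution has zero spread.
    """
    setA, setB = set(setA), set(setB)
    res = phylosor_pair(
        phy, setA, setB, include_root=include_root, guild_a=guild_a, guild_b=guild_b
    )
    arrays = tree_arrays(phy)
    n = arrays.n_tips
    ka, kb = len(setA), len(setB)
    shared = len(setA & setB)
    if rng is None:
        rng = membership_rng(seed, setA, setB) if seed is not None else np.random.default_rng()

    # ranked-uniform permutation per replicate: first `shared` tips go to both
    # guilds, the next ka-shared to A only, the next kb-shared to B only
    order = np.argsort(rng.random((n_null, n)), axis=1)
    SA = np.zeros((n, n_null))
    SB = np.zeros((n, n_null))
    cols = np.arange(n_null)
    for j in range(shared):
        SA[order[:, j], cols] = 1.0
        SB[order[:, j], cols] = 1.0
    for j in range(shared, ka):
        SA[order[:, j], cols] = 1.0
    for j in range(ka, ka + kb - shared):
        SB[order[:, j], cols] = 1.0

    a, b, c = _partition_batch(arrays, SA, SB, include_root)
    sor, sim, sne = _components(a, b, c)
    for comp, null in (("sor", sor), ("sim", sim), ("sne", sne)):
        obs = getattr(res, f"pbd_{comp}")
        setattr(res, f"ses_{comp}", ses_score(obs, null))
    res.n_null = n_null
    res.seed = seed
    return res


def guild_beta_matrix(
    phy: Phylogeny,
    traits: UseTraitTable,
    pairs=None,
    n_null: int = 999,
    seed=None,
    include_root: bool = True,
) -> list[BetaDivResult]:
    """ses_phylo_beta over a list of guild-name pairs (default: the nine
    use-versus-management comparisons)."""
    if pairs is None:
        pairs = DEFAULT_PAIRS
    arrays = tree_arrays(phy)
    tips = set(arrays.tip_labels)
    out = []
    for ga, gb in pairs:
        A = traits.guild(ga) & tips
        B = traits.guild(gb) & tips
        if not A or not B:
            raise BetaDiversityError(f"guild pair ({ga}, {gb}) has an empty side")
        out.append(
            ses_phylo_beta(
                phy, A, B, n_null=n_null, seed=seed,
                include_root=include_root, guild_a=ga, guild_b=gb,
            )
        )
    return out


def beta_frame(results: list[BetaDivResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        flags = r.flags()
        rows.append(
            {
                "guild1": r.guild_a,
                "guild2": r.guild_b,
                "pbd_sne": r.pbd_sne,
                "pbd_sim": r.pbd_sim,
                "pbd_sor": r.pbd_sor,
                "ses_sne": r.ses_sne,
                "ses_sim": r.ses_sim,
                "ses_sor": r.ses_sor,
                "flag_sne": flags["sne"],
                "flag_sim": flags["sim"],
                "flag_sor": flags["sor"],
            }
        )
    return pd.DataFrame(rows)
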