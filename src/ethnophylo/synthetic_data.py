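"""Synthetic trees, taxonomies and use-trait tables with known ground truth.

The generator emulates the shape of an ethnobotanical species database laid
over a dated phylogeny: an ultrametric pure-birth (Yule) tree, a
clade-respecting genus/family taxonomy, and binary use guilds whose
phylogenetic structure is controlled per guild:

* ``random`` — members drawn uniformly (no signal; D ~ 1);
* ``brownian`` — members are the top-k tips of a Brownian motion run along
  the tree (strong signal; D ~ 0);
* ``clade-planted`` — members fill whole clades (detectable hot nodes,
  strong clustering).

``make_study_like_dataset`` reproduces the guild sizes of the Gulf of Mexico
comestible-plant study system (473 species; 437 edible, 51 condiment, 26
wrapping, 55 cultivated, 416 wild) with condiment and wrapping planted in
disjoint clades.

One master seed determines the whole dataset: each component draws from its
own child stream of a :class:`numpy.random.SeedSequence`, so adding a stage
never shifts the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._treemath import tree_arrays
from .phylo_io import (
    ORGAN_FLAGS,
    Phylogeny,
    TaxonRecord,
    UseTraitTable,
)

__all__ = [
    "GuildSpec",
    "SyntheticDataset",
    "SyntheticDataError",
    "simulate_tree",
    "assign_taxonomy",
    "simulate_use_traits",
    "make_study_like_dataset",
    "STUDY_GUILD_SIZES",
]

# species richness per guild in the study system
STUDY_GUILD_SIZES = {
    "edible": 437,
    "condiment": 51,
    "wrapping": 26,
    "cultivated": 55,
    "wild": 416,
}
STUDY_N_SPECIES = 473

# plausible prevalences for the nine organ flags (fruits dominate, bark and
# wood are rare), drawn independently per species
ORGAN_PREVALENCE = {
    "root_rhizome_bulb": 0.07,
    "stem": 0.08,
    "bark": 0.01,
    "wood": 0.01,
    "leaf": 0.25,
    "flowers": 0.12,
    "fruits": 0.45,
    "seeds": 0.12,
    "resin_latex": 0.03,
}


class SyntheticDataError(ValueError):
    pass


@dataclass
class GuildSpec:
    """Recipe for one binary guild."""

    size: int
    clustering: str = "random"  # random | brownian | clade-planted
    parent: str | None = None  # draw members only from this guild
    exclude: str | None = None  # never touch members of this guild


@dataclass
class SyntheticDataset:
    phylogeny: Phylogeny
    taxonomy: list[TaxonRecord]
    traits: UseTraitTable
    params: dict = field(default_factory=dict)


def simulate_tree(n_tips: int, seed=None, rng=None) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree scaled to unit depth.

    Tip labels are binomial-shaped placeholders ``G<i>_s<i>`` (rewritten by
    :func:`assign_taxonomy`).
    """
    if n_tips < 2:
        raise SyntheticDataError("a tree needs at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(seed)

    # children[i] = (left, right) node ids or None for live lineages
    birth = [0.0, 0.0]  # birth time of each node's subtending edge start
    children: list[tuple[int, int] | None] = [None, None]
    live = [0, 1]
    t = 0.0
    while len(live) < n_tips:
        t += rng.exponential(1.0 / len(live))
        j = int(rng.integers(len(live)))
        node = live[j]
        a, b = len(birth), len(birth) + 1
        birth += [t, t]
        children += [None, None]
        children[node] = (a, b)
        live[j] = a
        live.append(b)
    t_end = t + rng.exponential(1.0 / n_tips)

    tip_counter = [0]

    def newick(node: int, parent_birth: float) -> str:
        if children[node] is None:
            tip_counter[0] += 1
            i = tip_counter[0]
            length = (t_end - parent_birth) / t_end
            return f"G{i}_s{i}:{length:.12f}"
        a, b = children[node]
        split_t = birth[a]
        length = (split_t - parent_birth) / t_end
        return f"({newick(a, split_t)},{newick(b, split_t)}):{length:.12f}"

    # the root is the common origin of lineages 0 and 1 at time 0
    s = f"({newick(0, 0.0)},{newick(1, 0.0)});"
    return Phylogeny.from_newick(s)


def _split_to_clades(arrays, n_blocks: int) -> list[int]:
    """Partition tips into n_blocks monophyletic blocks (node ids)."""
    if n_blocks > arrays.n_tips:
        raise SyntheticDataError(
            f"cannot cut {arrays.n_tips} tips into {n_blocks} clades"
        )
    blocks = [arrays.root]
    while len(blocks) < n_blocks:
        splittable = [b for b in blocks if len(arrays.children[b]) >= 2]
        if not splittable:
            raise SyntheticDataError("no clade left to split (degenerate tree)")
        big = max(splittable, key=lambda b: (arrays.clade_sizes[b], b))
        blocks.remove(big)
        blocks.extend(arrays.children[big])
        if len(blocks) > n_blocks:
            raise SyntheticDataError(
                "polytomy made an exact clade cut infeasible at "
                f"{len(blocks)} > {n_blocks} blocks"
            )
    return blocks


def assign_taxonomy(
    phy: Phylogeny, n_genera: int, n_families: int, seed=None
) -> tuple[Phylogeny, list[TaxonRecord]]:
    """Carve monophyletic genera nested in monophyletic families.

    Families are clade cuts of the tree; genera refine them, so every genus
    and family crown node is well defined.  Tips are relabeled
    ``Genus<g>_sp<k>``; returns the relabeled tree and its taxonomy.
    """
    if not (n_families <= n_genera <= phy.n_tips):
        raise SyntheticDataError(
            "need n_families <= n_genera <= n_tips; got "
            f"{n_families}, {n_genera}, {phy.n_tips}"
        )
    arrays = tree_arrays(phy)
    fam_blocks = _split_to_clades(arrays, n_families)
    # refine each family block into genus blocks, largest families first
    genus_blocks: list[tuple[int, int]] = []  # (family_idx, node_id)
    blocks = [(f, b) for f, b in enumerate(fam_blocks)]
    while len(blocks) < n_genera:
        splittable = [
            (f, b) for f, b in blocks if len(arrays.children[b]) >= 2
        ]
        if not splittable:
            raise SyntheticDataError("no genus clade left to split")
        f, big = max(splittable, key=lambda fb: (arrays.clade_sizes[fb[1]], fb[1]))
        blocks.remove((f, big))
        blocks.extend((f, c) for c in arrays.children[big])
    genus_blocks = blocks

    # stable naming: order blocks by their smallest tip index
    def first_tip(b):
        return int(np.flatnonzero(arrays.clade[b])[0])

    genus_blocks.sort(key=lambda fb: first_tip(fb[1]))
    fam_order = sorted(range(len(fam_blocks)), key=lambda f: first_tip(fam_blocks[f]))
    fam_name = {f: f"Family{i + 1}" for i, f in enumerate(fam_order)}

    relabel: dict[str, tuple[str, str]] = {}  # old label -> (new label, family)
    for g, (f, b) in enumerate(genus_blocks, start=1):
        tips = np.flatnonzero(arrays.clade[b])
        for k, tcol in enumerate(sorted(tips), start=1):
            old = arrays.tip_labels[tcol]
            relabel[old] = (f"Genus{g}_sp{k}", fam_name[f])

    out = phy.copy()
    taxonomy = []
    for leaf in out.tree.leaf_node_iter():
        new, family = relabel[leaf.taxon.label]
        leaf.taxon.label = new
        taxonomy.append(
            TaxonRecord(species=new, genus=new.split("_")[0], family=family)
        )
    relabeled = Phylogeny(out.tree)
    taxonomy.sort(key=lambda t: t.species)
    return relabeled, taxonomy


def _plant_clades(arrays, pool: np.ndarray, size: int, rng) -> np.ndarray:
    """Fill ~``size`` pool tips with whole disjoint clades, trimming overflow.

    Greedy: repeatedly take the largest clade that fits in the remainder;
    when none fits, take the smallest clade that covers it and trim the
    overflow at random.  Returns tip indices.
    """
    chosen: list[int] = []
    taken = np.zeros(arrays.n_tips, dtype=bool)
    remaining = size
    while remaining > 0:
        eff_sizes = (arrays.clade[:, pool].sum(axis=1) if pool is not None
                     else arrays.clade_sizes)
        usable = ~(arrays.clade[:, taken].any(axis=1) if taken.any()
                   else np.zeros(arrays.n_nodes, dtype=bool))
        cand = np.flatnonzero(usable & (eff_sizes > 0))
        fits = cand[eff_sizes[cand] <= remaining]
        if fits.size:
            node = fits[np.argmax(eff_sizes[fits])]
            tips = np.flatnonzero(arrays.clade[node] & _mask(arrays, pool))
            chosen.extend(tips.tolist())
            taken[tips] = True
            remaining -= tips.size
        else:
            node = cand[np.argmin(eff_sizes[cand])]
            tips = np.flatnonzero(arrays.clade[node] & _mask(arrays, pool))
            pick = rng.choice(tips, size=remaining, replace=False)
            chosen.extend(pick.tolist())
            remaining = 0
    return np.array(sorted(chosen), dtype=np.int64)


def _mask(arrays, pool: np.ndarray | None) -> np.ndarray:
    if pool is None:
        return np.ones(arrays.n_tips, dtype=bool)
    m = np.zeros(arrays.n_tips, dtype=bool)
    m[pool] = True
    return m


def _draw_guild(arrays, spec: GuildSpec, pools: dict, rng) -> np.ndarray:
    pool = None
    if spec.parent is not None:
        if spec.parent not in pools:
            raise SyntheticDataError(
                f"nesting parent {spec.parent!r} must be generated first"
            )
        pool = pools[spec.parent]
    if spec.exclude is not None and spec.exclude in pools:
        excl = set(pools[spec.exclude].tolist())
        base = pool if pool is not None else np.arange(arrays.n_tips)
        pool = np.array([i for i in base if i not in excl], dtype=np.int64)
    pool_size = arrays.n_tips if pool is None else len(pool)
    if spec.size > pool_size:
        raise SyntheticDataError(
            f"guild size {spec.size} exceeds its pool of {pool_size}"
        )
    if spec.clustering == "random":
        base = np.arange(arrays.n_tips) if pool is None else pool
        return np.sort(rng.choice(base, size=spec.size, replace=False))
    if spec.clustering == "brownian":
        cont = arrays.brownian_tips(1, rng)[:, 0]
        base = np.arange(arrays.n_tips) if pool is None else pool
        order = base[np.argsort(-cont[base])]
        return np.sort(order[: spec.size])
    if spec.clustering == "clade-planted":
        return _plant_clades(arrays, pool, spec.size, rng)
    raise SyntheticDataError(f"unknown clustering mode {spec.clustering!r}")


def simulate_use_traits(
    phy: Phylogeny,
    guild_spec: Mapping[str, GuildSpec],
    seed=None,
) -> UseTraitTable:
    """Generate a binary trait table realizing each guild's recipe exactly.

    Guilds are generated in the given order (nesting parents first); each
    guild draws from its own child seed stream.  The resulting table must
    satisfy the trait-table invariants — in particular every species must end
    up with at least one of the use flags, which is the caller's
    responsibility when sizing guilds.
    """
    arrays = tree_arrays(phy)
    streams = np.random.SeedSequence(seed).spawn(len(guild_spec))
    pools: dict[str, np.ndarray] = {}
    frame = pd.DataFrame(0, index=pd.Index(arrays.tip_labels, name="species"),
                         columns=[], dtype=np.int8)
    for (name, spec), ss in zip(guild_spec.items(), streams):
        idx = _draw_guild(arrays, spec, pools, np.random.default_rng(ss))
        pools[name] = idx
        col = np.zeros(arrays.n_tips, dtype=np.int8)
        col[idx] = 1
        frame[name] = col
    return UseTraitTable(frame)


def make_study_like_dataset(
    seed=None,
    n_tips: int = STUDY_N_SPECIES,
    n_genera: int = 150,
    n_families: int = 50,
) -> SyntheticDataset:
    """A full synthetic analogue of the study's species database.

    Guild structure: condiment (51) and wrapping (26) are planted in disjoint
    clades (wrapping avoids condiment's lineages, echoing their high
    turnover); edible (437) covers every species outside those two guilds and
    tops up with the highest-ranking tips of a Brownian trait among them;
    wild (416) is drawn uniformly and cultivated (55) fills all but two of
    its complement (the two flags are independent bits, but at these sizes at
    most 471 of the 473 species can carry a management flag).  Organ flags
    are independent draws at realistic prevalences.
    """
    if n_tips == STUDY_N_SPECIES:
        sizes = dict(STUDY_GUILD_SIZES)
    else:
        # proportional scaling for reduced-size fixtures
        scale = n_tips / STUDY_N_SPECIES
        sizes = {
            g: max(2, round(s * scale)) for g, s in STUDY_GUILD_SIZES.items()
        }
        sizes["wild"] = min(sizes["wild"], n_tips - 3)
        sizes["cultivated"] = n_tips - sizes["wild"] - 2
        sizes["edible"] = max(
            sizes["edible"], n_tips - sizes["condiment"] - sizes["wrapping"]
        )

    root_ss = np.random.SeedSequence(seed)
    ss_tree, ss_tax, ss_use, ss_mgmt, ss_organ = root_ss.spawn(5)

    tree = simulate_tree(n_tips, rng=np.random.default_rng(ss_tree))
    tree, taxonomy = assign_taxonomy(tree, n_genera, n_families)
    arrays = tree_arrays(tree)

    use_rngs = [np.random.default_rng(s) for s in ss_use.spawn(3)]
    condiment = _plant_clades(arrays, None, sizes["condiment"], use_rngs[0])
    pool_wrap = np.array(
        [i for i in range(n_tips) if i not in set(condiment.tolist())],
        dtype=np.int64,
    )
    wrapping = _plant_clades(arrays, pool_wrap, sizes["wrapping"], use_rngs[1])

    flagged = np.zeros(n_tips, dtype=bool)
    flagged[condiment] = True
    flagged[wrapping] = True
    forced = np.flatnonzero(~flagged)  # must be edible to cover every species
    topup_n = sizes["edible"] - forced.size
    if topup_n < 0:
        raise SyntheticDataError("edible guild too small to cover non-use species")
    cont = arrays.brownian_tips(1, use_rngs[2])[:, 0]
    candidates = np.flatnonzero(flagged)
    topup = candidates[np.argsort(-cont[candidates])][:topup_n]
    edible = np.sort(np.concatenate([forced, topup]))

    mgmt_rng = np.random.default_rng(ss_mgmt)
    wild = np.sort(
        mgmt_rng.choice(n_tips, size=sizes["wild"], replace=False)
    )
    not_wild = np.array(sorted(set(range(n_tips)) - set(wild.tolist())))
    drop = mgmt_rng.choice(
        not_wild, size=not_wild.size - sizes["cultivated"], replace=False
    )
    cultivated = np.sort(np.array(sorted(set(not_wild.tolist()) - set(drop.tolist()))))

    organ_rng = np.random.default_rng(ss_organ)
    frame = pd.DataFrame(
        0, index=pd.Index(arrays.tip_labels, name="species"),
        columns=[], dtype=np.int8,
    )
    for name, idx in (
        ("wild", wild),
        ("cultivated", cultivated),
        ("edible", edible),
        ("condiment", condiment),
        ("wrapping", wrapping),
    ):
        col = np.zeros(n_tips, dtype=np.int8)
        col[idx] = 1
        frame[name] = col
    for organ in ORGAN_FLAGS:
        frame[organ] = (
            organ_rng.random(n_tips) < ORGAN_PREVALENCE[organ]
        ).astype(np.int8)

    traits = UseTraitTable(frame)
    params = {
        "seed": seed,
        "n_tips": n_tips,
        "n_genera": n_genera,
        "n_families": n_families,
        "guild_sizes": dict(sizes),
        "guild_structure": {
            "condiment": "clade-planted",
            "wrapping": "clade-planted (disjoint from condiment)",
            "edible": "coverage-forced + brownian top-up",
            "wild": "random",
            "cultivated": "complement of wild minus 2",
        },
        "organ_prevalence": dict(ORGAN_PREVALENCE),
    }
    return SyntheticDataset(
        phylogeny=tree, taxonomy=taxonomy, traits=traits, params=params
    )
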