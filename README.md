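# ethnophylo

Phylogenetic-pattern analysis of ethnobotanical **use guilds** — the sets of
species a regional flora contributes to a particular human use (eaten raw or
cooked, used as condiment, used for wrapping food; gathered wild or
cultivated).  Given a dated phylogeny and a species-by-flag trait table, the
package answers the questions community phylogenetics asks of such data:

* **Is a use phylogenetically conserved?** Fritz–Purvis *D* for binary
  traits: the observed sum of sister-clade differences *d* is rescaled
  against two permutation nulls,

  *D* = (*d*<sub>obs</sub> − mean *d*<sub>Brownian</sub>) /
  (mean *d*<sub>random</sub> − mean *d*<sub>Brownian</sub>),

  so *D* ≈ 1 for a trait shuffled randomly across tips (no signal) and
  *D* ≈ 0 for a trait thresholded from Brownian motion (strong signal).
* **Is a guild clustered on the tree?** Faith's PD, MPD and MNTD with
  standardized effect sizes, ses = (obs − mean null)/sd null, against a
  uniform tip-pool null; p < 0.05 flags clustering, p > 0.95 overdispersion.
* **Do two guilds occupy the same lineages?** Phylogenetic beta diversity
  PBD = 1 − PhyloSor = (b + c)/(2a + b + c) over shared (a) and unique (b, c)
  branch lengths, decomposed additively into true turnover
  pβ<sub>sim</sub> = min(b,c)/(a + min(b,c)) and nestedness
  pβ<sub>sne</sub> = pβ<sub>sor</sub> − pβ<sub>sim</sub>, with SES scores
  from a fixed-size, fixed-overlap tip shuffle.
* **Which clades are enriched?** "Hot node" scans: each clade's count of
  trait-positive descendants versus a 999-fold tip-shuffle null; clades of
  ≥ 10 tips with ses > 1.96 are flagged.
* **How do study species get onto a megatree?** Missing species are grafted
  at the crown node of their genus (or family), preserving ultrametricity,
  then the tree is pruned to the study set.

A synthetic-data generator (`ethnophylo.synthetic_data`) produces ultrametric
pure-birth trees, clade-respecting genus/family taxonomies and guild tables
with *known* phylogenetic structure (random / Brownian-threshold /
clade-planted guilds), so every stage is testable without any external
dataset.  Its study-like preset emulates a 473-species comestible flora of
the Gulf of Mexico province (437 edible, 51 condiment, 26 wrapping, 55
cultivated, 416 wild).

## Worked example

```python
from ethnophylo import (make_study_like_dataset, phylo_d, guild_summary,
                        ses_phylo_beta, hot_node_scan)
from ethnophylo.alpha_diversity import summary_frame

ds = make_study_like_dataset(seed=7)           # 473-tip tree + trait table
tree, traits = ds.phylogeny, ds.traits

trait = {s: int(s in traits.guild("condiment")) for s in tree.tip_labels}
r = phylo_d(tree, trait, n_perm=1000, seed=1)
print(f"condiment: D = {r.D:.3f}, p_rand = {r.p_rand:.4f}")

rows = guild_summary(tree, traits, ["edible", "condiment", "wrapping"],
                     n_null=999, seed=2)
print(summary_frame(rows).round(3).to_string(index=False))
```

prints

```
condiment: D = -0.660, p_rand = 0.0010
    guild  SR     PD   MPD  MNTD  ses.PD  p.PD  ses.MPD  p.MPD  ses.MNTD  p.MNTD
   edible 437 68.377 1.565 0.152  -1.336 0.099   -3.679  0.001    -1.105   0.139
condiment  51  6.907 0.820 0.123 -17.489 0.001  -18.438  0.001    -9.206   0.001
 wrapping  26  4.635 0.609 0.207 -13.327 0.001  -15.327  0.001    -6.518   0.001
```

The condiment guild is clade-planted by construction, so its *D* falls at or
below the Brownian anchor (*D* ≤ 0, shuffles almost never reach a *d* this
low: p_rand = 0.001) and all three of its alpha metrics are far below the
tip-pool null (large negative ses, p = 0.001 — strong clustering).  Beta
diversity and the hot-node scan recover the planted geometry the same way:

```python
b = ses_phylo_beta(tree, traits.guild("condiment"), traits.guild("wrapping"),
                   n_null=999, seed=3)
# condiment vs wrapping: pbd_sor=0.918 (turnover 0.898 + nestedness 0.020),
# ses_sim=8.77  -> the two guilds sit in different lineages

hot = hot_node_scan(tree, trait, min_clade=10, n_perm=999, seed=4)
# 96 clades evaluated, 16 hot; top clade: 45 tips, 45 condiment, ses=19.47
```

The same analyses are available from the shell:

```sh
ethnophylo simulate --preset study-like --seed 7 --out-dir data/
ethnophylo dstat --tree data/tree.nwk --traits data/traits.csv \
    --columns edible,condiment,wrapping --n-perm 1000 --seed 1 --out signal.csv
ethnophylo alpha --tree data/tree.nwk --traits data/traits.csv --seed 2 --out alpha.csv
ethnophylo run --config run.yaml      # full pipeline with a manifest
```

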