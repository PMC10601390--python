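# Methods

This note documents the models, nulls, numerical choices and limitations of
the package, in the spirit of the methods documentation of picante or
betapart, whose analyses it re-implements in Python.

## Data model

A **Phylogeny** is a rooted tree with non-negative branch lengths (time
units, e.g. Myr for a dated megatree) and unique tip labels in underscore
binomial form (`Piper_auritum`).  Polytomies are legal everywhere: megatree
grafting creates them by design, so every statistic handles them natively.
Ultrametricity is checked as (max root-to-tip depth − min depth) ≤ tol × max
depth; the default tolerance 1e-6 is far below the rounding of published
megatree branch lengths.

A **UseTraitTable** holds strictly-binary flags per species: management
(wild, cultivated — independent bits, a species may be both), use type
(edible, condiment, wrapping — every species must carry at least one) and
nine organ flags.  Guilds are the species sets defined by these columns.

All statistics run on a postorder array flattening of the tree
(`_treemath.TreeArrays`).  The node-by-tip incidence matrix turns Faith PD,
PhyloSor branch partitions and clade counts into dense matrix products, so a
999-replicate null for a 473-tip tree is a single BLAS call rather than 999
tree traversals.  This is why 1000-permutation D estimates take ~50 ms.

## Megatree grafting

A species absent from the backbone attaches as a new child of the **crown
node of its genus** — the MRCA of all congeneric tips, or the tip's parent
when the genus is monotypic — with pendant length equal to that node's age,
keeping the tree ultrametric without inventing stem ages.  When the genus is
absent, the species drops to the crown node of its family (families of
backbone tips must be supplied as a tip-to-family map, since megatree labels
carry genus but not family).  Species with neither genus nor family present
are reported as unplaced and dropped rather than failing the run.  Node ages
are the mean path length to descendant tips, which is robust to tolerance-
level depth jitter.  Genus membership of tips is lexical (first epithet of
the label).

## Fritz–Purvis D

The d kernel assigns each internal node the inverse-branch-length weighted
average of its children's values, tips to root, and sums the absolute
child-minus-node differences over all internal nodes.  For a bifurcation
this reduces to |left − right|; for a polytomy it is the natural spread
generalization, so no random resolution of polytomies is needed.  Children
on zero-length edges get equal weights.  Because node values are linear in
tip values, d(x) = Σ|C·x| for a precomputed contrast matrix C, and a
permutation null is one matrix product.

D rescales d<sub>obs</sub> between two nulls at the observed prevalence k:

* **random**: k positives shuffled uniformly across tips;
* **Brownian threshold**: a continuous trait evolves by Brownian motion from
  the root (Gaussian increments, variance ∝ branch length) and the k tips
  with the largest values become 1, so realized prevalence is exact.

Any consistent d kernel is re-anchored by these two nulls, so the D scale
(0 = Brownian expectation, 1 = random) is preserved even though the nodal
weighting is not bit-identical to other implementations — cross-validation
against them is approximate by design.  D < 0 (clumping beyond Brownian) and
D > 1 (overdispersion) are legal and not clipped.  P values use the add-one
Monte-Carlo estimator, (1 + #{d<sub>null</sub> ≤ d<sub>obs</sub>})/(n+1) for
the random null (one-tailed toward clumping) and the ≥ tail for the Brownian
null; both are reported.  Default n_perm = 1000 for both nulls.  D is
invariant to affine rescaling of all branch lengths (weights are normalized
per node and Brownian ranks are scale-free), which the suite tests.

## Alpha diversity (PD, MPD, MNTD) and SES

Faith PD is the branch length of the union of root-to-tip paths of the guild
(`include_root=True` by default, matching the conventional rooted-tree
definition; the flag exposes the no-root variant for sensitivity checks).
MPD is the mean patristic distance over unordered pairs; MNTD the mean
distance to the nearest other member.  Patristic distances are assembled
once per tree into a dense matrix and reused across guilds and nulls
(O(n²) memory, ~1.8 MB at n = 473).

The null draws |guild| species uniformly without replacement from the full
tip pool ("taxa labels" null); alternative nulls are out of scope.
ses = (obs − mean null)/sd null (sample sd); p is the add-one low-tail rank,
so p < 0.05 flags clustering and p > 0.95 overdispersion.  A null judged
degenerate on its relative spread (≤ 1e-9, e.g. the guild is the whole pool)
reports ses = NaN with p still a valid rank — sd is not compared with zero
exactly because identical replicates can differ by ~1e-16 through
non-associative BLAS summation.  Per-guild null streams are keyed on
(seed, sorted membership), so identical guilds give identical rows whatever
their order in the request.

## Beta diversity (PhyloSor / turnover / nestedness)

For guilds A and B, every edge is classified by whether its subtended tips
intersect A and/or B (root paths included, consistent with faith_pd), giving
shared (a) and unique (b, c) branch lengths with a + b + c = PD(A ∪ B).
PBD = 1 − PhyloSor = (b + c)/(2a + b + c); turnover is the Simpson-derived
min(b,c)/(a + min(b,c)); nestedness the Sorensen remainder.  Additivity
holds to 1e-12 and all components are symmetric in the two guilds.

The SES null redraws both memberships uniformly while holding |A|, |B| and
|A ∩ B| fixed.  Holding the overlap preserves the nestedness/turnover
geometry of the comparison, so the score isolates *where* the guilds sit on
the tree rather than how much they overlap as sets.  Flags are two-sided,
|ses| > 1.96.

## Hot nodes

Counts of trait-positive descendants are compared per clade against a
tip-shuffle null (default 999 permutations); one shuffle scores all clades
simultaneously, so nested clades share replicates.  Only clades of
≥ min_clade = 10 tips are evaluated (smaller lineages give unstable
enrichment scores) and they are absent from the output, not merely
unflagged.  Flagging is one-sided (ses > 1.96): the scan looks for hot, not
cold, clades.  Nested hot clades are all reported; `maximal_only` collapses
to the outermost ones.  Under the shuffle null each clade's count is exactly
hypergeometric, which the test suite uses as an analytic oracle for the
permutation moments.  Shuffles are drawn over the sorted-tip-label order, so
results are invariant to the order a Newick file lists tips.  Annotated
output trees label hot nodes `HOT_ses_<value>` (Newick-safe characters
only).

## Synthetic data

Trees are pure-birth (Yule) with unit birth rate, grown to the requested tip
count, plus one final unobserved waiting time, then scaled to unit depth —
ultrametric by construction, with realistic shape variation and no
extinction pruning to manage.  Taxonomies are clade cuts: families are
monophyletic tip blocks, genera refine them, so genus and family crown nodes
are always well defined for grafting tests.

Guild recipes: `random` draws uniformly; `brownian` takes the top-k tips of
one Brownian realization (the D ≈ 0 anchor); `clade-planted` greedily fills
disjoint clades — repeatedly the largest clade that fits the remaining
quota, then the smallest clade covering the remainder with overflow trimmed
at random — giving interpretable planted signal for power tests.  Nested
guilds draw only from their parent's members.

The study-like preset uses the guild sizes of the Gulf of Mexico
comestible-flora system: 473 species, 437 edible, 51 condiment, 26 wrapping,
55 cultivated, 416 wild, over 150 genera in 50 families.  Exact sizes plus
the requirement that every species carry a use flag make full nesting of
condiment and wrapping inside edible arithmetically impossible (437 < 473),
so the preset plants condiment and wrapping in disjoint clades, forces the
remaining 396 species to be edible, and tops edible up to 437 with the
Brownian-ranked best 41 of the other 77.  Similarly 416 wild + 55 cultivated
can cover at most 471 species without overlap, so two species carry no
management flag (the bits remain overlap-capable).  Organ flags are
independent draws at fixed realistic prevalences (fruits 0.45 down to bark
and wood at 0.01) with no correlation structure.  One master seed drives a
`SeedSequence` tree whose child streams feed each component, so adding a
stage never shifts another stage's draws.

What the generator does **not** emulate: real nomenclatural noise,
geographic or cultural structure, correlated organ use, non-ultrametric
branch-length error, and the taxonomic imbalance of real floras.  Passing
tests therefore demonstrate correctness of the statistics and recoverability
of planted structure, not field realism.

## Problem sizes and defaults

Analysis constants follow standard practice for these methods: 1000
permutations for D, 999 randomizations for SES and hot nodes, min clade 10,
significance at p 0.05/0.95 and |ses| 1.96.  The calibration script uses a
300-tip tree and 200 traits per anchor, which bounds the Monte-Carlo error
of the mean D well below the ±0.1 acceptance band while completing in under
a minute; test-suite property checks use 40–300-tip trees and ≥ 100 random
instances per identity.

## Known limitations

* The d kernel's nodal weighting differs (documented above) from the
  original implementation's; only the anchored D scale, not raw d, is
  comparable across implementations.
* SES nulls are unweighted presence/absence; no abundance variants.
* Megatree grafting implements crown-node placement only — no stem-age
  attachment, no branch-length interpolation for undated backbone nodes.
* `read_trait_table` canonicalizes name *format*, not nomenclature: synonyms
  are validated, never merged.
* The patristic matrix is dense; beyond ~20k tips a different distance
  backend would be needed.
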