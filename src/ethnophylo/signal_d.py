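"""Fritz-Purvis D: phylogenetic signal for binary traits.

The statistic rescales the observed sum of sister-clade differences d of a
binary trait against two permutation nulls:

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

so that D ~ 1 for a trait shuffled at random across the tips (no signal) and
D ~ 0 for a trait generated by thresholding a Brownian motion at the observed
prevalence (strong signal).  Values below 0 indicate clumping beyond the
Brownian expectation; values above 1 indicate overdispersion.

The d kernel assigns each internal node the inverse-branch-length weighted
average of its children's values, tips to root, and sums the absolute
child-minus-node differences over all internal nodes.  Polytomies are handled
natively by the same formula (for a bifurcation it reduces to the plain
|left - right| difference).  Because both nulls are pushed through the same
kernel, the 0/1 anchoring of the D scale does not depend on the kernel
details.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._treemath import tree_arrays
from .phylo_io import Phylogeny

__all__ = [
    "DStatResult",
    "SignalError",
    "sum_sister_differences",
    "simulate_brownian_threshold",
    "phylo_d",
]


class SignalError(ValueError):
    """Raised when D is undefined (constant trait, degenerate nulls)."""


@dataclass
class DStatResult:
    """One Fritz-Purvis D estimate with its permutation context."""

    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float
    p_rand: float
    p_brownian: float
    n_perm: int
    prevalence: int
    n_tips: int
    seed: int | None = None
    trait_name: str | None = None
    subset: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_rand <= 1.0 and 0.0 <= self.p_brownian <= 1.0):
            raise ValueError("permutation p values must lie in [0, 1]")


def _binary_trait(arrays, trait) -> np.ndarray:
    x = arrays.trait_array(trait)
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise SignalError("trait values must be 0/1")
    return x


def sum_sister_differences(phy: Phylogeny, trait) -> float:
    """The d kernel: total absolute sister-clade difference of a binary trait.

    ``trait`` maps every tip label to 0/1 (a dict, Series, or an array in the
    tree's tip order).
    """
    arrays = tree_arrays(phy)
    x = _binary_trait(arrays, trait)
    return float(arrays.d_batch(x[:, None])[0])


def simulate_brownian_threshold(
    phy: Phylogeny, prevalence: int, rng=None, seed=None
) -> dict[str, int]:
    """Binary trait from a thresholded Brownian motion on the tree.

    A continuous character evolves by Brownian motion from the root (value 0,
    Gaussian increments with variance proportional to branch length); the
    ``prevalence`` tips with the largest values get state 1, so the realized
    number of 1s is exact.
    """
    arrays = tree_arrays(phy)
    n = arrays.n_tips
    if not 0 < prevalence < n:
        raise SignalError(f"prevalence must be in (0, {n}); got {prevalence}")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = _brownian_binary(arrays, prevalence, 1, rng)[:, 0]
    return {lab: int(v) for lab, v in zip(arrays.tip_labels, x)}


def _brownian_binary(arrays, k: int, n_sim: int, rng) -> np.ndarray:
    cont = arrays.brownian_tips(n_sim, rng)
    out = np.zeros_like(cont)
    top = np.argpartition(-cont, k - 1, axis=0)[:k, :]
    np.put_along_axis(out, top, 1.0, axis=0)
    return out


def phylo_d(
    phy: Phylogeny,
    trait,
    n_perm: int = 1000,
    seed=None,
    rng=None,
    trait_name: str | None = None,
    subset: str | None = None,
) -> DStatResult:
    """Estimate Fritz-Purvis D for a binary trait.

    ``p_rand`` is the one-tailed probability (add-one Monte Carlo estimator)
    of a shuffle producing d <= d_obs — small values mean the trait is more
    phylogenetically clumped than random.  ``p_brownian`` is the probability
    of a Brownian-threshold simulation producing d >= d_obs — small values
    mean the trait is more overdispersed than the Brownian expectation.
    """
    arrays = tree_arrays(phy)
    x = _binary_trait(arrays, trait)
    k = int(x.sum())
    n = arrays.n_tips
    if k == 0 or k == n:
        raise SignalError("trait is constant; phylogenetic signal is undefined")
    if rng is None:
        rng = np.random.default_rng(seed)

    d_obs = float(arrays.d_batch(x[:, None])[0])
    d_rand = arrays.d_batch(arrays.shuffle_matrix(x, n_perm, rng))
    d_brown = arrays.d_batch(_brownian_binary(arrays, k, n_perm, rng))

    d_random_mean = float(d_rand.mean())
    d_brownian_mean = float(d_brown.mean())
    denom = d_random_mean - d_brownian_mean
    if denom == 0:
        raise SignalError(
            "random and Brownian null means coincide; D is undefined on this tree"
        )
    D = (d_obs - d_brownian_mean) / denom
    p_rand = (1 + int((d_rand <= d_obs).sum())) / (n_perm + 1)
    p_brownian = (1 + int((d_brown >= d_obs).sum())) / (n_perm + 1)
    return DStatResult(
        d_obs=d_obs,
        d_random_mean=d_random_mean,
        d_brownian_mean=d_brownian_mean,
        D=float(D),
        p_rand=p_rand,
        p_brownian=p_brownian,
        n_perm=n_perm,
        prevalence=k,
        n_tips=n,
        seed=seed,
        trait_name=trait_name,
        subset=subset,
    )
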