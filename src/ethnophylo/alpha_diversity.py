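"""Faith PD, MPD, MNTD and their standardized effect sizes per guild.

Observed metrics for each species guild are compared with a null that draws
the same number of species uniformly without replacement from the tree's full
tip pool ("taxa labels" null).  ses = (obs - mean null) / sd null; low rank
P values (p < 0.05) flag phylogenetic clustering, high ones (p > 0.95)
overdispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._treemath import membership_rng, ses_score, tree_arrays
from .phylo_io import Phylogeny, UseTraitTable

__all__ = [
    "AlphaDiversityResult",
    "AlphaDiversityError",
    "faith_pd",
    "mpd",
    "mntd",
    "ses_alpha",
    "guild_summary",
]

log = logging.getLogger(__name__)

METRICS = ("PD", "MPD", "MNTD")


class AlphaDiversityError(ValueError):
    pass


@dataclass
class AlphaDiversityResult:
    """Per-guild alpha phylodiversity row (one line of the summary table)."""

    guild: str
    SR: int
    PD: float
    MPD: float
    MNTD: float
    ses_PD: float
    p_PD: float
    ses_MPD: float
    p_MPD: float
    ses_MNTD: float
    p_MNTD: float
    n_null: int
    seed: int | None = None

    def clustering_flags(self, low: float = 0.05, high: float = 0.95) -> dict:
        """'clustered' (p < low), 'overdispersed' (p > high) or 'ns' per metric."""
        out = {}
        for m in METRICS:
            p = getattr(self, f"p_{m}")
            if np.isnan(p):
                out[m] = "undefined"
            elif p < low:
                out[m] = "clustered"
            elif p > high:
                out[m] = "overdispersed"
            else:
                out[m] = "ns"
        return out


def faith_pd(phy: Phylogeny, taxa, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of branch lengths in the union of root-to-tip paths of ``taxa``
    (with ``include_root=False``, branches above the set's MRCA are dropped,
    the classical minimal-spanning-subtree variant).
    """
    taxa = set(taxa)
    if not taxa:
        raise AlphaDiversityError("faith_pd needs at least one species")
    arrays = tree_arrays(phy)
    s = arrays.member_matrix(taxa)
    return float(arrays.pd_batch(s, include_root=include_root)[0])


def _pair_indices(arrays, taxa):
    taxa = set(taxa)
    if len(taxa) < 2:
        raise AlphaDiversityError("MPD/MNTD need at least two species")
    try:
        return np.array(sorted(arrays.tip_index[t] for t in taxa))
    except KeyError as exc:
        raise AlphaDiversityError(f"species not in tree: {exc}") from exc


def mpd(phy: Phylogeny, taxa) -> float:
    """Mean pairwise patristic distance over all unordered pairs."""
    arrays = tree_arrays(phy)
    idx = _pair_indices(arrays, taxa)
    sub = arrays.patristic[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def mntd(phy: Phylogeny, taxa) -> float:
    """Mean distance from each member to its nearest other member."""
    arrays = tree_arrays(phy)
    idx = _pair_indices(arrays, taxa)
    sub = arrays.patristic[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_metric_batch(arrays, metric: str, S: np.ndarray, include_root: bool):
    if metric == "PD":
        return arrays.pd_batch(S, include_root=include_root)
    D = arrays.patristic
    k = int(S[:, 0].sum())
    if metric == "MPD":
        return np.einsum("ib,ib->b", S, D @ S) / (k * (k - 1))
    if metric == "MNTD":
        out = np.empty(S.shape[1])
        for b in range(S.shape[1]):
            idx = np.flatnonzero(S[:, b])
            sub = D[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            out[b] = sub.min(axis=1).mean()
        return out
    raise AlphaDiversityError(f"unknown metric {metric!r}")


def ses_alpha(
    phy: Phylogeny,
    taxa,
    metric: str = "PD",
    n_null: int = 999,
    seed=None,
    rng=None,
    include_root: bool = True,
):
    """Standardized effect size of PD, MPD or MNTD against the tip-pool null.

    Returns ``(obs, ses, p)``.  p is the add-one rank estimator
    ``(1 + #{null <= obs}) / (n_null + 1)``; ses is NaN when the null has zero
    spread (e.g. the guild is the full tip pool), in which case p is still a
    valid rank.
    """
    metric = metric.upper()
    if metric not in METRICS:
        raise AlphaDiversityError(f"metric must be one of {METRICS}")
    arrays = tree_arrays(phy)
    taxa = set(taxa)
    k = len(taxa)
    if metric == "PD":
        obs = faith_pd(phy, taxa, include_root=include_root)
    elif metric == "MPD":
        obs = mpd(phy, taxa)
    else:
        obs = mntd(phy, taxa)
    if rng is None:
        rng = np.random.default_rng(seed)
    S = arrays.random_subsets(k, n_null, rng)
    null = _null_metric_batch(arrays, metric, S, include_root)
    ses = ses_score(obs, null)
    p = (1 + int((null <= obs * (1 + 1e-12)).sum())) / (n_null + 1)
    return obs, ses, p


def guild_summary(
    phy: Phylogeny,
    traits: UseTraitTable,
    guilds,
    n_null: int = 999,
    seed=None,
    include_root: bool = True,
) -> list[AlphaDiversityResult]:
    """One alpha-diversity row per guild (flag column of the trait table).

    Species carrying a flag but absent from the tree are logged and excluded.
    Empty guilds are skipped with a warning.  Each guild consumes an
    independent child stream of the seed, so rows are reproducible regardless
    of guild order.
    """
    arrays = tree_arrays(phy)
    tips = set(arrays.tip_labels)
    results = []
    for guild in guilds:
        members = traits.guild(guild)
        dropped = members - tips
        if dropped:
            log.info("guild %s: %d species not in tree, excluded", guild, len(dropped))
        members &= tips
        if not members:
            log.warning("guild %s: empty after matching to tree; skipped", guild)
            continue
        # rng keyed on (seed, membership): identical guilds give identical rows
        rng = membership_rng(seed, members)
        row = {"guild": guild, "SR": len(members), "n_null": n_null, "seed": seed}
        for metric in METRICS:
            if metric != "PD" and len(members) < 2:
                row[metric] = float("nan")
                row[f"ses_{metric}"] = float("nan")
                row[f"p_{metric}"] = float("nan")
                continue
            obs, ses, p = ses_alpha(
                phy, members, metric=metric, n_null=n_null, rng=rng,
                include_root=include_root,
            )
            row[metric] = obs
            row[f"ses_{metric}"] = ses
            row[f"p_{metric}"] = p
        results.append(AlphaDiversityResult(**row))
    return results


def summary_frame(results: list[AlphaDiversityResult]) -> pd.DataFrame:
    """Tabulate guild results with the conventional picante-style headers."""
    rows = []
    for r in results:
        rows.append(
            {
                "guild": r.guild,
                "SR": r.SR,
                "PD": r.PD,
                "MPD": r.MPD,
                "MNTD": r.MNTD,
                "ses.PD": r.ses_PD,
                "p.PD": r.p_PD,
                "ses.MPD": r.ses_MPD,
                "p.MPD": r.p_MPD,
                "ses.MNTD": r.ses_MNTD,
                "p.MNTD": r.p_MNTD,
            }
        )
    return pd.DataFrame(rows)
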