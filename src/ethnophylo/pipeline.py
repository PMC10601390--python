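"""Orchestration: graft -> signal -> alpha -> beta -> hot nodes over a config.

``run_all`` executes the stages in dependency order over one set of inputs,
writing the four result tables (signal.csv, alpha.csv, beta.csv,
hotnodes_<guild>.csv), the grafted tree and graft report when a megatree is
supplied, and a JSON manifest with seeds and input/output checksums.  Every
stage draws from its own child stream of the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha_diversity import guild_summary, summary_frame
from .beta_diversity import DEFAULT_PAIRS, beta_frame, guild_beta_matrix
from .hotnodes import hot_node_scan, results_frame
from .megatree import graft_species, prune_to
from .phylo_io import (
    USE_FLAGS,
    ORGAN_FLAGS,
    Phylogeny,
    PhyloIOError,
    read_newick,
    read_trait_table,
)
from .signal_d import SignalError, phylo_d

__all__ = ["RunConfig", "run_all", "PipelineError"]

log = logging.getLogger(__name__)

DEFAULT_GUILDS = ["edible", "condiment", "wrapping", "cultivated", "wild"]
DEFAULT_SUBSETS = ["all", "wild", "cultivated"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All paths and analysis constants for one pipeline run."""

    tree: str  # megatree or ready study tree (Newick)
    traits: str  # trait table CSV/TSV
    out_dir: str
    family_map: str | None = None  # tip,family CSV for family-level grafts
    graft: bool = True  # place missing species before pruning
    guilds: list[str] = field(default_factory=lambda: list(DEFAULT_GUILDS))
    signal_columns: list[str] = field(
        default_factory=lambda: list(USE_FLAGS) + list(ORGAN_FLAGS)
    )
    subsets: list[str] = field(default_factory=lambda: list(DEFAULT_SUBSETS))
    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    hotnode_columns: list[str] = field(default_factory=lambda: list(DEFAULT_GUILDS))
    n_perm: int = 1000  # D-statistic permutations
    n_null: int = 999  # alpha / beta / hot-node randomizations
    min_clade: int = 10
    ses_threshold: float = 1.96
    include_root: bool = True
    tolerance: float = 1e-6
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairs" in raw:
            raw["pairs"] = [tuple(p.split(":")) if isinstance(p, str) else tuple(p)
                            for p in raw["pairs"]]
        return cls(**raw)

    def validate(self, trait_columns) -> None:
        for n, v in (("n_perm", self.n_perm), ("n_null", self.n_null),
                     ("min_clade", self.min_clade)):
            if v <= 0:
                raise PipelineError(f"{n} must be positive, got {v}")
        known = set(trait_columns)
        for group, cols in (
            ("guilds", self.guilds),
            ("signal_columns", self.signal_columns),
            ("hotnode_columns", self.hotnode_columns),
            ("pairs", [g for p in self.pairs for g in p]),
        ):
            unknown = [c for c in cols if c not in known]
            if unknown:
                raise PipelineError(
                    f"config {group} references unknown trait columns {unknown}"
                )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _subset_species(traits, subset: str) -> set[str]:
    if subset == "all":
        return set(traits.species)
    return traits.guild(subset)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    ss = np.random.SeedSequence(config.seed)
    seed_signal, seed_alpha, seed_beta, seed_hot = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        tree = read_newick(config.tree)
        traits, taxa = read_trait_table(config.traits)
        config.validate(traits.frame.columns)
        manifest["inputs"]["tree"] = _sha256(config.tree)
        manifest["inputs"]["traits"] = _sha256(config.traits)
    except (OSError, PhyloIOError, PipelineError) as exc:
        raise PipelineError(f"stage load failed: {exc}") from exc

    try:
        stage("graft")
        if config.graft:
            family_map = None
            if config.family_map:
                fm = pd.read_csv(config.family_map)
                family_map = dict(zip(fm.iloc[:, 0], fm.iloc[:, 1]))
                manifest["inputs"]["family_map"] = _sha256(config.family_map)
            tree, report = graft_species(
                tree, taxa, family_map=family_map, tol=config.tolerance
            )
            keep = set(traits.species) & set(tree.tip_labels)
            tree = prune_to(tree, keep)
            tree.write(out_dir / "grafted_pruned.nwk")
            report.to_frame().to_csv(out_dir / "graft_report.csv", index=False)
            manifest["graft"] = {
                "n_already_present": report.n_already_present,
                "n_grafted_to_genus": report.n_grafted_to_genus,
                "n_grafted_to_family": report.n_grafted_to_family,
                "unplaced": report.unplaced,
            }
    except PhyloIOError as exc:
        raise PipelineError(f"stage graft failed: {exc}") from exc

    study_species = set(tree.tip_labels) & set(traits.species)
    traits_on_tree = traits.subset(study_species)

    try:
        stage("signal")
        rows = []
        for subset in config.subsets:
            sub_species = _subset_species(traits_on_tree, subset) & study_species
            if len(sub_species) < 3:
                log.warning("subset %s has <3 species; skipped", subset)
                continue
            sub_tree = prune_to(tree, sub_species)
            sub_traits = traits_on_tree.subset(sub_species)
            for col in config.signal_columns:
                vec = {
                    s: int(v)
                    for s, v in sub_traits.frame[col].items()
                }
                try:
                    res = phylo_d(
                        sub_tree, vec, n_perm=config.n_perm,
                        seed=seed_signal, trait_name=col, subset=subset,
                    )
                except SignalError:
                    rows.append({"subset": subset, "column": col, "D": np.nan,
                                 "p_rand": np.nan, "p_brownian": np.nan,
                                 "d_obs": np.nan, "n_perm": config.n_perm,
                                 "seed": seed_signal})
                    continue
                rows.append({"subset": subset, "column": col, "D": res.D,
                             "p_rand": res.p_rand, "p_brownian": res.p_brownian,
                             "d_obs": res.d_obs, "n_perm": res.n_perm,
                             "seed": seed_signal})
        pd.DataFrame(rows).to_csv(out_dir / "signal.csv", index=False)
    except SignalError as exc:
        raise PipelineError(f"stage signal failed: {exc}") from exc

    try:
        stage("alpha")
        alpha = guild_summary(
            tree, traits_on_tree, config.guilds,
            n_null=config.n_null, seed=seed_alpha,
            include_root=config.include_root,
        )
        summary_frame(alpha).to_csv(out_dir / "alpha.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"stage alpha failed: {exc}") from exc

    try:
        stage("beta")
        beta = guild_beta_matrix(
            tree, traits_on_tree, pairs=config.pairs,
            n_null=config.n_null, seed=seed_beta,
            include_root=config.include_root,
        )
        beta_frame(beta).to_csv(out_dir / "beta.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"stage beta failed: {exc}") from exc

    try:
        stage("hotnodes")
        order = list(tree.tip_labels)
        for col in config.hotnode_columns:
            vec = traits_on_tree.trait_vector(col, order)
            results = hot_node_scan(
                tree, dict(zip(order, (int(v) for v in vec))),
                min_clade=config.min_clade, n_perm=config.n_null,
                ses_threshold=config.ses_threshold, seed=seed_hot,
            )
            results_frame(results).to_csv(
                out_dir / f"hotnodes_{col}.csv", index=False
            )
    except Exception as exc:
        raise PipelineError(f"stage hotnodes failed: {exc}") from exc

    for f in sorted(out_dir.iterdir()):
        if f.suffix in (".csv", ".nwk"):
            manifest["outputs"][f.name] = _sha256(f)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
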