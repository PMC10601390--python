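"""Input/output and validation for trees and use-trait tables.

Trees are held as rooted, branch-lengthed :class:`Phylogeny` objects built on
dendropy; trait tables as :class:`UseTraitTable` objects built on pandas.
Species names are matched between the two on canonical underscore binomials
("Piper_auritum"), the labelling convention of published seed-plant megatrees.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "UseTraitTable",
    "TaxonRecord",
    "PhyloIOError",
    "NewickParseError",
    "TraitTableError",
    "canonicalize_name",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "write_trait_table",
    "MANAGEMENT_FLAGS",
    "USE_FLAGS",
    "ORGAN_FLAGS",
    "ALL_FLAGS",
]

MANAGEMENT_FLAGS = ("wild", "cultivated")
USE_FLAGS = ("edible", "condiment", "wrapping")
ORGAN_FLAGS = (
    "root_rhizome_bulb",
    "stem",
    "bark",
    "wood",
    "leaf",
    "flowers",
    "fruits",
    "seeds",
    "resin_latex",
)
ALL_FLAGS = MANAGEMENT_FLAGS + USE_FLAGS + ORGAN_FLAGS

_TAXONOMY_COLUMNS = ("species", "genus", "family")


class PhyloIOError(ValueError):
    """Base error for malformed tree or trait-table input."""


class NewickParseError(PhyloIOError):
    """Raised when a Newick file violates the tree invariants."""


class TraitTableError(PhyloIOError):
    """Raised when a trait table violates the table invariants."""


def canonicalize_name(raw: str) -> str:
    """Normalize a species name to an underscore-joined binomial.

    Whitespace is trimmed and collapsed, separators (spaces or underscores)
    become single underscores, the genus is capitalized and the remaining
    epithets lowercased.  The function is idempotent.

    >>> canonicalize_name(" piper  auritum ")
    'Piper_auritum'
    """
    if raw is None:
        raise PhyloIOError("species name is empty")
    parts = [p for p in re.split(r"[\s_]+", str(raw).strip()) if p]
    if len(parts) < 2:
        raise PhyloIOError(
            f"species name {raw!r} has fewer than two parts; expected a binomial"
        )
    genus = parts[0][0].upper() + parts[0][1:].lower()
    epithets = [p.lower() for p in parts[1:]]
    return "_".join([genus] + epithets)


@dataclass(frozen=True)
class TaxonRecord:
    """Species-to-genus-to-family mapping used for megatree placement."""

    species: str
    genus: str
    family: str

    def __post_init__(self):
        if not self.family:
            raise PhyloIOError(f"taxon {self.species!r} has an empty family")
        if self.species.split("_")[0] != self.genus:
            raise PhyloIOError(
                f"taxon {self.species!r}: genus field {self.genus!r} does not "
                f"match the first epithet of the species name"
            )


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Thin validation wrapper around a :class:`dendropy.Tree`.  All downstream
    statistics consume this type; they treat it as immutable and cache derived
    numeric structures on it.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        if tree.seed_node.edge.length is None:
            tree.seed_node.edge.length = 0.0
        self._tree = tree
        self._validate()
        self._cache: dict = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a single Newick string (must end with ';')."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        labels: list[str] = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickParseError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise NewickParseError(
                    f"edge above {describe_node(node)} has no branch length"
                )
            if node.edge.length < 0:
                raise NewickParseError(
                    f"edge above {describe_node(node)} has negative length "
                    f"{node.edge.length}"
                )
        self._tip_labels = tuple(labels)

    # -- basic accessors ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def __len__(self) -> int:
        return self.n_tips

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def total_branch_length(self) -> float:
        return float(
            sum(
                nd.edge.length
                for nd in self._tree.preorder_node_iter()
                if nd is not self._tree.seed_node
            )
        )

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths keyed by tip label."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        """True when (max depth - min depth) <= tol * max depth."""
        depths = np.array(list(self.tip_depths().values()))
        dmax = depths.max()
        if dmax == 0:
            return True
        return bool(depths.max() - depths.min() <= tol * dmax)

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())


def describe_node(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"clade of {len(tips)} tips ({', '.join(sorted(tips)[:3])}...)"


def read_newick(path) -> Phylogeny:
    """Read one Newick tree from ``path`` and validate it."""
    with open(path) as fh:
        text = fh.read()
    if ";" not in text:
        raise NewickParseError(f"{path}: no ';'-terminated Newick statement found")
    return Phylogeny.from_newick(text)


def write_newick(phy: Phylogeny, path) -> None:
    phy.write(path)


class UseTraitTable:
    """Species-by-flag binary table of management, use, and organ traits.

    Wraps a pandas DataFrame indexed by canonical species name with strictly
    0/1 integer columns.  Every species must carry at least one use flag
    (edible, condiment or wrapping); management flags are independent bits, so
    a species may be both wild and cultivated.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in MANAGEMENT_FLAGS + USE_FLAGS if c not in frame.columns]
        if missing:
            raise TraitTableError(f"missing required flag columns: {missing}")
        for organ in ORGAN_FLAGS:
            if organ not in frame.columns:
                frame[organ] = 0
        # standard flags first; extra user-defined guild columns are kept
        extra = [c for c in frame.columns if c not in ALL_FLAGS]
        frame = frame[list(ALL_FLAGS) + extra]
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise TraitTableError(f"duplicate species: {dupes}")
        coded = frame.apply(lambda col: col.map(_coerce_flag))
        bad = coded.isna()
        if bad.any().any():
            rows = []
            for i, j in zip(*np.where(bad.values)):
                sp, col = frame.index[i], frame.columns[j]
                rows.append(f"row {sp!r}, column {col!r}: {frame.at[sp, col]!r}")
            raise TraitTableError("non-binary flag values: " + "; ".join(rows))
        coded = coded.astype(np.int8)
        no_use = coded[list(USE_FLAGS)].sum(axis=1) == 0
        if no_use.any():
            raise TraitTableError(
                "species with no use flag (edible/condiment/wrapping all 0): "
                f"{coded.index[no_use].tolist()}"
            )
        self._frame = coded

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, UseTraitTable) and self._frame.equals(other._frame)

    def guild(self, flag: str) -> set[str]:
        """Species set carrying a given flag."""
        if flag not in self._frame.columns:
            raise TraitTableError(f"unknown flag column {flag!r}")
        col = self._frame[flag]
        return set(col.index[col == 1])

    def trait_vector(self, flag: str, order: Sequence[str]) -> np.ndarray:
        """0/1 vector for ``flag`` in the given species order."""
        if flag not in self._frame.columns:
            raise TraitTableError(f"unknown flag column {flag!r}")
        missing = [s for s in order if s not in self._frame.index]
        if missing:
            raise TraitTableError(f"species absent from trait table: {missing[:5]}")
        return self._frame.loc[list(order), flag].to_numpy(dtype=np.int8)

    def subset(self, species: Iterable[str]) -> "UseTraitTable":
        keep = [s for s in self._frame.index if s in set(species)]
        return UseTraitTable(self._frame.loc[keep])


def _coerce_flag(v):
    if isinstance(v, str):
        v = v.strip().lower()
        if v in ("1", "true", "t", "yes"):
            return 1
        if v in ("0", "false", "f", "no"):
            return 0
        return np.nan
    if isinstance(v, (bool, np.bool_)):
        return int(v)
    try:
        f = float(v)
    except (TypeError, ValueError):
        return np.nan
    if f in (0.0, 1.0):
        return int(f)
    return np.nan


def read_trait_table(path, delimiter: str | None = None):
    """Read a delimited trait table.

    Returns a ``(UseTraitTable, list[TaxonRecord])`` pair.  The delimiter is
    auto-detected between comma and tab unless given.  Required columns:
    species, genus, family, plus the five management/use flags; the nine organ
    flags are filled with 0 when absent.
    """
    with open(path) as fh:
        text = fh.read()
    if delimiter is None:
        header = text.splitlines()[0] if text else ""
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"{path}: missing required columns {missing}")
    species = [canonicalize_name(s) for s in df["species"]]
    taxa = []
    for sp, genus, family in zip(species, df["genus"], df["family"]):
        genus = str(genus).strip()
        genus = genus[0].upper() + genus[1:].lower() if genus else genus
        taxa.append(TaxonRecord(species=sp, genus=genus, family=str(family).strip()))
    flags = df.drop(columns=list(_TAXONOMY_COLUMNS))
    flags.index = pd.Index(species, name="species")
    return UseTraitTable(flags), taxa


def write_trait_table(
    table: UseTraitTable,
    taxa: Sequence[TaxonRecord],
    path,
    delimiter: str = ",",
) -> None:
    """Write a trait table with its taxonomy in the standard column order."""
    by_species = {t.species: t for t in taxa}
    missing = [s for s in table.species if s not in by_species]
    if missing:
        raise TraitTableError(f"no TaxonRecord for species: {missing[:5]}")
    out = table.frame.copy()
    out.insert(0, "family", [by_species[s].family for s in out.index])
    out.insert(0, "genus", [by_species[s].genus for s in out.index])
    out.index.name = "species"
    out.to_csv(path, sep=delimiter)
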