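"""Tree and trait-table IO: parsing, validation, canonical names, round trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethnophylo.phylo_io import (
    NewickParseError,
    Phylogeny,
    TaxonRecord,
    TraitTableError,
    UseTraitTable,
    canonicalize_name,
    read_newick,
    read_trait_table,
    write_trait_table,
)
from ethnophylo.synthetic_data import make_study_like_dataset, simulate_tree

from .conftest import FOUR_TIP, bipartitions_with_lengths


class TestCanonicalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (" piper  auritum ", "Piper_auritum"),
            ("Piper_auritum", "Piper_auritum"),
            ("PIPER AURITUM", "Piper_auritum"),
            ("sechium edule var. edule", "Sechium_edule_var._edule"),
            ("annona  muricata", "Annona_muricata"),
        ],
    )
    def test_examples(self, raw, expected):
        assert canonicalize_name(raw) == expected

    @given(st.text(alphabet="abcdefgXYZ _", min_size=0, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_or_rejects(self, raw):
        try:
            once = canonicalize_name(raw)
        except Exception:
            return
        assert canonicalize_name(once) == once

    @pytest.mark.parametrize("bad", ["Piper", "  ", "", "genus"])
    def test_mononomials_rejected(self, bad):
        with pytest.raises(Exception):
            canonicalize_name(bad)


class TestNewick:
    def test_four_tip_total_length(self, four_tip):
        assert four_tip.n_tips == 4
        assert four_tip.total_branch_length() == pytest.approx(6.0)

    def test_round_trip_preserves_structure(self, tmp_path):
        phy = Phylogeny.from_newick(FOUR_TIP)
        path = tmp_path / "t.nwk"
        phy.write(path)
        back = read_newick(path)
        assert set(back.tip_labels) == set(phy.tip_labels)
        assert bipartitions_with_lengths(back) == pytest.approx(
            bipartitions_with_lengths(phy)
        )

    def test_round_trip_random_trees(self, tmp_path):
        for seed in range(5):
            phy = simulate_tree(17, seed=seed)
            p = tmp_path / f"{seed}.nwk"
            phy.write(p)
            back = read_newick(p)
            orig = bipartitions_with_lengths(phy)
            got = bipartitions_with_lengths(back)
            assert set(got) == set(orig)
            for k in orig:
                assert got[k] == pytest.approx(orig[k], rel=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError):
            Phylogeny.from_newick("((A:1,A:1):1);")

    def test_unbalanced_rejected(self):
        with pytest.raises(NewickParseError):
            Phylogeny.from_newick("((A:1,B:1:1);")

    def test_negative_length_rejected(self):
        with pytest.raises(NewickParseError, match="negative"):
            Phylogeny.from_newick("((A:1,B:-0.5):1,C:2);")

    def test_missing_length_rejected(self):
        with pytest.raises(NewickParseError, match="branch length"):
            Phylogeny.from_newick("((A:1,B):1,C:2);")

    def test_quoted_labels_and_comments(self):
        phy = Phylogeny.from_newick("(('Piper auritum':1,B:1)[a comment]:1,C:2);")
        assert "Piper auritum" in phy.tip_labels

    def test_ultrametric_check(self):
        assert Phylogeny.from_newick(FOUR_TIP).is_ultrametric(1e-9)
        skewed = Phylogeny.from_newick("((A:1,B:2):1,C:2);")
        assert not skewed.is_ultrametric(0.1)


class TestTaxonRecord:
    def test_genus_must_match_species(self):
        with pytest.raises(Exception):
            TaxonRecord(species="Piper_auritum", genus="Ocotea", family="Piperaceae")
        with pytest.raises(Exception):
            TaxonRecord(species="Piper_auritum", genus="Piper", family="")
        rec = TaxonRecord(species="Piper_auritum", genus="Piper", family="Piperaceae")
        assert rec.family == "Piperaceae"


HEADER = (
    "species,genus,family,wild,cultivated,edible,condiment,wrapping,"
    "root_rhizome_bulb,stem,bark,wood,leaf,flowers,fruits,seeds,resin_latex"
)


def _table_text(rows):
    return HEADER + "\n" + "\n".join(rows) + "\n"


class TestTraitTable:
    def test_three_row_echo(self, tmp_path):
        text = _table_text(
            [
                "Piper auritum,Piper,Piperaceae,1,0,0,1,0,0,0,0,0,1,0,0,0,0",
                "Annona muricata,Annona,Annonaceae,0,1,1,0,0,0,0,0,0,0,0,1,0,0",
                "Zea mays,Zea,Poaceae,1,1,1,0,1,0,0,0,0,1,0,1,1,0",
            ]
        )
        p = tmp_path / "t.csv"
        p.write_text(text)
        table, taxa = read_trait_table(p)
        assert len(table) == 3
        assert table.guild("condiment") == {"Piper_auritum"}
        assert table.guild("wild") == {"Piper_auritum", "Zea_mays"}
        assert {t.family for t in taxa} == {"Piperaceae", "Annonaceae", "Poaceae"}

    def test_tab_delimiter_autodetected(self, tmp_path):
        text = _table_text(
            ["Zea mays,Zea,Poaceae,1,0,1,0,0,0,0,0,0,0,0,1,1,0"]
        ).replace(",", "\t")
        p = tmp_path / "t.tsv"
        p.write_text(text)
        table, _ = read_trait_table(p)
        assert table.guild("edible") == {"Zea_mays"}

    def test_no_use_flag_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            _table_text(["Zea mays,Zea,Poaceae,1,0,0,0,0,0,0,0,0,0,0,0,0,0"])
        )
        with pytest.raises(TraitTableError, match="no use flag"):
            read_trait_table(p)

    def test_nonbinary_flag_names_row_and_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            _table_text(["Zea mays,Zea,Poaceae,1,0,2,0,0,0,0,0,0,0,0,0,0,0"])
        )
        with pytest.raises(TraitTableError) as err:
            read_trait_table(p)
        assert "Zea_mays" in str(err.value) and "edible" in str(err.value)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            _table_text(
                [
                    "Zea mays,Zea,Poaceae,1,0,1,0,0,0,0,0,0,0,0,1,0,0",
                    "zea  mays,Zea,Poaceae,0,1,1,0,0,0,0,0,0,0,0,1,0,0",
                ]
            )
        )
        with pytest.raises(TraitTableError, match="duplicate"):
            read_trait_table(p)

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("species,genus\nZea mays,Zea\n")
        with pytest.raises(TraitTableError, match="missing required"):
            read_trait_table(p)

    def test_wild_and_cultivated_may_coexist(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            _table_text(["Zea mays,Zea,Poaceae,1,1,1,0,0,0,0,0,0,0,0,1,0,0"])
        )
        table, _ = read_trait_table(p)
        assert table.guild("wild") == table.guild("cultivated") == {"Zea_mays"}

    def test_write_read_round_trip_synthetic(self, tmp_path):
        ds = make_study_like_dataset(seed=3, n_tips=40, n_genera=12, n_families=4)
        p = tmp_path / "t.csv"
        write_trait_table(ds.traits, ds.taxonomy, p)
        back, taxa = read_trait_table(p)
        assert back == ds.traits
        assert sorted(t.species for t in taxa) == sorted(
            t.species for t in ds.taxonomy
        )
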