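"""Lineage normalization, the taxonomy table dialect, and hierarchy gaps."""

import pytest
from hypothesis import given, strategies as st

from ampligauge.errors import ParseError, TaxonomyError
from ampligauge.taxonomy import (
    RANKS,
    Rank,
    RankedLineage,
    TaxonomyDialect,
    TaxonomyTree,
    TrainingRecord,
    TrainingSet,
    normalize_lineage,
    parse_taxonomy_table,
    ranks_omitted_below,
    trim_to_genus,
    write_taxonomy_table,
)


class TestParseTaxonomyTable:
    def test_prefixed_lineage_with_gaps(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tdomain__Bacteria;phylum__P1;genus__G1;\n")
        ts = parse_taxonomy_table(p)
        (rec,) = ts.records
        assert len(rec.lineage) == 3
        assert rec.lineage.name_at(Rank.GENUS) == "genus__G1"
        assert not rec.lineage.has_rank(Rank.CLASS)

    def test_positional_dialect(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tBacteria;P1;C1;O1;F1;G1\n")
        ts = parse_taxonomy_table(p, TaxonomyDialect())
        (rec,) = ts.records
        assert len(rec.lineage) == 6
        assert rec.lineage.entries[0] == (Rank.DOMAIN, "domain__Bacteria")
        assert rec.lineage.entries[5] == (Rank.GENUS, "genus__G1")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("")
        assert len(parse_taxonomy_table(p)) == 0

    def test_species_column(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tdomain__Bacteria;genus__G1;\tEscherichia coli\n")
        ts = parse_taxonomy_table(p, TaxonomyDialect(species_column=True))
        assert ts.records[0].lineage.species == "Escherichia coli"

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tdomain__Bacteria;\njunk-without-tab\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_taxonomy_table(p)

    def test_duplicate_id_names_the_id(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tdomain__Bacteria;\ns1\tdomain__Bacteria;\n")
        with pytest.raises(ParseError, match="s1"):
            parse_taxonomy_table(p)

    def test_round_trip_is_byte_identical(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p1.write_text(
            "s1\tdomain__Bacteria;phylum__P1;genus__G1;\n"
            "s2\tdomain__Bacteria;phylum__P2;class__C2;order__O2;family__F2;genus__G2;\n"
        )
        ts = parse_taxonomy_table(p1)
        p2 = tmp_path / "b.tsv"
        write_taxonomy_table(ts, p2)
        assert p2.read_bytes() == p1.read_bytes()
        assert parse_taxonomy_table(p2) == ts


class TestNormalizeLineage:
    def test_drops_unclassified_and_incertae_sedis(self):
        lin = normalize_lineage(
            [
                ("Bacteria", Rank.DOMAIN),
                ("unclassified_Bacteria", Rank.PHYLUM),
                ("Foo_incertae_sedis", Rank.CLASS),
                ("G1", Rank.GENUS),
            ]
        )
        assert [n for _, n in lin] == ["domain__Bacteria", "genus__G1"]

    def test_same_name_at_two_ranks_distinguished_by_prefix(self):
        lin = normalize_lineage(
            [
                ("Bacteria", Rank.DOMAIN),
                ("Actinobacteria", Rank.PHYLUM),
                ("Actinobacteria", Rank.CLASS),
            ]
        )
        assert [n for _, n in lin] == [
            "domain__Bacteria",
            "phylum__Actinobacteria",
            "class__Actinobacteria",
        ]

    def test_idempotent_on_clean_lineage(self):
        raw = [(f"{r.label}__T{r}", r) for r in RANKS]
        once = normalize_lineage(raw)
        twice = normalize_lineage([(n, r) for r, n in once.entries])
        assert once == twice

    def test_duplicate_rank_is_error(self):
        with pytest.raises(TaxonomyError, match="rank"):
            normalize_lineage([("A", Rank.PHYLUM), ("B", Rank.PHYLUM)])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(RANKS),
                st.text(
                    alphabet=st.characters(whitelist_categories=("Lu", "Ll")),
                    min_size=1,
                    max_size=8,
                ),
            ),
            unique_by=lambda t: t[0],
            min_size=1,
            max_size=6,
        )
    )
    def test_each_rank_appears_at_most_once_and_idempotent(self, raw):
        lin = normalize_lineage([(name, rank) for rank, name in raw])
        ranks = [r for r, _ in lin]
        assert len(ranks) == len(set(ranks))
        again = normalize_lineage([(n, r) for r, n in lin.entries])
        assert again == lin


class TestTrimToGenus:
    def test_species_is_dropped(self):
        lin = normalize_lineage(
            [("Bacteria", Rank.DOMAIN), ("G1", Rank.GENUS)], species="G1 sp1"
        )
        trimmed = trim_to_genus(lin)
        assert trimmed.species is None
        assert trimmed.entries == lin.entries

    @pytest.mark.parametrize(
        "raw",
        [
            [("Bacteria", Rank.DOMAIN), ("G1", Rank.GENUS)],
            [("Bacteria", Rank.DOMAIN), ("P1", Rank.PHYLUM)],
        ],
    )
    def test_identity_without_species(self, raw):
        lin = normalize_lineage(raw)
        assert trim_to_genus(lin) == lin


class TestRanksOmittedBelow:
    def _tree(self, *lineage_specs):
        lineages = [
            normalize_lineage([(n, r) for n, r in spec]) for spec in lineage_specs
        ]
        return TaxonomyTree.from_lineages(lineages)

    def test_childless_phylum_omits_everything_below(self):
        tree = self._tree([("Bacteria", Rank.DOMAIN), ("P1", Rank.PHYLUM)])
        node = tree.find(Rank.PHYLUM, "phylum__P1")
        assert ranks_omitted_below(tree, node) == {
            Rank.CLASS,
            Rank.ORDER,
            Rank.FAMILY,
            Rank.GENUS,
        }

    def test_classes_parenting_genera_omit_order_and_family(self):
        tree = self._tree(
            [
                ("Bacteria", Rank.DOMAIN),
                ("Acidobacteria", Rank.PHYLUM),
                ("C1", Rank.CLASS),
                ("G1", Rank.GENUS),
            ]
        )
        node = tree.find(Rank.PHYLUM, "phylum__Acidobacteria")
        assert ranks_omitted_below(tree, node) == {Rank.ORDER, Rank.FAMILY}

    def test_fully_populated_subtree_omits_nothing(self):
        tree = self._tree(
            [(f"T{r.label}", r) for r in RANKS],
        )
        node = tree.find(Rank.PHYLUM, "phylum__Tphylum")
        assert ranks_omitted_below(tree, node) == set()

    def test_unknown_node_is_error(self):
        tree = self._tree([("Bacteria", Rank.DOMAIN), ("P1", Rank.PHYLUM)])
        from ampligauge.taxonomy import TaxonNode

        foreign = TaxonNode(name="phylum__X", rank=Rank.PHYLUM)
        with pytest.raises(TaxonomyError):
            ranks_omitted_below(tree, foreign)


def test_duplicate_sequence_ids_rejected():
    lin = normalize_lineage([("Bacteria", Rank.DOMAIN)])
    with pytest.raises(TaxonomyError, match="dup"):
        TrainingSet(
            (
                TrainingRecord("x", "ACGT", lin),
                TrainingRecord("x", "ACGT", lin),
            )
        )


def test_lineage_ranks_must_strictly_increase():
    with pytest.raises(TaxonomyError):
        RankedLineage(((Rank.GENUS, "genus__G"), (Rank.PHYLUM, "phylum__P")))
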