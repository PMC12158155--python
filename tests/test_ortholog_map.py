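import pytest

from orthomapper import (
    ConversionWarning,
    DialectError,
    HomologyType,
    OrthologPair,
    OrthologTable,
    OrthomapperError,
    classify_cardinality,
    filter_table,
    load_ortholog_table,
    write_ortholog_table_tsv,
)
from tests.conftest import make_table
from tests.oracles import degree_scan_classes


def write_tsv(path, header, rows):
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(r) for r in rows]) + "\n")


class TestLoading:
    def test_biomart_dedup_and_empty_target(self, tmp_path):
        """Duplicate rows collapse; empty homolog cells become unmapped pairs."""
        f = tmp_path / "t.tsv"
        write_tsv(
            f,
            ["external_gene_name", "hsapiens_homolog_associated_gene_name",
             "hsapiens_homolog_orthology_type"],
            [
                ["Trp53", "TP53", "ortholog_one2one"],
                ["Trp53", "TP53", "ortholog_one2one"],
                ["Gm12345", "", ""],
            ],
        )
        table = load_ortholog_table(f, "biomart_tsv")
        assert len(table.mapped_pairs) == 1
        assert table.forward_index["Trp53"] == {"TP53"}
        unmapped = [p for p in table.pairs if p.target_gene is None]
        assert [p.source_gene for p in unmapped] == ["Gm12345"]

    def test_header_only_file_is_no_mapping_rows_error(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_tsv(f, ["source", "target"], [])
        with pytest.raises(OrthomapperError, match="no mapping rows"):
            load_ortholog_table(f, "generic_two_column")

    def test_generic_five_distinct_pairs_all_one2one(self, tmp_path):
        f = tmp_path / "t.tsv"
        rows = [[f"Gene{i}", f"HUM{i}"] for i in range(5)]
        write_tsv(f, ["source", "target"], rows)
        table = load_ortholog_table(f, "generic_two_column")
        assert len(table.mapped_pairs) == 5
        assert all(p.homology_type is HomologyType.ONE2ONE for p in table.mapped_pairs)

    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_tsv(f, ["source", "wrong"], [["A", "B"]])
        with pytest.raises(DialectError, match="target"):
            load_ortholog_table(f, "generic_two_column")
        with pytest.raises(DialectError, match="external_gene_name"):
            load_ortholog_table(f, "biomart_tsv")

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.raises(DialectError, match="empty"):
            load_ortholog_table(f, "biomart_tsv")

    def test_empty_source_rows_skipped_with_warning_and_counted(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_tsv(f, ["source", "target"], [["", "TP53"], ["Trp53", "TP53"]])
        with pytest.warns(ConversionWarning, match="empty source"):
            table = load_ortholog_table(f, "generic_two_column")
        assert table.load_info["n_skipped_empty_source"] == 1
        assert len(table.pairs) == 1

    def test_whitespace_trimmed_and_file_labels_overridden(self, tmp_path):
        """A subsetted export's stale type strings are recomputed away."""
        f = tmp_path / "t.tsv"
        write_tsv(
            f,
            ["external_gene_name", "hsapiens_homolog_associated_gene_name",
             "hsapiens_homolog_orthology_type"],
            [[" Trp53 ", " TP53", "ortholog_many2many"]],
        )
        table = load_ortholog_table(f, "biomart_tsv")
        (pair,) = table.mapped_pairs
        assert (pair.source_gene, pair.target_gene) == ("Trp53", "TP53")
        assert pair.homology_type is HomologyType.ONE2ONE

    def test_roundtrip_through_writer(self, tmp_path):
        table = make_table([("A", "H1"), ("A", "H2"), ("B", "H1")], ["C"])
        for dialect in ("biomart_tsv", "generic_two_column"):
            f = tmp_path / f"{dialect}.tsv"
            write_ortholog_table_tsv(table, f, dialect)
            back = load_ortholog_table(f, dialect)
            assert {(p.source_gene, p.target_gene, p.homology_type)
                    for p in back.pairs} == {
                (p.source_gene, p.target_gene, p.homology_type) for p in table.pairs
            }


class TestClassification:
    def test_isolated_pair_is_one2one(self):
        table = make_table([("A", "H1")])
        assert table.mapped_pairs[0].homology_type is HomologyType.ONE2ONE

    def test_fanout_two_is_one2many(self):
        table = make_table([("A", "H1"), ("A", "H2")])
        assert all(
            p.homology_type is HomologyType.ONE2MANY for p in table.mapped_pairs
        )

    def test_complete_bipartite_all_many2many(self):
        table = make_table(
            [(s, t) for s in ("A", "B") for t in ("H1", "H2")]
        )
        assert all(
            p.homology_type is HomologyType.MANY2MANY for p in table.mapped_pairs
        )

    def test_idempotent(self):
        table = make_table(
            [("A", "H1"), ("A", "H2"), ("B", "H2"), ("C", "H3")], ["D"]
        )
        once = classify_cardinality(table)
        twice = classify_cardinality(once)
        assert once.pairs == twice.pairs

    def test_matches_degree_scan_oracle_on_random_tables(self, rng):
        for _ in range(30):
            n_src = int(rng.integers(2, 15))
            n_tgt = int(rng.integers(2, 10))
            pairs = set()
            for i in range(n_src):
                size = min(int(rng.integers(0, 4)), n_tgt)
                for t in rng.choice(n_tgt, size=size, replace=False):
                    pairs.add((f"S{i}", f"T{t}"))
            if not pairs:
                continue
            table = make_table(sorted(pairs))
            expected = degree_scan_classes(table)
            for p in table.mapped_pairs:
                assert p.homology_type.value == expected[(p.source_gene, p.target_gene)]


class TestFiltering:
    def test_one2one_only_on_bipartite_unmaps_everything(self):
        table = make_table([(s, t) for s in ("A", "B") for t in ("H1", "H2")])
        with pytest.warns(ConversionWarning, match="every mapped pair"):
            out = filter_table(table, allowed_types={HomologyType.ONE2ONE})
        assert len(out.mapped_pairs) == 0
        assert {p.source_gene for p in out.pairs} == {"A", "B"}
        assert all(p.homology_type is HomologyType.UNMAPPED for p in out.pairs)

    def test_min_confidence(self):
        pairs = (
            OrthologPair("A", "H1", HomologyType.ONE2ONE, confidence=1),
            OrthologPair("B", "H2", HomologyType.ONE2ONE, confidence=0),
        )
        out = filter_table(classify_cardinality(OrthologTable(pairs)), min_confidence=1)
        assert [p.source_gene for p in out.mapped_pairs] == ["A"]
        assert {p.source_gene for p in out.pairs} == {"A", "B"}

    def test_noop_filter_is_identity(self):
        table = make_table([("A", "H1"), ("B", "H2"), ("B", "H3")], ["C"])
        out = filter_table(table)
        assert set(out.pairs) == set(table.pairs)

    def test_biotype_filter_and_subset_property(self):
        pairs = (
            OrthologPair("A", "H1", HomologyType.ONE2ONE, source_biotype="protein_coding"),
            OrthologPair("B", "H2", HomologyType.ONE2ONE, source_biotype="lncRNA"),
        )
        table = classify_cardinality(OrthologTable(pairs))
        out = filter_table(table, allowed_biotypes={"protein_coding"})
        assert {p.source_gene for p in out.mapped_pairs} == {"A"}
        assert set(out.mapped_pairs) <= set(table.mapped_pairs)

    def test_reclassification_after_filter(self):
        """Removing one branch of a fan-out turns the survivor one2one."""
        pairs = (
            OrthologPair("A", "H1", HomologyType.ONE2ONE, confidence=1),
            OrthologPair("A", "H2", HomologyType.ONE2ONE, confidence=0),
        )
        table = classify_cardinality(OrthologTable(pairs))
        assert table.mapped_pairs[0].homology_type is HomologyType.ONE2MANY
        out = filter_table(table, min_confidence=1)
        (survivor,) = out.mapped_pairs
        assert survivor.target_gene == "H1"
        assert survivor.homology_type is HomologyType.ONE2ONE


class TestInvariants:
    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OrthologTable(
                (
                    OrthologPair("A", "H1", HomologyType.ONE2ONE),
                    OrthologPair("A", "H1", HomologyType.ONE2ONE),
                )
            )

    def test_indexes_reflect_pairs(self, rng):
        table = make_table([("A", "H1"), ("A", "H2"), ("B", "H1")], ["C"])
        assert table.forward_index == {"A": {"H1", "H2"}, "B": {"H1"}}
        assert table.reverse_index == {"H1": {"A", "B"}, "H2": {"A"}}
        assert table.source_genes == {"A", "B", "C"}

    def test_case_folded_forward_map_unions_targets(self):
        table = make_table([("Abc", "H1"), ("ABC", "H2")])
        folded = table.forward_map(case_insensitive=True)
        assert folded["ABC"] == ("H1", "H2")
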