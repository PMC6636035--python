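"""Gene-table parsing, representative selection, ortholog matching and the
common-gene-set rule."""

import pandas as pd
import pytest

from exomescape.catalog import (
    BASAL_CLADES,
    CLADES,
    GeneRecord,
    GeneTableFormatError,
    SpeciesTable,
    build_common_set,
    filter_protein_coding,
    finalize_table,
    match_orthologs,
    read_alias_map,
    read_gene_table,
    select_representative,
    write_gene_table,
)
from conftest import make_record


def write_tsv(path, rows, columns=None):
    columns = columns or [
        "gene_symbol", "chromosome", "start", "end", "strand",
        "transcript_accession", "transcript_length",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


class TestReadGeneTable:
    def test_reads_valid_rows(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [
            ["A1", "chr1", 1, 100, "+", "NM_1", 100],
            ["B1", "chr1", 200, 400, "-", "NM_2", 150],
            ["C1", "chr2", 1, 50, "+", "XM_3", 50],
        ])
        t = read_gene_table(p, "human", "mammal")
        assert len(t) == 3
        assert t.records[0].gene_symbol == "A1"
        assert t.records[1].strand == "-"

    def test_start_after_end_names_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [
            ["A1", "chr1", 1, 100, "+", "NM_1", 100],
            ["B1", "chr1", 500, 400, "-", "NM_2", 150],
        ])
        with pytest.raises(GeneTableFormatError, match="row 2"):
            read_gene_table(p, "human", "mammal")

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [])
        assert len(read_gene_table(p, "human", "mammal")) == 0

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [["A1", "chr1", 1, 100, "+"]],
                  columns=["gene_symbol", "chromosome", "start", "end", "strand"])
        with pytest.raises(GeneTableFormatError, match="transcript_accession"):
            read_gene_table(p, "human", "mammal")

    def test_unknown_clade_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, [])
        with pytest.raises(ValueError, match="clade"):
            read_gene_table(p, "human", "invertebrate")

    def test_round_trip(self, tmp_path, small_table):
        p = tmp_path / "t.tsv"
        write_gene_table(small_table, p)
        back = read_gene_table(p, "human", "mammal")
        assert back.symbols() == small_table.symbols()
        assert back.records[0].transcript_length == 400


class TestProteinCodingFilter:
    @pytest.mark.parametrize(
        "accessions,kept",
        [
            (["NM_000546", "NR_003287"], ["NM_000546"]),  # rRNA pseudogene-style NR_ dropped
            (["XM_012345"], ["XM_012345"]),  # predicted mRNA retained
            (["XR_001", "NR_002"], []),  # non-coding classes dropped
            ([], []),
        ],
    )
    def test_refseq_prefix_rule(self, accessions, kept):
        recs = [make_record(symbol=f"G{i}", tx=a) for i, a in enumerate(accessions)]
        assert [r.transcript_accession for r in filter_protein_coding(recs)] == kept


class TestSelectRepresentative:
    def test_longest_transcript_wins(self):
        recs = [make_record(tx="NM_1", length=1200),
                make_record(tx="NM_2", length=3400),
                make_record(tx="NM_3", length=800)]
        assert select_representative(recs).transcript_accession == "NM_2"

    def test_single_record(self):
        r = make_record()
        assert select_representative([r]) is r

    def test_tie_breaks_on_accession(self):
        recs = [make_record(tx="NM_9", length=1000), make_record(tx="NM_2", length=1000)]
        assert select_representative(recs).transcript_accession == "NM_2"

    def test_empty_is_usage_error(self):
        with pytest.raises(ValueError):
            select_representative([])

    def test_finalize_idempotent(self):
        recs = [
            make_record("A", tx="NM_1", length=100),
            make_record("A", tx="NM_2", length=300),
            make_record("A", tx="NR_9", length=900),
            make_record("B", chrom="chr2", tx="XM_5", length=50),
        ]
        t = SpeciesTable(species="s", clade="mammal", records=recs)
        once = finalize_table(t)
        twice = finalize_table(once)
        assert [r.transcript_accession for r in once.records] == ["NM_2", "XM_5"]
        assert once.records == twice.records


class TestMatchOrthologs:
    def _ref(self):
        recs = [make_record(s, tx=f"NM_{i}") for i, s in enumerate(["TP53", "BRCA1", "MYC"])]
        return SpeciesTable("human", "mammal", recs)

    def test_exact_and_case_insensitive_match(self):
        ref = self._ref()
        mouse = SpeciesTable("mouse", "mammal", [
            make_record("Tp53", species="mouse", tx="NM_10"),
            make_record("MYC", species="mouse", tx="NM_11"),
        ])
        m = match_orthologs([mouse], ref)
        assert m.presence.loc["TP53", "mouse"]
        assert m.presence.loc["MYC", "mouse"]
        assert not m.presence.loc["BRCA1", "mouse"]

    def test_alias_redirects_loc_symbols(self):
        ref = self._ref()
        frog = SpeciesTable("frog", "amphibia", [
            make_record("LOC123", species="frog", clade="amphibia", tx="NM_20"),
        ])
        m = match_orthologs([frog], ref, alias_map={"LOC123": "TP53"})
        assert m.presence.loc["TP53", "frog"]

    def test_unmatched_symbols_reported_not_matched(self):
        ref = self._ref()
        fish = SpeciesTable("gar", "fish", [
            make_record("NOVEL9", species="gar", clade="fish", tx="NM_30"),
        ])
        m = match_orthologs([fish], ref)
        assert not m.presence["gar"].any()
        assert m.unmatched["gar"] == ["NOVEL9"]

    def test_duplicate_after_aliasing_raises(self):
        ref = self._ref()
        sp = SpeciesTable("x", "bird", [
            make_record("TP53", species="x", clade="bird", tx="NM_40"),
            make_record("LOC1", species="x", clade="bird", tx="NM_41"),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            match_orthologs([sp], ref, alias_map={"LOC1": "TP53"})

    def test_alias_target_must_exist(self):
        with pytest.raises(ValueError, match="alias"):
            match_orthologs([], self._ref(), alias_map={"LOC1": "NOPE"})

    def test_alias_map_round_trip(self, tmp_path):
        p = tmp_path / "alias.tsv"
        p.write_text("LOC123\tTP53\nLOC456\tMYC\n")
        assert read_alias_map(p) == {"LOC123": "TP53", "LOC456": "MYC"}


def _matrix(species_clades, presence_rows, symbols=("G1", "G2", "G3")):
    """Build an ortholog matrix through the public API."""
    ref_recs = [make_record(s, tx=f"NM_{i}") for i, s in enumerate(symbols)]
    ref = SpeciesTable("ref", "mammal", ref_recs)
    tables = []
    for sp, clade in species_clades.items():
        recs = [
            make_record(sym, species=sp, clade=clade, tx=f"NM_{sp}{k}")
            for k, sym in enumerate(symbols)
            if presence_rows[sp][symbols.index(sym)]
        ]
        tables.append(SpeciesTable(sp, clade, recs))
    return match_orthologs(tables, ref)


class TestCommonGeneSet:
    def test_basal_clade_rule(self):
        # G1: 1 fish + 1 amphibian -> kept; G2: mammals only -> dropped;
        # G3: everywhere -> kept
        m = _matrix(
            {"gar": "fish", "frog": "amphibia", "mouse": "mammal", "cow": "mammal"},
            {
                "gar": [1, 0, 1],
                "frog": [1, 0, 1],
                "mouse": [0, 1, 1],
                "cow": [0, 1, 1],
            },
        )
        common = build_common_set(m, min_count=2)
        assert common.symbols == ("G1", "G3")

    def test_all_present_everywhere_gives_reference_order(self):
        m = _matrix(
            {"gar": "fish", "frog": "amphibia", "lizard": "non_avian_reptile"},
            {"gar": [1, 1, 1], "frog": [1, 1, 1], "lizard": [1, 1, 1]},
        )
        assert build_common_set(m).symbols == ("G1", "G2", "G3")

    def test_monotone_in_min_count(self):
        m = _matrix(
            {"gar": "fish", "frog": "amphibia", "lizard": "non_avian_reptile"},
            {"gar": [1, 1, 0], "frog": [1, 0, 0], "lizard": [1, 1, 1]},
        )
        sizes = [len(build_common_set(m, min_count=k)) for k in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == 3 and sizes[2] == 1

    def test_min_count_exceeding_group_is_usage_error(self):
        m = _matrix({"gar": "fish"}, {"gar": [1, 1, 1]})
        with pytest.raises(ValueError, match="min_count"):
            build_common_set(m, min_count=5)

    def test_clade_labels_validated(self):
        m = _matrix({"gar": "fish"}, {"gar": [1, 1, 1]})
        with pytest.raises(ValueError, match="clade"):
            build_common_set(m, clade_group=frozenset({"plant"}), min_count=1)


def test_clade_vocabulary_is_the_five_vertebrate_groups():
    assert set(CLADES) == {"fish", "amphibia", "non_avian_reptile", "bird", "mammal"}
    assert BASAL_CLADES < set(CLADES)
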