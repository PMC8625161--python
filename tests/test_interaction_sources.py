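"""Interaction table parsing, key resolution, and cross-source merging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compoundmap import (
    FormatError,
    merge_interactions,
    parse_chembl_table,
    parse_ctd_table,
    resolve_interactions,
)
from compoundmap.interaction_sources import InteractionRecord, classify_compound_key


def write_ctd(path, rows):
    path.write_text(
        "ChemicalName\tCasRN\tGeneSymbol\tInteractionActions\n"
        + "".join(r + "\n" for r in rows)
    )
    return path


def write_chembl(path, rows):
    path.write_text(
        "compound_key\tgene_symbol\ttarget_name\n" + "".join(r + "\n" for r in rows)
    )
    return path


class TestParseCtd:
    def test_skips_rows_with_empty_fields_and_counts_them(self, tmp_path):
        p = write_ctd(tmp_path / "ctd.tsv", [
            "Curcumin\t458-37-7\tCFTR\tbinds",
            "Curcumin\t458-37-7\t\tbinds",       # empty gene -> skip
            "Other\t50-00-0\tHSP90AA1\t",
            "NoCas\t\tCFTR\tbinds",              # empty CAS -> skip
        ])
        result = parse_ctd_table(p)
        assert (result.n_input, len(result.rows), result.n_skipped) == (4, 2, 2)

    def test_missing_casrn_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("ChemicalName\tGeneSymbol\nX\tCFTR\n")
        with pytest.raises(FormatError, match="CasRN"):
            parse_ctd_table(p)

    def test_row_values_preserved_verbatim(self, tmp_path):
        p = write_ctd(tmp_path / "ctd.tsv", ["Curcumin\t458-37-7\tCftr\tbinds"])
        row = parse_ctd_table(p).rows[0]
        assert (row.compound_key, row.gene_symbol) == ("458-37-7", "Cftr")
        assert row.key_kind == "cas" and row.evidence == "binds"

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "ctd.tsv"
        p.write_text(
            "# CTD export\nChemicalName\tCasRN\tGeneSymbol\tInteractionActions\n"
            "X\t50-00-0\tCFTR\tbinds\n"
        )
        assert parse_ctd_table(p).n_input == 1


class TestParseChembl:
    def test_all_valid_lines_pass_through(self, tmp_path):
        p = write_chembl(tmp_path / "c.tsv", [
            f"AAAAAAAAAAAAAA-BBBBBBBBBB-{c}\tG{i}\tt" for i, c in enumerate("NMQRS")
        ])
        assert len(parse_chembl_table(p).rows) == 5

    @pytest.mark.parametrize("key,kind", [
        ("12345", "cid"),
        ("VFLDPWHFBUODDF-FCXRPNKRSA-N", "inchikey"),
        ("not-a-key", None),
        ("12a45", None),
        ("vfldpwhfbuoddf-fcxrpnksra-n", None),  # lowercase is not InChIKey-shaped
    ])
    def test_key_classifier(self, key, kind):
        assert classify_compound_key(key) == kind

    def test_unclassifiable_key_skipped_and_counted(self, tmp_path):
        p = write_chembl(tmp_path / "c.tsv", ["999\tCFTR\t", "junk-key\tCFTR\t"])
        result = parse_chembl_table(p)
        assert (len(result.rows), result.n_skipped) == (1, 1)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("compound_key\tname\n1\tx\n")
        with pytest.raises(FormatError, match="gene_symbol"):
            parse_chembl_table(p)


class TestResolve:
    def test_cas_key_resolves_to_collection_record(self, tmp_path, demo_collection):
        p = write_ctd(tmp_path / "ctd.tsv", ["Curcumin\t458-37-7\tCFTR\tbinds"])
        records, unresolved = resolve_interactions(
            parse_ctd_table(p).rows, demo_collection, "CTD"
        )
        assert len(unresolved) == 0
        assert records == [InteractionRecord("CAND0001", "CFTR", "CTD", "binds")]

    def test_unknown_cas_goes_to_unresolved_report(self, tmp_path, demo_collection):
        p = write_ctd(tmp_path / "ctd.tsv", ["Ghost\t9999999-99-9\tCFTR\t"])
        records, unresolved = resolve_interactions(
            parse_ctd_table(p).rows, demo_collection, "CTD"
        )
        assert records == [] and len(unresolved) == 1
        assert unresolved.entries[0][0] == "9999999-99-9"

    def test_gene_symbols_uppercased_and_trimmed(self, tmp_path, demo_collection):
        p = write_ctd(tmp_path / "ctd.tsv", ["Curcumin\t458-37-7\t  cftr \t"])
        records, _ = resolve_interactions(
            parse_ctd_table(p).rows, demo_collection, "CTD"
        )
        assert records[0].gene_symbol == "CFTR"

    def test_resolved_ids_always_in_collection(self, small_fixture, tmp_path):
        from compoundmap import load_compound_db
        manifest, _ = small_fixture
        coll = load_compound_db(manifest.compounds_csv)
        for parse, path, src in [
            (parse_ctd_table, manifest.ctd_tsv, "CTD"),
            (parse_chembl_table, manifest.chembl_tsv, "CHEMBL"),
        ]:
            records, _ = resolve_interactions(parse(path).rows, coll, src)
            known = {r.compound_id for r in coll.records}
            assert {r.compound_id for r in records} <= known

    def test_count_conservation(self, tmp_path, demo_collection):
        p = write_ctd(tmp_path / "ctd.tsv", [
            "Curcumin\t458-37-7\tCFTR\t",
            "NoGene\t458-37-7\t\t",
            "Ghost\t1111-11-1\tCFTR\t",
        ])
        result = parse_ctd_table(p)
        records, unresolved = resolve_interactions(result.rows, demo_collection, "CTD")
        assert result.n_skipped + len(unresolved) + len(records) == result.n_input


class TestMerge:
    def test_cross_source_duplicate_carries_both_sources(self):
        merged = merge_interactions(
            [InteractionRecord("C1", "CFTR", "CTD")],
            [InteractionRecord("C1", "CFTR", "CHEMBL")],
        )
        assert len(merged) == 1
        rec = merged[0]
        assert rec.source == "CTD"
        assert "CTD" in rec.evidence and "CHEMBL" in rec.evidence

    def test_merge_is_idempotent(self):
        records = [
            InteractionRecord("C1", "A", "CTD"),
            InteractionRecord("C2", "B", "CHEMBL", "ev"),
        ]
        once = merge_interactions(records)
        assert merge_interactions(once) == once
        assert merge_interactions(records, records) == once

    def test_union_of_distinct_pairs(self):
        merged = merge_interactions(
            [InteractionRecord("C1", "A"), InteractionRecord("C1", "B")],
            [InteractionRecord("C2", "A")],
        )
        assert [r.pair for r in merged] == [("C1", "A"), ("C1", "B"), ("C2", "A")]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.sampled_from([f"C{i}" for i in range(8)]),
                      st.sampled_from(list("ABCDEFG"))),
            max_size=60,
        ),
        split=st.integers(min_value=0, max_value=60),
    )
    def test_merge_cardinality_equals_distinct_pair_count(self, pairs, split):
        """|merge output| equals the brute-force pair-set size, any split."""
        records = [InteractionRecord(c, g, "CTD") for c, g in pairs]
        merged = merge_interactions(records[:split], records[split:])
        assert len(merged) == len(set(pairs))
        assert [r.pair for r in merged] == sorted(set(pairs))
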