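"""GenBank feature mining, taxonomy linkage and database bookkeeping."""

import io
import random

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from markerkit.refdb import (
    CombinedDatabase,
    MarkerRecord,
    attach_taxonomy,
    build_database,
    dedupe_assemblies,
    find_16s,
    find_gh48_cds,
    find_identical,
    parse_genbank,
    read_taxonomy,
    summarize,
    translation_consistent,
)


def _record(features, seq, name="LOC1"):
    return SeqRecord(
        Seq(seq),
        id=name,
        name=name,
        annotations={"molecule_type": "DNA", "organism": "Testus testi"},
        features=features,
    )


def _cds(start, end, strand=1, product="glycoside hydrolase family 48 protein", pid="P1.1"):
    return SeqFeature(
        SimpleLocation(start, end, strand=strand),
        type="CDS",
        qualifiers={"product": [product], "protein_id": [pid]},
    )


def _rrna(start, end, strand=1, product="16S ribosomal RNA"):
    return SeqFeature(
        SimpleLocation(start, end, strand=strand),
        type="rRNA",
        qualifiers={"product": [product]},
    )


class TestFeatureSelection:
    def test_gh48_product_selected_gh9_not(self):
        rec = _record(
            [
                _cds(0, 30, product="glycoside hydrolase family 48 protein"),
                _cds(30, 60, product="glycoside hydrolase family 9", pid="P2.1"),
            ],
            "ACGTAA" * 10,
        )
        hits = find_gh48_cds(rec)
        assert len(hits) == 1
        assert hits[0].qualifiers["protein_id"] == ["P1.1"]

    def test_both_annotation_spellings_and_case(self):
        rec = _record(
            [
                _cds(0, 30, product="Glycosyl Hydrolase Family 48"),
                _cds(30, 60, product="cellulase GH48 module", pid="P2.1"),
            ],
            "ACGTAA" * 10,
        )
        assert len(find_gh48_cds(rec)) == 2

    def test_multispecies_excluded(self):
        rec = _record(
            [_cds(0, 30, product="MULTISPECIES: glycoside hydrolase family 48")],
            "ACGTAA" * 5,
        )
        assert find_gh48_cds(rec) == []

    def test_allow_list_rescues_hypothetical(self):
        rec = _record([_cds(0, 30, product="hypothetical protein", pid="WP_1.1")], "ACGTAA" * 5)
        assert find_gh48_cds(rec) == []
        assert len(find_gh48_cds(rec, allow_list=["WP_1.1"])) == 1

    def test_first_of_two_16s_copies_wins(self):
        seq = "A" * 20 + "C" * 20 + "G" * 20
        rec = _record([_rrna(0, 20), _rrna(20, 40)], seq)
        assert find_16s(rec) == "A" * 20

    def test_non_16s_rrna_absent(self):
        rec = _record([_rrna(0, 20, product="23S ribosomal RNA")], "A" * 40)
        assert find_16s(rec) is None

    def test_complement_strand_16s_reverse_complemented(self):
        seq = "AACCGGTTAACCGGTTAACC"
        rec = _record([_rrna(0, 20, strand=-1)], seq)
        assert find_16s(rec) == str(Seq(seq).reverse_complement())


class TestParseGenbank:
    def test_synthetic_records_roundtrip(self, genbank_fixture):
        fixture, path = genbank_fixture
        records = parse_genbank(path)
        assert len(records) == len(fixture.records)
        # every record exposes its CDS and rRNA features with locations
        truth_cds = fixture.truth[fixture.truth.feature == "CDS"]
        assert {r.name for r in records} == set(fixture.truth.locus)
        assert len(truth_cds) == len(fixture.records)

    def test_complement_cds_extraction_matches_truth(self, genbank_fixture):
        fixture, path = genbank_fixture
        truth = fixture.truth
        by_locus = {r.name: r for r in parse_genbank(path)}
        rows = truth[(truth.feature == "CDS") & (truth.strand == -1)]
        assert len(rows) > 0
        for row in rows.itertuples():
            rec = by_locus[row.locus]
            feats = find_gh48_cds(rec, allow_list=fixture.allow_list)
            assert str(feats[0].extract(rec.seq)) == row.sequence

    def test_joined_cds_concatenates_exons(self, genbank_fixture):
        fixture, path = genbank_fixture
        rec = parse_genbank(path)[0]  # record 0 carries the join case
        feats = find_gh48_cds(rec, allow_list=fixture.allow_list)
        row = fixture.truth[
            (fixture.truth.locus == rec.name) & (fixture.truth.feature == "CDS")
        ].iloc[0]
        assert len(feats[0].location.parts) == 2
        assert str(feats[0].extract(rec.seq)) == row.sequence

    def test_missing_file_and_empty_file(self, tmp_path):
        with pytest.raises(Exception):
            parse_genbank(tmp_path / "missing.gb")
        empty = tmp_path / "empty.gb"
        empty.write_text("")
        with pytest.raises(ValueError, match="no GenBank records"):
            parse_genbank(empty)


class TestTaxonomy:
    def test_lineage_attached(self):
        rec = MarkerRecord(
            record_id="r1", txid="42", organism="Hungateiclostridium thermocellum",
            nt_accession="N1", gh48_nt="ATG", protein_accession="P1", gh48_aa="M",
            product="gh48",
        )
        taxmap = {"42": {"domain": "Bacteria", "genus": "Hungateiclostridium"}}
        attach_taxonomy([rec], taxmap)
        assert rec.genus == "Hungateiclostridium"
        assert "no-lineage" not in rec.flags

    def test_unknown_txid_flagged_not_dropped(self):
        rec = MarkerRecord(
            record_id="r1", txid="99", organism="X y", nt_accession="N1",
            gh48_nt="ATG", protein_accession="P1", gh48_aa="M", product="gh48",
        )
        out = attach_taxonomy([rec], {})
        assert len(out) == 1
        assert "no-lineage" in out[0].flags

    def test_malformed_taxonomy_row_names_line(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("txid\tlineage\n1\tBacteria;Bacillota\n2\n")
        with pytest.raises(ValueError, match="line 3"):
            read_taxonomy(path)

    def test_lineage_string_parsing(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("txid\tlineage\n7\tBacteria;Bacillota;Clostridia;Eubacteriales;Oscillospiraceae;Hungateiclostridium\n")
        taxmap = read_taxonomy(path)
        assert taxmap["7"]["genus"] == "Hungateiclostridium"
        assert taxmap["7"]["family"] == "Oscillospiraceae"


def _mk(record_id, organism, assembly_id, level, seq="ATGAAA"):
    return MarkerRecord(
        record_id=record_id, txid="1", organism=organism, nt_accession="N",
        gh48_nt=seq, protein_accession=record_id, gh48_aa="", product="gh48",
        assembly_id=assembly_id, assembly_level=level,
    )


class TestDedupe:
    def test_complete_preferred_over_contig(self):
        recs = [
            _mk("a", "Testus testi DSM 1", "GCF_2", "contig"),
            _mk("b", "Testus testi DSM 1", "GCF_1", "complete"),
        ]
        kept = dedupe_assemblies(recs)
        assert [r.record_id for r in kept] == ["b"]

    def test_different_strains_both_kept(self):
        recs = [
            _mk("a", "Testus testi DSM 1313", "GCF_1", "complete"),
            _mk("b", "Testus testi AD2", "GCF_2", "complete"),
        ]
        assert len(dedupe_assemblies(recs)) == 2

    def test_idempotent_and_single_record_unchanged(self):
        recs = [_mk("a", "Testus testi", "GCF_1", "scaffold")]
        once = dedupe_assemblies(recs)
        assert once == dedupe_assemblies(once)
        assert len(once) == 1

    def test_tie_broken_lexicographically(self):
        recs = [
            _mk("a", "Testus testi", "GCF_B", "complete"),
            _mk("b", "Testus testi", "GCF_A", "complete"),
        ]
        assert [r.record_id for r in dedupe_assemblies(recs)] == ["b"]


class TestIdenticalPairs:
    def test_identical_and_near_identical(self):
        recs = [
            _mk("a", "Testus alpha", "G1", "complete", seq="ATGAAACCC"),
            _mk("b", "Testus alpha", "G2", "complete", seq="ATGAAACCC"),
            _mk("c", "Testus beta", "G3", "complete", seq="ATGAAACCG"),
        ]
        pairs = find_identical(recs, level="module")
        assert pairs == [("a", "b", "same-species")]

    def test_n_identical_gives_all_pairs(self):
        recs = [_mk(f"r{i}", f"Testus sp{i}", f"G{i}", "complete", seq="ATGCCC") for i in range(5)]
        pairs = find_identical(recs, level="module")
        assert len(pairs) == 5 * 4 // 2
        # brute-force oracle
        brute = sum(
            1
            for i in range(5)
            for j in range(i + 1, 5)
            if recs[i].gh48_nt == recs[j].gh48_nt
        )
        assert len(pairs) == brute

    def test_amplicon_level_uses_provided_amplicons(self):
        recs = [
            _mk("a", "Testus alpha", "G1", "complete", seq="ATGAAA"),
            _mk("b", "Genus beta", "G2", "complete", seq="ATGCCC"),
        ]
        pairs = find_identical(recs, level="amplicon", amplicons={"a": "TTT", "b": "TTT"})
        assert pairs == [("a", "b", "cross-genus")]


class TestBuildAndSummarize:
    def test_build_database_from_fixture(self, genbank_fixture):
        fixture, path = genbank_fixture
        db = build_database(
            [path],
            taxonomy=fixture.taxonomy,
            allow_list=fixture.allow_list,
            assembly_info=fixture.assembly_info,
        )
        # duplicate assembly of the first strain collapsed
        assert len(db) == len(fixture.pairs.tips)
        assert all(r.rrna16s for r in db.records)
        assert all(translation_consistent(r) for r in db.records)
        # first-16S rule: extracted copy equals truth copy 0
        truth = fixture.truth
        for rec in db.records:
            locus = rec.assembly_id.replace("GCF_", "")
            row = truth[
                (truth.locus == locus) & (truth.feature == "rRNA") & (truth["copy"] == 0)
            ]
            assert rec.rrna16s == row.iloc[0]["sequence"]

    def test_hypothetical_flag_from_allow_list(self, genbank_fixture):
        fixture, path = genbank_fixture
        db = build_database(
            [path], taxonomy=fixture.taxonomy, allow_list=fixture.allow_list,
            assembly_info=fixture.assembly_info,
        )
        hyp = {r.record_id for r in db.records if "hypothetical" in r.flags}
        assert hyp == set(fixture.allow_list)

    def test_summarize_counts_and_permutation_invariance(self, genbank_fixture):
        fixture, path = genbank_fixture
        db = build_database(
            [path], taxonomy=fixture.taxonomy, allow_list=fixture.allow_list,
            assembly_info=fixture.assembly_info,
        )
        table = summarize(db)
        cfg = fixture.pairs.config
        assert table.loc["n_entries", "value"] == cfg.n_taxa * cfg.strains_per_taxon
        assert table.loc["n_genera", "value"] == cfg.n_taxa
        assert table.loc["n_families", "value"] == cfg.n_taxa
        assert table.loc["pct_with_16s", "value"] == 100.0
        shuffled = CombinedDatabase(records=list(reversed(db.records)))
        assert summarize(shuffled).equals(table)

    def test_summarize_small_fixture(self):
        recs = [
            _mk("a", "Aus alpha", "G1", "complete", seq="A" * 1500),
            _mk("b", "Bus beta", "G2", "complete", seq="A" * 2100),
        ]
        recs[0].rrna16s = "G" * 1500
        table = summarize(CombinedDatabase(records=recs))
        assert table.loc["n_entries", "value"] == 2
        assert table.loc["pct_with_16s", "value"] == 50.0
        assert table.loc["module_nt_min", "value"] == 1500
        assert table.loc["module_nt_mean", "value"] == 1800
        assert table.loc["module_nt_max", "value"] == 2100

    def test_export_import_round_trip(self, genbank_fixture, tmp_path):
        fixture, path = genbank_fixture
        db = build_database(
            [path], taxonomy=fixture.taxonomy, allow_list=fixture.allow_list,
            assembly_info=fixture.assembly_info,
        )
        prefix = tmp_path / "combined"
        db.export(prefix)
        back = CombinedDatabase.from_table(f"{prefix}.tsv")
        assert back.records == db.records
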