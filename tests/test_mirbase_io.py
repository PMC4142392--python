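"""Flat-file dialect parsing, writing and round-trips."""

import io

import pytest

from mirtrack.mirbase_io import (
    ParseError,
    load_release,
    parse_dead_file,
    parse_mature_fasta,
    parse_precursor_flatfile,
    read_batch_queries,
    read_report,
    write_release,
    write_report,
)
from mirtrack.records import snapshots_equal
from mirtrack.synthetic_releases import SimulationParams, simulate_release_series

from conftest import make_snapshot

# Synthetic stand-in for a real stem-loop record block (same dialect shape
# as the public flat file, abbreviated annotation).
DME_MIR_1 = """\
ID   dme-mir-1         standard; RNA; DME; 72 BP.
XX
AC   MI0000116;
XX
DE   Drosophila melanogaster miR-1 stem-loop
XX
RN   [1]
RX   PUBMED; 11679670.
XX
FH   Key             Location/Qualifiers
FH
FT   miRNA           48..69
FT                   /accession="MIMAT0000341"
FT                   /product="dme-miR-1-3p"
FT                   /evidence=experimental
SQ   Sequence 72 BP; 18 A; 18 C; 18 G; 0 T; 18 other;
     acguacguac guacguacgu acguacguac guacguacgu acguacguug gaauguaaag    60
     aaguauggag cg                                                        72
//
"""


class TestPrecursorFlatfile:
    def test_parses_accession_name_and_features(self):
        recs = parse_precursor_flatfile(io.StringIO(DME_MIR_1), "21")
        assert len(recs) == 1
        r = recs[0]
        assert r.accession == "MI0000116"
        assert r.name == "dme-mir-1"
        assert r.species_code == "dme"
        assert r.species_name == "Drosophila melanogaster"
        assert r.length_nt == 72
        (ft,) = r.mature_features
        assert ft.mature_accession == "MIMAT0000341"
        assert ft.product_name == "dme-miR-1-3p"
        assert (ft.start, ft.end) == (48, 69)
        # reference lines retained verbatim, not parsed
        assert any("PUBMED" in line for line in r.references)

    def test_empty_stream_yields_empty_list(self):
        assert parse_precursor_flatfile(io.StringIO(""), "21") == []

    def test_sequence_normalized_t_to_u_upper(self):
        text = DME_MIR_1.replace("acguacguac", "ACGTACGTAC", 1)
        (r,) = parse_precursor_flatfile(io.StringIO(text), "21")
        assert r.sequence.startswith("ACGUACGUAC")
        assert set(r.sequence) <= set("ACGUN")

    @pytest.mark.parametrize("mangle, fragment", [
        (lambda t: t.replace("ID   dme-mir-1         standard; RNA; DME; 72 BP.\nXX\n", ""),
         "missing ID"),
        (lambda t: t[: t.index("SQ")] + "//\n", "missing SQ"),
        (lambda t: t.replace("48..69", "48..999"), "outside sequence"),
    ])
    def test_malformed_blocks_raise_named_errors(self, mangle, fragment):
        with pytest.raises(ParseError, match=fragment):
            parse_precursor_flatfile(io.StringIO(mangle(DME_MIR_1)), "21")

    def test_feature_without_accession_is_tolerated(self):
        text = DME_MIR_1.replace('FT                   /accession="MIMAT0000341"\n', "")
        (r,) = parse_precursor_flatfile(io.StringIO(text), "5.0")
        assert r.mature_features[0].mature_accession is None


class TestMatureFasta:
    def test_header_with_accession(self):
        text = ">rno-miR-125b-2-3p MIMAT0026467 Rattus norvegicus\n" \
               "ACAAGUCAGGCUCUUGGGACCU\n"
        ((name, acc, species, seq),) = parse_mature_fasta(io.StringIO(text))
        assert name == "rno-miR-125b-2-3p"
        assert acc == "MIMAT0026467"
        assert species == "Rattus norvegicus"
        assert seq == "ACAAGUCAGGCUCUUGGGACCU"

    def test_pre_accession_header_and_dna_alphabet(self):
        text = ">cel-let-7 Caenorhabditis elegans\nACAAGTCAGG\n"
        ((name, acc, _sp, seq),) = parse_mature_fasta(io.StringIO(text))
        assert name == "cel-let-7"
        assert acc is None
        assert seq == "ACAAGUCAGG"

    def test_duplicate_accession_rejected(self):
        text = (">a-miR-1 MIMAT0000001 x\nACGU\n"
                ">a-miR-2 MIMAT0000001 x\nACGU\n")
        with pytest.raises(ParseError, match="duplicate"):
            parse_mature_fasta(io.StringIO(text))

    def test_non_nucleotide_body_rejected(self):
        with pytest.raises(ParseError):
            parse_mature_fasta(io.StringIO(">x-miR-1 MIMAT0000001 x\nACGX\n"))


class TestDeadFile:
    def test_forward_pointer_and_plain_deletion(self):
        text = ("AC   MI0009999\nID   hsa-mir-x\nFW   MI0000001\n//\n"
                "AC   MIMAT0000007\n//\n")
        d1, d2 = parse_dead_file(io.StringIO(text))
        assert d1.accession == "MI0009999"
        assert d1.forward_to == "MI0000001"
        assert d1.molecule_type == "precursor"
        assert d2.forward_to is None
        assert d2.molecule_type == "mature"

    def test_block_without_ac_rejected(self):
        with pytest.raises(ParseError, match="missing AC"):
            parse_dead_file(io.StringIO("ID   hsa-mir-x\n//\n"))


class TestRoundTrip:
    def test_write_then_load_is_identity(self, tmp_path, tiny_snapshot):
        write_release(tiny_snapshot, tmp_path)
        warnings = []
        again = load_release(tmp_path, "1.0", warnings_out=warnings)
        assert warnings == []
        assert snapshots_equal(again, tiny_snapshot)

    def test_empty_snapshot_writes_three_valid_files(self, tmp_path):
        from mirtrack.records import ReleaseSnapshot

        write_release(ReleaseSnapshot(release_label="1.0"), tmp_path)
        for fname in ("miRNA.dat", "mature.fa", "miRNA.dead"):
            assert (tmp_path / fname).exists()
        snap = load_release(tmp_path, "1.0")
        assert not snap.precursors and not snap.matures and not snap.dead

    def test_invariant_violation_refuses_to_write(self, tmp_path, tiny_snapshot):
        bad = tiny_snapshot
        bad.precursors["MI0000001"].mature_features[0].end = 9999
        with pytest.raises(Exception):
            write_release(bad, tmp_path)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_randomized_series_round_trips(self, tmp_path, seed):
        params = SimulationParams(n_releases=4, n_initial_precursors=25,
                                  rng_seed=seed, p_merge=0.03, p_delete=0.03)
        dirs, _ = simulate_release_series(params, tmp_path / "series")
        from mirtrack.synthetic_releases import simulate_snapshots

        snaps, _ = simulate_snapshots(params)
        for d, snap in zip(dirs, snaps):
            assert snapshots_equal(load_release(d, d.name), snap)

    def test_mature_fa_line_lengths_bounded(self, tmp_path, tiny_snapshot):
        write_release(tiny_snapshot, tmp_path)
        for line in (tmp_path / "mature.fa").read_text().splitlines():
            assert len(line) <= 80


class TestBatchAndReports:
    def test_header_only_file_is_empty(self):
        assert read_batch_queries(io.StringIO("query\tid_type\n")) == []

    def test_typed_row_parses_with_release_context(self):
        rows = read_batch_queries(io.StringIO(
            "query\tid_type\tmolecule_type\trelease\n"
            "rno-miR-125b-2-3p\tname\tmature\t21\n"
        ))
        (row,) = rows
        assert row.raw_query == "rno-miR-125b-2-3p"
        assert row.id_type == "name"
        assert row.molecule_type == "mature"
        assert row.release_context == "21"

    def test_unknown_id_type_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            read_batch_queries(io.StringIO("query\tid_type\nfoo\tbogus\n"))

    def test_blank_lines_skipped(self):
        rows = read_batch_queries(io.StringIO("query\na\n\nb\n"))
        assert [r.raw_query for r in rows] == ["a", "b"]

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_report_round_trip(self, fmt):
        rows = [
            {"query": f"q{i}", "matched_accession": f"MIMAT{i:07d}",
             "molecule_type": "mature", "status": "current",
             "latest_name": f"hsa-miR-{i}", "latest_sequence": "ACGU" * 5,
             "latest_relations": "", "last_change_release": "1.0", "note": ""}
            for i in range(200)
        ]
        buf = io.StringIO()
        write_report(rows, buf, fmt)
        assert read_report(io.StringIO(buf.getvalue()), fmt) == rows

    def test_write_preserves_opaque_annotation(self, tmp_path):
        snap = make_snapshot()
        snap.precursors["MI0000001"].references = ["RN   [1]", "RX   PUBMED; 1."]
        snap.precursors["MI0000001"].xrefs = ['DR   RFAM; RF00103; mir-1.']
        write_release(snap, tmp_path)
        again = load_release(tmp_path, "1.0")
        assert again.precursors["MI0000001"].references == snap.precursors[
            "MI0000001"].references
        assert again.precursors["MI0000001"].xrefs == snap.precursors[
            "MI0000001"].xrefs
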