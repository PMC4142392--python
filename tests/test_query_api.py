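"""Identifier resolution, history, update and comparison queries."""

import dataclasses

import pytest

from mirtrack.event_store import build_store_from_snapshots
from mirtrack.query_api import (
    batch_update,
    compare_releases,
    history_query,
    resolve_identifier,
    update_query,
)
from mirtrack.records import DeadEntry, MatureRecord, QueryRow

from conftest import make_snapshot


@pytest.fixture(scope="module")
def tiny_store():
    return build_store_from_snapshots([make_snapshot("1.0")])


class TestResolveIdentifier:
    def test_accession_auto_detected(self, tiny_store):
        assert resolve_identifier(tiny_store, "MIMAT0000001") == [
            ("MIMAT0000001", "mature")]
        assert resolve_identifier(tiny_store, "MI0000001") == [
            ("MI0000001", "precursor")]

    def test_sequence_auto_detected(self, tiny_store):
        seq = make_snapshot().matures["MIMAT0000001"].sequence
        hits = resolve_identifier(tiny_store, seq)
        assert ("MIMAT0000001", "mature") in hits

    def test_name_case_insensitive_by_default(self, tiny_store):
        assert resolve_identifier(tiny_store, "HSA-MIR-1-5P") == [
            ("MIMAT0000001", "mature")]
        assert resolve_identifier(tiny_store, "HSA-MIR-1-5P",
                                  case_sensitive=True) == []

    def test_empty_result_is_a_value(self, tiny_store):
        assert resolve_identifier(tiny_store, "no-such-mir") == []

    def test_molecule_type_filter(self, tiny_store):
        # "hsa-mir-1" (precursor) vs arm names; filter precursors only
        hits = resolve_identifier(tiny_store, "hsa-mir-1",
                                  molecule_type="precursor")
        assert hits == [("MI0000001", "precursor")]

    def test_reused_name_returns_both_accessions(self):
        """A name re-issued to a new record resolves to two accessions."""
        a = make_snapshot("1.0")
        b = make_snapshot("2.0")
        old = b.matures.pop("MIMAT0000001")
        b.precursors["MI0000001"].mature_features[0].mature_accession = \
            "MIMAT0000009"
        b.matures["MIMAT0000009"] = MatureRecord(
            name=old.name, sequence=old.sequence[:-2] + "GG",
            accession="MIMAT0000009", parent_precursors=old.parent_precursors)
        b.dead.append(DeadEntry("MIMAT0000001", last_name=old.name))
        store = build_store_from_snapshots([a, b])
        hits = resolve_identifier(store, "hsa-miR-1-5p")
        assert [h[0] for h in hits] == ["MIMAT0000001", "MIMAT0000009"]


class TestHistoryQuery:
    def test_single_release_record_has_one_entry(self, tiny_store):
        (h,) = history_query(tiny_store, "MIMAT0000003")
        assert len(h.timeline) == 1
        assert h.timeline[0][4] == ["ADDED"]
        assert h.current_status == "active"

    def test_unresolvable_identifier_yields_empty(self, tiny_store):
        assert history_query(tiny_store, "zzz-miR-0") == []

    def test_timeline_matches_injected_schedule(self, default_series,
                                                default_store):
        _snaps, log = default_series
        by_acc = {}
        for e in log.events:
            by_acc.setdefault(e.accession, []).append(e)
        # a mature with >= 3 events exercises ordering and status
        acc = max((a for a in by_acc if a.startswith("MIMAT")),
                  key=lambda a: len(by_acc[a]))
        (h,) = history_query(default_store, acc)
        assert [t[0] for t in h.timeline] == [e.release_label
                                              for e in by_acc[acc]]
        for entry, expected in zip(h.timeline, by_acc[acc]):
            assert set(entry[4]) == set(expected.change_types)


class TestUpdateQuery:
    def test_unchanged_record_is_current(self, tiny_store):
        r = update_query(tiny_store, QueryRow("MIMAT0000003"))
        assert r.status == "current"
        assert r.latest_name == "mmu-miR-2"

    def test_unknown_string(self, tiny_store):
        r = update_query(tiny_store, QueryRow("xyz"))
        assert r.status == "unknown"
        assert r.matched_accessions == []

    def test_rename_then_sequence_change_reports_updated_both(self):
        a = make_snapshot("1.0")
        b = make_snapshot("2.0")
        m = b.matures["MIMAT0000003"]
        m.name = "mmu-miR-2-5p"
        b.precursors["MI0000002"].mature_features[0].product_name = m.name
        c = make_snapshot("3.0")
        mc = c.matures["MIMAT0000003"]
        mc.name = "mmu-miR-2-5p"
        p2 = c.precursors["MI0000002"]
        p2.mature_features[0].product_name = mc.name
        base = "G" if p2.sequence[4] != "G" else "C"
        p2.sequence = p2.sequence[:4] + base + p2.sequence[5:]
        mc.sequence = p2.feature_substring(p2.mature_features[0])
        store = build_store_from_snapshots([a, b, c])
        # case-insensitive lookup conflates "mmu-mir-2" (precursor) with
        # "mmu-miR-2" (mature); the molecule type disambiguates
        r = update_query(store, QueryRow("mmu-miR-2", id_type="name",
                                         molecule_type="mature"))
        assert r.status == "updated-both"
        assert r.latest_name == "mmu-miR-2-5p"
        assert r.latest_sequence == mc.sequence

    def test_merge_chases_forward_pointers_transitively(self):
        a = make_snapshot("1.0")
        b = make_snapshot("2.0")
        gone = b.matures.pop("MIMAT0000001")
        b.precursors["MI0000001"].mature_features = \
            b.precursors["MI0000001"].mature_features[1:]
        b.dead.append(DeadEntry("MIMAT0000001", last_name=gone.name,
                                forward_to="MIMAT0000002"))
        c = make_snapshot("3.0")
        for snap_mut in (c,):
            snap_mut.matures.pop("MIMAT0000001")
            snap_mut.precursors["MI0000001"].mature_features = \
                snap_mut.precursors["MI0000001"].mature_features[1:]
        gone2 = c.matures.pop("MIMAT0000002")
        c.precursors["MI0000001"].mature_features = []
        c.dead.append(DeadEntry("MIMAT0000001", last_name=gone.name,
                                forward_to="MIMAT0000002"))
        c.dead.append(DeadEntry("MIMAT0000002", last_name=gone2.name,
                                forward_to="MIMAT0000003"))
        store = build_store_from_snapshots([a, b, c])
        r = update_query(store, QueryRow("MIMAT0000001"))
        assert r.status == "merged"
        assert r.matched_accessions == ["MIMAT0000003"]

    def test_update_is_idempotent(self, default_store):
        latest = default_store.latest_release()
        snap = default_store.reconstruct(latest)
        acc = sorted(snap.matures)[0]
        first = update_query(default_store, QueryRow(acc))
        assert first.status == "current"
        again = update_query(default_store,
                             QueryRow(first.latest_name, id_type="name"))
        assert again.status in {"current", "ambiguous"}
        if again.status == "current":
            assert again.latest_name == first.latest_name

    def test_batch_flags_unknowns_per_row(self, tiny_store):
        rows = [QueryRow("MIMAT0000001"), QueryRow("bogus-name")]
        report = batch_update(tiny_store, rows)
        assert [r["status"] for r in report] == ["current", "unknown"]


class TestCompareReleases:
    def test_self_comparison_all_unchanged(self, default_store):
        label = default_store.releases()[2]
        rep = compare_releases(default_store, label, label)
        s = rep.summary()
        assert s["added"] == s["removed"] == s["changed"] == 0
        assert s["unchanged"] == len(
            default_store.reconstruct(label).matures)

    def test_counts_match_ground_truth_single_transition(self, default_series):
        snaps, log = default_series
        store = build_store_from_snapshots(snaps)
        a, b = snaps[3].release_label, snaps[4].release_label
        rep = compare_releases(store, a, b, molecule_type="mature")
        gt = [e for e in log.events
              if e.release_label == b and e.molecule_type == "mature"]
        assert len(rep.added) == sum(
            1 for e in gt if e.change_types & {"ADDED", "RESURRECTED"})
        assert len(rep.removed_merged) == sum(
            1 for e in gt if "MERGED" in e.change_types)
        assert len(rep.removed_deleted) == sum(
            1 for e in gt if "DELETED" in e.change_types)
        assert len(rep.name_changed) == sum(
            1 for e in gt if "NAME_CHANGE" in e.change_types)
        assert len(rep.sequence_changed) == sum(
            1 for e in gt if "SEQUENCE_CHANGE" in e.change_types)

    def test_added_removed_symmetry(self, default_store):
        rels = default_store.releases()
        fwd = compare_releases(default_store, rels[1], rels[4])
        bwd = compare_releases(default_store, rels[4], rels[1])
        assert fwd.added == bwd.removed
        assert fwd.removed == bwd.added

    def test_partition_accounts_for_every_active_accession(self, default_store):
        rels = default_store.releases()
        rep = compare_releases(default_store, rels[0], rels[-1])
        everything = (rep.added | rep.removed | rep.changed | rep.unchanged)
        active = set(default_store.reconstruct(rels[0]).matures) | set(
            default_store.reconstruct(rels[-1]).matures)
        assert everything == active

    def test_species_filter(self, default_store):
        rels = default_store.releases()
        rep = compare_releases(default_store, rels[0], rels[-1], species="hsa")
        snap = default_store.reconstruct(rels[-1])
        for acc in rep.added | rep.changed | rep.unchanged:
            if acc in snap.matures:
                assert snap.matures[acc].species_code == "hsa"

    def test_unknown_release_lists_registered(self, default_store):
        with pytest.raises(KeyError, match="registered"):
            compare_releases(default_store, "1.0", "42")
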