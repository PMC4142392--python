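"""Change classification, release diffing and retro-accession assignment."""

import dataclasses
import random

import pytest

from mirtrack.diff_engine import (
    assign_retro_accessions,
    classify_change,
    diff_releases,
    empty_snapshot,
    provisional_accession,
    read_overrides,
)
from mirtrack.records import MatureRecord, ReleaseSnapshot, DeadEntry
from mirtrack.synthetic_releases import SimulationParams, simulate_snapshots

from conftest import make_snapshot


class TestClassifyChange:
    def test_identical_records_no_types(self, tiny_snapshot):
        m = tiny_snapshot.matures["MIMAT0000001"]
        assert classify_change(m, m) == set()

    def test_name_only_difference(self, tiny_snapshot):
        m = tiny_snapshot.matures["MIMAT0000001"]
        renamed = dataclasses.replace(m, name="hsa-miR-1a-5p")
        assert classify_change(m, renamed) == {"NAME_CHANGE"}

    def test_agrees_with_field_by_field_comparator(self, tiny_snapshot):
        """Randomized single/multi-field perturbations vs a brute-force oracle."""
        rng = random.Random(5)
        m = tiny_snapshot.matures["MIMAT0000001"]
        perturbations = {
            "NAME_CHANGE": lambda r: dataclasses.replace(r, name=r.name + "x"),
            "SEQUENCE_CHANGE": lambda r: dataclasses.replace(
                r, sequence=r.sequence[:-1] + ("A" if r.sequence[-1] != "A" else "C")),
            "RELATION_CHANGE": lambda r: dataclasses.replace(
                r, parent_precursors=r.parent_precursors + ["MI0009999"]),
        }
        for _ in range(50):
            expected = set(rng.sample(sorted(perturbations),
                                      rng.randint(0, 3)))
            new = m
            for t in expected:
                new = perturbations[t](new)
            # oracle: direct field comparison
            oracle = set()
            if m.name != new.name:
                oracle.add("NAME_CHANGE")
            if m.sequence != new.sequence:
                oracle.add("SEQUENCE_CHANGE")
            if sorted(m.parent_precursors) != sorted(new.parent_precursors):
                oracle.add("RELATION_CHANGE")
            assert classify_change(m, new) == oracle == expected


class TestDiffReleases:
    def test_self_comparison_is_empty(self, tiny_snapshot):
        later = dataclasses.replace(tiny_snapshot, release_label="2.0")
        assert diff_releases(tiny_snapshot, later) == []

    def test_out_of_order_snapshots_rejected(self, tiny_snapshot):
        earlier = dataclasses.replace(tiny_snapshot, release_label="0.5")
        with pytest.raises(ValueError, match="ordinal"):
            diff_releases(tiny_snapshot, earlier)

    def test_first_release_is_all_added(self, tiny_snapshot):
        events = diff_releases(empty_snapshot(), tiny_snapshot)
        assert len(events) == len(tiny_snapshot.precursors) + len(
            tiny_snapshot.matures)
        assert all(e.change_types == {"ADDED"} for e in events)

    def test_injected_events_recovered_exactly(self):
        """Simulated transitions reproduce the injected ground truth 1:1."""
        params = SimulationParams(n_releases=5, n_initial_precursors=30,
                                  rng_seed=13, p_delete=0.04, p_merge=0.03,
                                  p_relink=0.02, p_resurrect=0.1)
        snaps, log = simulate_snapshots(params)
        prev = empty_snapshot()
        got = set()
        for snap in snaps:
            for e in diff_releases(prev, snap):
                got.add((e.release_label, e.accession, e.change_types,
                         e.merge_target or ""))
            prev = snap
        assert got == log.comparable_set()

    def test_reused_name_is_never_a_rename(self):
        """A name moving to a different record yields DELETED + ADDED,
        joined by nothing — identity follows accessions, not names."""
        a = make_snapshot("1.0")
        b = make_snapshot("2.0")
        old = b.matures.pop("MIMAT0000001")
        b.precursors["MI0000001"].mature_features[0].mature_accession = \
            "MIMAT0000009"
        b.matures["MIMAT0000009"] = MatureRecord(
            name=old.name, sequence=old.sequence, accession="MIMAT0000009",
            parent_precursors=old.parent_precursors)
        b.dead.append(DeadEntry("MIMAT0000001", last_name=old.name))
        by_acc = {e.accession: e for e in diff_releases(a, b)}
        assert by_acc["MIMAT0000001"].change_types == {"DELETED"}
        assert by_acc["MIMAT0000009"].change_types == {"ADDED"}
        assert not any("NAME_CHANGE" in e.change_types for e in by_acc.values())

    def test_merge_distinguished_by_forward_pointer(self):
        a = make_snapshot("1.0")
        b = make_snapshot("2.0")
        gone = b.matures.pop("MIMAT0000001")
        b.precursors["MI0000001"].mature_features = \
            b.precursors["MI0000001"].mature_features[1:]
        b.dead.append(DeadEntry("MIMAT0000001", last_name=gone.name,
                                forward_to="MIMAT0000002"))
        (ev,) = [e for e in diff_releases(a, b)
                 if e.accession == "MIMAT0000001"]
        assert ev.change_types == {"MERGED"}
        assert ev.merge_target == "MIMAT0000002"

    def test_deterministic_event_order(self, default_series):
        snaps, _ = default_series
        first = diff_releases(snaps[0], snaps[1])
        second = diff_releases(snaps[0], snaps[1])
        assert first == second
        assert [e.accession for e in first] == sorted(e.accession for e in first)


class TestRetroAccessions:
    def _series(self, **kw):
        params = SimulationParams(n_releases=5, n_initial_precursors=25,
                                  rng_seed=4, accession_epoch=4,
                                  p_delete=0.0, p_merge=0.0, p_resurrect=0.0,
                                  **kw)
        return simulate_snapshots(params)

    @staticmethod
    def _strip(snaps, epoch):
        from mirtrack.synthetic_releases import _strip_mature_accessions

        return [_strip_mature_accessions(s) if i < epoch else s
                for i, s in enumerate(snaps, start=1)]

    def test_name_preserving_records_inherit_via_rule_name(self):
        snaps, _ = self._series(p_rename=0.0)
        stripped = self._strip(snaps, 4)
        retro = assign_retro_accessions(stripped[:3], stripped[3])
        assert set(retro.provenance.values()) == {"rule:name"}
        for (release, lk), acc in retro.entries.items():
            idx = int(release.split(".")[0]) - 1
            assert snaps[idx].matures[acc].local_key() == lk

    def test_renamed_records_fall_through_to_rule_sequence(self):
        snaps, log = self._series(p_rename=0.3, p_seqchange=0.0)
        stripped = self._strip(snaps, 4)
        retro = assign_retro_accessions(stripped[:3], stripped[3])
        rules = set(retro.provenance.values())
        assert "rule:sequence" in rules  # renames at the boundary
        assert "provisional" not in rules
        for (release, lk), acc in retro.entries.items():
            idx = int(release.split(".")[0]) - 1
            assert snaps[idx].matures[acc].local_key() == lk

    def test_record_gone_before_anchor_gets_stable_provisional(self):
        anchor = make_snapshot("6.0")
        old = ReleaseSnapshot(release_label="5.1")
        orphan = MatureRecord(name="xla-miR-99", sequence="A" * 22,
                              accession=None)
        old.matures[orphan.key()] = orphan
        retro = assign_retro_accessions([old], anchor)
        acc = retro.accession_for("5.1", orphan.local_key())
        assert acc.startswith("PROV-")
        assert retro.provenance[("5.1", orphan.local_key())] == "provisional"
        # stable across rebuilds and content-addressed
        assert acc == provisional_accession(*orphan.local_key())

    def test_map_stability_under_unrelated_addition(self):
        anchor = make_snapshot("6.0")
        old = ReleaseSnapshot(release_label="5.1")
        m1 = MatureRecord(name="hsa-miR-1-5p",
                          sequence=anchor.matures["MIMAT0000001"].sequence,
                          accession=None)
        old.matures[m1.key()] = m1
        before = assign_retro_accessions([old], anchor).entries
        extra = MatureRecord(name="dre-miR-77", sequence="G" * 20,
                             accession=None)
        old.matures[extra.key()] = extra
        after = assign_retro_accessions([old], anchor).entries
        for key, acc in before.items():
            assert after[key] == acc

    def test_overrides_take_absolute_precedence(self, tmp_path):
        anchor = make_snapshot("6.0")
        old = ReleaseSnapshot(release_label="5.1")
        m1 = MatureRecord(name="hsa-miR-1-5p",
                          sequence=anchor.matures["MIMAT0000001"].sequence,
                          accession=None)
        old.matures[m1.key()] = m1
        ov_path = tmp_path / "overrides.tsv"
        ov_path.write_text(
            "release\tspecies_code\tname\tsequence\taccession\n"
            f"5.1\thsa\thsa-miR-1-5p\t{m1.sequence}\tMIMAT0000002\n"
        )
        retro = assign_retro_accessions([old], anchor, read_overrides(ov_path))
        assert retro.accession_for("5.1", m1.local_key()) == "MIMAT0000002"
        assert retro.provenance[("5.1", m1.local_key())] == "override"

    def test_override_naming_unknown_accession_rejected(self):
        anchor = make_snapshot("6.0")
        old = ReleaseSnapshot(release_label="5.1")
        with pytest.raises(ValueError, match="absent from the anchor"):
            assign_retro_accessions(
                [old], anchor,
                {("5.1", ("hsa", "hsa-miR-1-5p", "ACGU")): "MIMAT9999999"})
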