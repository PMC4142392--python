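"""The three user-facing queries over an event store.

*History* — the full annotation timeline of one accession; *update* — the
most recent annotation for any name, sequence or accession from any
release (the reannotation workhorse for platform probe lists and outdated
gene lists); *comparison* — which records were added, removed, changed or
unchanged between any two releases.

Identity resolution never guesses: a name query returns every accession
that ever bore the name (names get reused — querying such a name in an
update yields ``ambiguous`` rather than a heuristic pick, and supplying a
``release_context`` disambiguates).  Name matching is case-insensitive by
default ("HSA-MIR-21" finds "hsa-miR-21") with a case-sensitive override.

Comparison reports are computed from *reconstructed snapshots*, not by
summing events, so they stay correct across gaps in the ingested series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .diff_engine import classify_change
from .event_store import EventStore
from .mirbase_io import REPORT_COLUMNS
from .records import QueryRow, normalize_sequence, parse_ordinal

__all__ = [
    "AnnotationHistory",
    "UpdateResult",
    "ComparisonReport",
    "resolve_identifier",
    "history_query",
    "update_query",
    "batch_update",
    "compare_releases",
]

_ACC_RE = re.compile(r"^(MI\d+|MIMAT\d+|PROV-[0-9a-f]+)$", re.IGNORECASE)
_SEQ_RE = re.compile(r"^[ACGUTNacgutn]+$")


@dataclass
class AnnotationHistory:
    """Ordered per-accession timeline of record states and events."""

    accession: str
    molecule_type: str
    # (release_label, name, sequence, relations, change_types)
    timeline: list = field(default_factory=list)
    current_status: str = "active"


@dataclass
class UpdateResult:
    query: QueryRow
    matched_accessions: list = field(default_factory=list)
    status: str = "unknown"  # current | updated-name | updated-sequence |
    #                          updated-both | dead | merged | ambiguous | unknown
    molecule_type: str = ""
    latest_name: str = ""
    latest_sequence: str = ""
    latest_relations: str = ""
    last_change_release: str = ""
    note: str = ""

    def as_report_row(self) -> dict:
        return {
            "query": self.query.raw_query,
            "matched_accession": ";".join(self.matched_accessions),
            "molecule_type": self.molecule_type,
            "status": self.status,
            "latest_name": self.latest_name,
            "latest_sequence": self.latest_sequence,
            "latest_relations": self.latest_relations,
            "last_change_release": self.last_change_release,
            "note": self.note,
        }


@dataclass
class ComparisonReport:
    release_a: str
    release_b: str
    molecule_type: str
    species: str | None = None
    added: set = field(default_factory=set)
    removed_deleted: set = field(default_factory=set)
    removed_merged: set = field(default_factory=set)
    name_changed: set = field(default_factory=set)
    sequence_changed: set = field(default_factory=set)
    relation_changed: set = field(default_factory=set)
    unchanged: set = field(default_factory=set)

    @property
    def removed(self) -> set:
        return self.removed_deleted | self.removed_merged

    @property
    def changed(self) -> set:
        """The single 'changed' bucket: union of the per-field sets."""
        return self.name_changed | self.sequence_changed | self.relation_changed

    def summary(self) -> dict:
        return {
            "added": len(self.added),
            "removed": len(self.removed),
            "removed_deleted": len(self.removed_deleted),
            "removed_merged": len(self.removed_merged),
            "changed": len(self.changed),
            "name_changed": len(self.name_changed),
            "sequence_changed": len(self.sequence_changed),
            "relation_changed": len(self.relation_changed),
            "unchanged": len(self.unchanged),
        }


# ---------------------------------------------------------------------------
# identifier resolution


def resolve_identifier(
    store: EventStore,
    raw: str,
    id_type: str = "auto",
    molecule_type: str = "auto",
    release_context: str | None = None,
    case_sensitive: bool = False,
) -> list[tuple[str, str]]:
    """Resolve a name, sequence or accession to (accession, molecule_type).

    Auto-detection order: accession pattern, then sequence alphabet, then
    name.  Name matches return every accession that bore the name in any
    release (or only in *release_context* when given); sequence matches are
    exact on the normalized string.  An empty result is a value, not an
    error.
    """
    raw = raw.strip()
    if id_type == "auto":
        if _ACC_RE.match(raw):
            id_type = "accession"
        elif _SEQ_RE.match(raw):
            id_type = "sequence"
        else:
            id_type = "name"

    if id_type == "accession":
        acc = raw if raw.startswith("PROV-") else raw.upper()
        hits = []
        if store.accession_known(acc):
            mol = "mature" if acc.startswith(("MIMAT", "PROV-")) else "precursor"
            hits = [(acc, mol)]
    elif id_type == "sequence":
        seq = normalize_sequence(raw)
        if release_context is not None:
            snap = store.reconstruct(release_context)
            hits = sorted(
                [(p.accession, "precursor") for p in snap.precursors.values()
                 if p.sequence == seq]
                + [(m.accession, "mature") for m in snap.matures.values()
                   if m.sequence == seq]
            )
        else:
            hits = store.accessions_bearing_sequence(seq)
    else:
        if release_context is not None:
            snap = store.reconstruct(release_context)

            def match(n):
                return n == raw if case_sensitive else n.lower() == raw.lower()

            hits = sorted(
                [(p.accession, "precursor") for p in snap.precursors.values()
                 if match(p.name)]
                + [(m.accession, "mature") for m in snap.matures.values()
                   if match(m.name)]
            )
        else:
            hits = store.accessions_bearing_name(raw, case_sensitive=case_sensitive)

    if molecule_type != "auto":
        hits = [h for h in hits if h[1] == molecule_type]
    return hits


# ---------------------------------------------------------------------------
# history


def _relations_of(state: dict) -> str:
    if state.get("features") is not None:
        return ";".join(f"{f[0]}:{f[1]}:{f[2]}..{f[3]}" for f in state["features"])
    return ";".join(state.get("parents", []))


def history_query(
    store: EventStore, raw: str, *, id_type: str = "auto",
    molecule_type: str = "auto", release_context: str | None = None,
    case_sensitive: bool = False,
) -> list[AnnotationHistory]:
    """Assemble one annotation history per resolved accession.

    Timeline entries exist exactly at the releases where an event occurred;
    the terminal status follows the last event.
    """
    hits = resolve_identifier(store, raw, id_type, molecule_type,
                              release_context, case_sensitive)
    histories = []
    for acc, mol in hits:
        rows = store.history_rows(acc)
        timeline = []
        last_name = last_seq = ""
        status = "active"
        for ev in rows:
            types = sorted(ev["change_types"])
            state = ev.get("state")
            if state is not None:
                last_name, last_seq = state["name"], state["sequence"]
                timeline.append((ev["release_label"], last_name, last_seq,
                                 _relations_of(state), types))
                status = "active"
            else:
                timeline.append((ev["release_label"], last_name, last_seq,
                                 "", types))
                if "MERGED" in types:
                    fw = store.dead_detail(ev["release_label"], acc)[1]
                    status = f"merged-into:{fw}"
                else:
                    status = "dead"
        histories.append(AnnotationHistory(
            accession=acc, molecule_type=mol, timeline=timeline,
            current_status=status))
    return histories


# ---------------------------------------------------------------------------
# update


def _last_event(store: EventStore, acc: str) -> dict | None:
    rows = store.history_rows(acc)
    return rows[-1] if rows else None


def _chase_forward(store: EventStore, acc: str) -> tuple[str, str]:
    """Follow forward pointers transitively; return (terminal accession,
    'active'|'dead').  Cyclic pointers raise ``ValueError`` naming the cycle."""
    visited = [acc]
    current = acc
    while True:
        last = _last_event(store, current)
        if last is None or not (last["change_types"] & {"DELETED", "MERGED"}):
            return current, "active"
        fw = store.dead_detail(last["release_label"], current)[1]
        if not fw:
            return current, "dead"
        if fw in visited:
            raise ValueError(
                "cyclic forward pointers: " + " -> ".join(visited + [fw]))
        visited.append(fw)
        current = fw


def _state_asof(store: EventStore, acc: str, label: str | None) -> dict | None:
    """Last persisted state of *acc* at or before *label* (or ever)."""
    target = parse_ordinal(label) if label is not None else None
    state = None
    for ev in store.history_rows(acc):
        if target is not None and parse_ordinal(ev["release_label"]) > target:
            break
        if ev.get("state") is not None:
            state = ev
    return state


def update_query(store: EventStore, row: QueryRow) -> UpdateResult:
    """Most up-to-date annotation for one queried identifier.

    The record's state at resolution time (the release context, or the
    latest state that matched the query) is compared with the latest
    release; merged records chase forward pointers transitively and report
    the terminal accession.  Updating an already-latest annotation is
    idempotent (status ``current``).
    """
    hits = resolve_identifier(store, row.raw_query, row.id_type,
                              row.molecule_type, row.release_context)
    result = UpdateResult(query=row,
                          matched_accessions=[a for a, _ in hits])
    if not hits:
        result.status = "unknown"
        result.note = "identifier not found in any release"
        return result
    if len(hits) > 1:
        result.status = "ambiguous"
        result.note = ("multiple records matched; supply a release context "
                       "to disambiguate")
        return result

    acc, mol = hits[0]
    result.molecule_type = mol
    last = _last_event(store, acc)
    result.last_change_release = last["release_label"]

    # state the user is holding: at the release context when given, else the
    # newest state that matched the query string
    if row.release_context is not None:
        ref = _state_asof(store, acc, row.release_context)
    elif row.id_type == "name" or (row.id_type == "auto"
                                   and not _ACC_RE.match(row.raw_query)
                                   and not _SEQ_RE.match(row.raw_query)):
        ref = None
        for ev in store.history_rows(acc):
            st = ev.get("state")
            if st is not None and st["name"].lower() == row.raw_query.lower():
                ref = ev
    elif row.id_type == "sequence" or (row.id_type == "auto"
                                       and _SEQ_RE.match(row.raw_query)):
        seq = normalize_sequence(row.raw_query)
        ref = None
        for ev in store.history_rows(acc):
            st = ev.get("state")
            if st is not None and st["sequence"] == seq:
                ref = ev
    else:
        ref = _state_asof(store, acc, None)

    terminal, terminal_status = _chase_forward(store, acc)
    if terminal_status == "dead":
        result.status = "dead"
        result.matched_accessions = [acc]
        result.note = (f"record removed; forward chain ends dead at {terminal}"
                       if terminal != acc else "record removed from the database")
        return result
    if terminal != acc:
        result.status = "merged"
        result.note = f"merged into {terminal}"
        tstate = _state_asof(store, terminal, None)
        if tstate is not None:
            st = tstate["state"]
            result.latest_name = st["name"]
            result.latest_sequence = st["sequence"]
            result.latest_relations = _relations_of(st)
        result.matched_accessions = [terminal]
        return result

    latest = _state_asof(store, acc, None)
    st = latest["state"]
    result.latest_name = st["name"]
    result.latest_sequence = st["sequence"]
    result.latest_relations = _relations_of(st)
    if ref is None:
        result.status = "current"
        return result
    rst = ref["state"]
    name_diff = rst["name"] != st["name"]
    seq_diff = rst["sequence"] != st["sequence"]
    result.status = ("updated-both" if name_diff and seq_diff
                     else "updated-name" if name_diff
                     else "updated-sequence" if seq_diff
                     else "current")
    return result


def batch_update(store: EventStore, rows: list[QueryRow]) -> list[dict]:
    """Run update queries for a batch; unknowns are flagged per-row, never fatal."""
    report = [update_query(store, row).as_report_row() for row in rows]
    assert all(set(REPORT_COLUMNS) >= set(r) for r in report)
    return report


# ---------------------------------------------------------------------------
# release comparison


def compare_releases(
    store: EventStore,
    release_a: str,
    release_b: str,
    species: str | None = None,
    molecule_type: str = "mature",
) -> ComparisonReport:
    """Compare two releases; direction respected (*a* may be later than *b*).

    Sets are computed from reconstructed snapshots, never by summing
    events.  A record both renamed and sequence-changed appears in both
    ``*_changed`` sets; ``changed`` in summaries is the union.
    """
    store.require_release(release_a)
    store.require_release(release_b)
    snap_a = store.reconstruct(release_a)
    snap_b = store.reconstruct(release_b)

    def active(snap):
        recs = snap.matures if molecule_type == "mature" else snap.precursors
        return {
            acc: r for acc, r in recs.items()
            if species is None or r.species_code == species
        }

    a_recs, b_recs = active(snap_a), active(snap_b)
    b_dead = {d.accession: d for d in snap_b.dead}
    report = ComparisonReport(release_a=release_a, release_b=release_b,
                              molecule_type=molecule_type, species=species)
    report.added = set(b_recs) - set(a_recs)
    for acc in set(a_recs) - set(b_recs):
        d = b_dead.get(acc)
        if d is not None and d.forward_to:
            report.removed_merged.add(acc)
        else:
            report.removed_deleted.add(acc)
    for acc in set(a_recs) & set(b_recs):
        types = classify_change(a_recs[acc], b_recs[acc])
        if "NAME_CHANGE" in types:
            report.name_changed.add(acc)
        if "SEQUENCE_CHANGE" in types:
            report.sequence_changed.add(acc)
        if "RELATION_CHANGE" in types:
            report.relation_changed.add(acc)
        if not types:
            report.unchanged.add(acc)
    return report
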