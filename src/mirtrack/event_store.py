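"""Persist change events and post-change annotation; reconstruct by replay.

The logical schema is two tables — ``CHANGES`` (one row per change type per
accession per release, sharing an ``event_id``) and ``STATES`` (the full
annotation of the record *after* the change) — plus a release registry, the
retro-accession provenance table, and ``DEAD_DETAILS`` (last name, forward
pointer and comment of removed records, which ``CHANGES`` has no columns
for but replay of the cumulative dead list needs).

The engine is sqlite3; the schema, not the engine, is the contract, and
:func:`dump_store` writes every table as sorted TSV so two stores can be
diffed textually.  Replaying all events from the empty state in release-
ordinal order reproduces any ingested release exactly (the module's central
property, exercised by :func:`reconstruct_snapshot`).

Release ordering is numeric on (major, minor) parsed from labels:
``"9.2" < "10.0" < "21"``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
from pathlib import Path

from .diff_engine import (
    ChangeEvent,
    RetroAccessionMap,
    assign_retro_accessions,
    diff_releases,
    empty_snapshot,
    record_from_state,
)
from .records import DeadEntry, ReleaseSnapshot, is_mature_accession, parse_ordinal
from .mirbase_io import load_release

logger = logging.getLogger(__name__)

__all__ = ["EventStore", "build_store", "build_store_from_snapshots",
           "reconstruct_snapshot", "dump_store"]

_SCHEMA = """
CREATE TABLE changes (
    event_id TEXT NOT NULL,
    accession TEXT NOT NULL,
    molecule_type TEXT NOT NULL,
    change_type TEXT NOT NULL,
    release_label TEXT NOT NULL,
    UNIQUE (accession, release_label, change_type)
);
CREATE TABLE states (
    event_id TEXT NOT NULL,
    accession TEXT NOT NULL,
    name TEXT NOT NULL,
    sequence TEXT NOT NULL,
    species_code TEXT NOT NULL,
    relations TEXT NOT NULL,
    release_label TEXT NOT NULL,
    UNIQUE (event_id)
);
CREATE TABLE releases (
    label TEXT PRIMARY KEY,
    major INTEGER NOT NULL,
    minor INTEGER NOT NULL,
    date TEXT,
    position INTEGER NOT NULL
);
CREATE TABLE retro_provenance (
    release_label TEXT NOT NULL,
    species_code TEXT NOT NULL,
    name TEXT NOT NULL,
    sequence TEXT NOT NULL,
    accession TEXT NOT NULL,
    rule TEXT NOT NULL
);
CREATE TABLE dead_details (
    release_label TEXT NOT NULL,
    accession TEXT NOT NULL,
    last_name TEXT NOT NULL,
    forward_to TEXT,
    comment TEXT NOT NULL,
    UNIQUE (release_label, accession)
);
CREATE TABLE manifest (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE INDEX idx_changes_acc ON changes (accession);
CREATE INDEX idx_states_name ON states (name);
CREATE INDEX idx_states_seq ON states (sequence);
"""

TABLES = ("changes", "states", "releases", "retro_provenance",
          "dead_details", "manifest")


class EventStore:
    """sqlite3-backed change-event store."""

    def __init__(self, path: str | Path = ":memory:", *, create: bool = False):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        if create:
            self.conn.executescript(_SCHEMA)
            self.conn.commit()

    @classmethod
    def open(cls, path: str | Path) -> "EventStore":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no store at {path}")
        return cls(p)

    def close(self) -> None:
        self.conn.close()

    # -- registry -----------------------------------------------------------

    def register_release(self, label: str, date: str | None = None) -> None:
        major, minor = parse_ordinal(label)
        cur = self.conn.execute("SELECT MAX(position) FROM releases")
        pos = (cur.fetchone()[0] or 0) + 1
        last = self.conn.execute(
            "SELECT label, major, minor FROM releases ORDER BY position DESC LIMIT 1"
        ).fetchone()
        if last is not None and (major, minor) <= (last[1], last[2]):
            raise ValueError(
                f"release {label} does not follow {last[0]} in ordinal order"
            )
        try:
            self.conn.execute(
                "INSERT INTO releases (label, major, minor, date, position) "
                "VALUES (?,?,?,?,?)", (label, major, minor, date, pos)
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"duplicate release label {label}") from exc

    def releases(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT label FROM releases ORDER BY major, minor")]

    def require_release(self, label: str) -> None:
        if label not in set(self.releases()):
            raise KeyError(
                f"unknown release {label!r}; registered: {', '.join(self.releases())}"
            )

    def latest_release(self) -> str:
        rels = self.releases()
        if not rels:
            raise ValueError("empty store: no releases registered")
        return rels[-1]

    # -- ingest -------------------------------------------------------------

    def insert_events(self, events: list[ChangeEvent]) -> None:
        for e in events:
            for ct in sorted(e.change_types):
                self.conn.execute(
                    "INSERT INTO changes VALUES (?,?,?,?,?)",
                    (e.event_id, e.accession, e.molecule_type, ct, e.release_label),
                )
            if e.post_state is not None:
                s = e.post_state
                relations = {
                    k: v for k, v in s.items()
                    if k not in {"molecule_type", "name", "sequence", "species_code"}
                }
                self.conn.execute(
                    "INSERT INTO states VALUES (?,?,?,?,?,?,?)",
                    (e.event_id, e.accession, s["name"], s["sequence"],
                     s["species_code"], json.dumps(relations, sort_keys=True),
                     e.release_label),
                )

    def record_dead_details(self, release_label: str, dead: list[DeadEntry]) -> None:
        for d in dead:
            self.conn.execute(
                "INSERT OR IGNORE INTO dead_details VALUES (?,?,?,?,?)",
                (release_label, d.accession, d.last_name, d.forward_to, d.comment),
            )

    def record_retro_map(self, retro: RetroAccessionMap) -> None:
        for (release, (sp, name, seq)), acc in sorted(retro.entries.items()):
            rule = retro.provenance[(release, (sp, name, seq))]
            self.conn.execute(
                "INSERT INTO retro_provenance VALUES (?,?,?,?,?,?)",
                (release, sp, name, seq, acc, rule),
            )

    def set_manifest(self, manifest: dict) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO manifest VALUES ('build', ?)",
            (json.dumps(manifest, sort_keys=True),),
        )

    def manifest(self) -> dict:
        row = self.conn.execute(
            "SELECT value FROM manifest WHERE key='build'").fetchone()
        return json.loads(row[0]) if row else {}

    # -- replay -------------------------------------------------------------

    def events_at(self, label: str) -> list[dict]:
        """Grouped events of one release, accession-ordered."""
        rows = self.conn.execute(
            "SELECT event_id, accession, molecule_type, change_type FROM changes "
            "WHERE release_label=? ORDER BY accession, molecule_type, change_type",
            (label,),
        ).fetchall()
        grouped: dict[str, dict] = {}
        for event_id, acc, mol, ct in rows:
            g = grouped.setdefault(event_id, {
                "event_id": event_id, "accession": acc, "molecule_type": mol,
                "change_types": set(), "release_label": label,
            })
            g["change_types"].add(ct)
        for event_id, g in grouped.items():
            srow = self.conn.execute(
                "SELECT name, sequence, species_code, relations FROM states "
                "WHERE event_id=?", (event_id,),
            ).fetchone()
            if srow:
                name, seq, sp, relations = srow
                g["state"] = {
                    "molecule_type": g["molecule_type"], "name": name,
                    "sequence": seq, "species_code": sp,
                    **json.loads(relations),
                }
        return [grouped[k] for k in sorted(grouped)]

    def dead_detail(self, label: str, accession: str) -> tuple[str, str | None, str]:
        row = self.conn.execute(
            "SELECT last_name, forward_to, comment FROM dead_details "
            "WHERE release_label=? AND accession=?", (label, accession),
        ).fetchone()
        return row if row else ("", None, "")

    def reconstruct(self, label: str) -> ReleaseSnapshot:
        self.require_release(label)
        target = parse_ordinal(label)
        precursors, matures = {}, {}
        dead: dict[str, DeadEntry] = {}
        for rel in self.releases():
            if parse_ordinal(rel) > target:
                break
            for ev in self.events_at(rel):
                acc, types = ev["accession"], ev["change_types"]
                active = matures if ev["molecule_type"] == "mature" else precursors
                if types & {"DELETED", "MERGED"}:
                    old = active.pop(acc, None)
                    last_name, fw, comment = self.dead_detail(rel, acc)
                    if not last_name and old is not None:
                        last_name = old.name
                    dead[acc] = DeadEntry(accession=acc, last_name=last_name,
                                          forward_to=fw, comment=comment)
                else:
                    active[acc] = record_from_state(acc, ev["state"])
                    if "RESURRECTED" in types:
                        dead.pop(acc, None)
        return ReleaseSnapshot(
            release_label=label, precursors=precursors, matures=matures,
            dead=sorted(dead.values(), key=lambda d: d.accession),
        )

    # -- lookups used by the query layer ------------------------------------

    def accessions_bearing_name(self, name: str, *,
                                case_sensitive: bool = False) -> list[tuple[str, str]]:
        """Accessions that bore *name* in any release, as (accession, type)."""
        if case_sensitive:
            rows = self.conn.execute(
                "SELECT DISTINCT accession FROM states WHERE name=?", (name,))
        else:
            rows = self.conn.execute(
                "SELECT DISTINCT accession FROM states WHERE name=? COLLATE NOCASE",
                (name,))
        return [(a, "mature" if is_mature_accession(a) else "precursor")
                for (a,) in sorted(rows)]

    def accessions_bearing_sequence(self, sequence: str) -> list[tuple[str, str]]:
        rows = self.conn.execute(
            "SELECT DISTINCT accession FROM states WHERE sequence=?", (sequence,))
        return [(a, "mature" if is_mature_accession(a) else "precursor")
                for (a,) in sorted(rows)]

    def accession_known(self, accession: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM changes WHERE accession=? LIMIT 1", (accession,)
        ).fetchone()
        return row is not None

    def history_rows(self, accession: str) -> list[dict]:
        """All events of one accession in release-ordinal order."""
        out = []
        for rel in self.releases():
            for ev in self.events_at(rel):
                if ev["accession"] == accession:
                    out.append(ev)
        return out


# ---------------------------------------------------------------------------
# building


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_store_from_snapshots(
    snapshots: list[ReleaseSnapshot],
    overrides: dict | None = None,
    store_path: str | Path = ":memory:",
    manifest_extra: dict | None = None,
) -> EventStore:
    """Diff consecutive snapshots and persist the events.

    The first release is diffed against the empty pre-database state (all
    ADDED).  Snapshots with unaccessioned matures (pre-6.0 files) are
    resolved through :func:`assign_retro_accessions` against the earliest
    fully accessioned snapshot, with *overrides* taking precedence.
    """
    snapshots = sorted(snapshots, key=lambda s: s.ordinal)
    labels = [s.release_label for s in snapshots]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate release label in {labels}")

    retro = None
    needs_retro = [s for s in snapshots
                   if any(m.accession is None for m in s.matures.values())]
    if needs_retro:
        anchors = [s for s in snapshots
                   if s not in needs_retro and s.matures]
        if not anchors:
            raise ValueError(
                "all snapshots lack mature accessions: no anchor release "
                "to retro-assign from"
            )
        anchor = anchors[0]
        pre = [s for s in needs_retro if s.ordinal < anchor.ordinal]
        if len(pre) != len(needs_retro):
            raise ValueError("unaccessioned matures after the anchor release")
        retro = assign_retro_accessions(pre, anchor, overrides)
        snapshots = [retro.apply(s) if s in needs_retro else s for s in snapshots]

    path = Path(store_path) if store_path != ":memory:" else None
    if path is not None and path.exists():
        path.unlink()
    store = EventStore(store_path, create=True)
    if retro is not None:
        store.record_retro_map(retro)

    prev = empty_snapshot()
    for i, snap in enumerate(snapshots):
        if i > 0:
            pa, pb = prev.ordinal, snap.ordinal
            if pb[0] - pa[0] > 1:
                logger.info("gap in release series: %s -> %s",
                            prev.release_label, snap.release_label)
        store.register_release(snap.release_label, snap.release_date)
        events = diff_releases(prev, snap)
        store.insert_events(events)
        store.record_dead_details(snap.release_label, snap.dead)
        prev = snap
    manifest = {"releases": labels}
    if manifest_extra:
        manifest.update(manifest_extra)
    store.set_manifest(manifest)
    store.conn.commit()
    return store


def build_store(
    release_directories: list,
    overrides: dict | None = None,
    store_path: str | Path = ":memory:",
) -> EventStore:
    """Load release directories (label = directory basename) and build a store.

    A build manifest with per-file sha256 checksums is recorded; building
    twice from identical inputs yields an identical store dump.
    """
    snapshots = []
    checksums = {}
    for d in release_directories:
        d = Path(d)
        label = d.name
        snapshots.append(load_release(d, label))
        checksums[label] = {
            f.name: _checksum(f)
            for f in sorted(d.iterdir())
            if f.name in {"miRNA.dat", "mature.fa", "miRNA.dead"}
        }
    return build_store_from_snapshots(
        snapshots, overrides, store_path, manifest_extra={"checksums": checksums}
    )


def reconstruct_snapshot(store: EventStore, release_label: str) -> ReleaseSnapshot:
    """Replay all events up to *release_label* from the empty state."""
    return store.reconstruct(release_label)


def dump_store(store: EventStore, directory) -> None:
    """Dump every table as sorted TSV for textual diffing."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table in TABLES:
        cur = store.conn.execute(f"SELECT * FROM {table}")
        cols = [c[0] for c in cur.description]
        rows = sorted(tuple("" if v is None else str(v) for v in r)
                      for r in cur.fetchall())
        with open(directory / f"{table}.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
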