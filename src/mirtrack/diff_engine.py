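"""Reconcile records across consecutive releases into typed change events.

Identity follows accession numbers, never names: a name that disappears
from one record and reappears on another (the ``hsa-miR-34b`` hazard) is a
DELETED/MERGED plus an ADDED event, not a rename.  The change taxonomy:

ADDED
    accession appears for the first time.
RESURRECTED
    accession returns after having been in the cumulative dead list.
NAME_CHANGE / SEQUENCE_CHANGE
    the obvious field changes (sequences compared after normalization).
RELATION_CHANGE
    the record's linkage changed — for matures, the parent-precursor
    accession set; for precursors, the annotated feature list (mature
    accession, product name, 1-based span, evidence).
DELETED / MERGED
    accession leaves the active set; MERGED iff the dead file carries a
    forward pointer, which becomes ``merge_target``.

Mature accessions exist only from release 6.0; :func:`assign_retro_accessions`
propagates canonical accessions backwards through older releases by a
name → sequence → overlap rule cascade, with an explicit override table
taking absolute precedence and content-addressed ``PROV-`` accessions
guaranteeing every record an identifier.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

from .records import (
    DeadEntry,
    MatureFeature,
    MatureRecord,
    PrecursorRecord,
    ReleaseSnapshot,
)

__all__ = [
    "ChangeEvent",
    "RetroAccessionMap",
    "CHANGE_TYPES",
    "classify_change",
    "diff_releases",
    "assign_retro_accessions",
    "read_overrides",
    "empty_snapshot",
    "record_state",
    "record_from_state",
]

CHANGE_TYPES = (
    "ADDED",
    "NAME_CHANGE",
    "SEQUENCE_CHANGE",
    "RELATION_CHANGE",
    "DELETED",
    "MERGED",
    "RESURRECTED",
)


@dataclass(frozen=True)
class ChangeEvent:
    """All classified changes of one accession at one release transition."""

    event_id: str
    accession: str
    molecule_type: str  # "precursor" | "mature"
    release_label: str
    change_types: frozenset
    merge_target: str | None = None
    post_state: dict | None = None

    def __post_init__(self):
        if not self.change_types:
            raise ValueError("change_types must be non-empty")
        unknown = set(self.change_types) - set(CHANGE_TYPES)
        if unknown:
            raise ValueError(f"unknown change types {unknown}")
        if ("MERGED" in self.change_types) != (self.merge_target is not None):
            raise ValueError("merge_target required iff MERGED")
        if self.change_types & {"DELETED", "MERGED"}:
            if self.post_state is not None:
                raise ValueError("DELETED/MERGED events carry no post_state")
        elif self.post_state is None:
            raise ValueError("non-terminal events require a post_state")


# ---------------------------------------------------------------------------
# record state serialization (shared with the event store)


def record_state(rec) -> dict:
    """Serializable post-change annotation of a record."""
    if isinstance(rec, PrecursorRecord):
        return {
            "molecule_type": "precursor",
            "name": rec.name,
            "sequence": rec.sequence,
            "species_code": rec.species_code,
            "description": rec.description,
            "species_name": rec.species_name,
            "features": [
                [ft.mature_accession, ft.product_name, ft.start, ft.end, ft.evidence]
                for ft in rec.mature_features
            ],
        }
    return {
        "molecule_type": "mature",
        "name": rec.name,
        "sequence": rec.sequence,
        "species_code": rec.species_code,
        "parents": sorted(rec.parent_precursors),
    }


def record_from_state(accession: str, state: dict):
    if state["molecule_type"] == "precursor":
        return PrecursorRecord(
            accession=accession,
            name=state["name"],
            sequence=state["sequence"],
            description=state.get("description", ""),
            species_name=state.get("species_name", ""),
            mature_features=[
                MatureFeature(
                    mature_accession=f[0], product_name=f[1], start=f[2],
                    end=f[3], evidence=f[4],
                )
                for f in state["features"]
            ],
        )
    return MatureRecord(
        accession=accession,
        name=state["name"],
        sequence=state["sequence"],
        parent_precursors=list(state.get("parents", [])),
    )


# ---------------------------------------------------------------------------
# change classification


def classify_change(old, new) -> set[str]:
    """Change types between two states of the *same* accession.

    Identical records yield the empty set (no event).
    """
    types: set[str] = set()
    if old.name != new.name:
        types.add("NAME_CHANGE")
    if old.sequence != new.sequence:
        types.add("SEQUENCE_CHANGE")
    if isinstance(old, PrecursorRecord):
        old_rel = [(ft.mature_accession, ft.product_name, ft.start, ft.end, ft.evidence)
                   for ft in old.mature_features]
        new_rel = [(ft.mature_accession, ft.product_name, ft.start, ft.end, ft.evidence)
                   for ft in new.mature_features]
        if sorted(old_rel, key=repr) != sorted(new_rel, key=repr):
            types.add("RELATION_CHANGE")
    else:
        if sorted(old.parent_precursors) != sorted(new.parent_precursors):
            types.add("RELATION_CHANGE")
    return types


def empty_snapshot(label: str = "0") -> ReleaseSnapshot:
    """The pre-database state against which the first release is diffed."""
    return ReleaseSnapshot(release_label=label)


def diff_releases(prev: ReleaseSnapshot, next: ReleaseSnapshot) -> list[ChangeEvent]:
    """Classify every annotation change between two consecutive releases.

    Both snapshots must already use canonical accessions (retro-assignment
    applied).  Events are emitted in deterministic accession-lexicographic
    order; unchanged records produce no event.
    """
    if prev.ordinal >= next.ordinal:
        raise ValueError(
            f"snapshots out of ordinal order: {prev.release_label!r} !< "
            f"{next.release_label!r}"
        )
    prev_dead = {d.accession for d in prev.dead}
    next_dead = {d.accession: d for d in next.dead}
    label = next.release_label
    events: list[ChangeEvent] = []

    for mol, prev_map, next_map in (
        ("precursor", prev.precursors, next.precursors),
        ("mature", prev.matures, next.matures),
    ):
        for acc in sorted(set(prev_map) | set(next_map)):
            in_prev, in_next = acc in prev_map, acc in next_map
            if in_next and not in_prev:
                ctype = "RESURRECTED" if acc in prev_dead else "ADDED"
                events.append(ChangeEvent(
                    event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                    release_label=label, change_types=frozenset({ctype}),
                    post_state=record_state(next_map[acc]),
                ))
            elif in_prev and not in_next:
                d = next_dead.get(acc)
                if d is not None and d.forward_to:
                    events.append(ChangeEvent(
                        event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                        release_label=label, change_types=frozenset({"MERGED"}),
                        merge_target=d.forward_to,
                    ))
                else:
                    events.append(ChangeEvent(
                        event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                        release_label=label, change_types=frozenset({"DELETED"}),
                    ))
            else:
                types = classify_change(prev_map[acc], next_map[acc])
                if types:
                    events.append(ChangeEvent(
                        event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                        release_label=label, change_types=frozenset(types),
                        post_state=record_state(next_map[acc]),
                    ))

    # Dead-file entries never seen active in prev (first ingested release
    # already shipping a miRNA.dead, or an add+delete inside a series gap):
    # emit their terminal event here so replay reproduces the dead list.
    covered = {e.accession for e in events}
    for acc in sorted(next_dead):
        if acc in covered or acc in prev_dead or acc in next.precursors \
                or acc in next.matures:
            continue
        d = next_dead[acc]
        mol = d.molecule_type
        if d.forward_to:
            events.append(ChangeEvent(
                event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                release_label=label, change_types=frozenset({"MERGED"}),
                merge_target=d.forward_to,
            ))
        else:
            events.append(ChangeEvent(
                event_id=f"{label}:{acc}", accession=acc, molecule_type=mol,
                release_label=label, change_types=frozenset({"DELETED"}),
            ))
    events.sort(key=lambda e: (e.accession, e.molecule_type))
    return events


# ---------------------------------------------------------------------------
# retro-accession assignment (pre-6.0 mature records)

_OVERLAP_MIN = 16  # contiguous shared nucleotides required by rule 3


@dataclass
class RetroAccessionMap:
    """(release, species+name+sequence) → canonical accession, with provenance.

    Provenance per entry is one of ``rule:name``, ``rule:sequence``,
    ``rule:overlap``, ``override``, ``provisional``.
    """

    entries: dict = field(default_factory=dict)    # (release, (sp, name, seq)) -> acc
    provenance: dict = field(default_factory=dict)

    def accession_for(self, release_label: str, local_key) -> str | None:
        return self.entries.get((release_label, tuple(local_key)))

    def apply(self, snapshot: ReleaseSnapshot) -> ReleaseSnapshot:
        """Return a copy of *snapshot* with mature accessions filled in."""
        new_matures: dict[str, MatureRecord] = {}
        name_seq_to_acc: dict[tuple[str, str], str] = {}
        for m in snapshot.matures.values():
            if m.accession is not None:
                rec = m
            else:
                acc = self.accession_for(snapshot.release_label, m.local_key())
                if acc is None:
                    raise KeyError(
                        f"no retro accession for {m.local_key()} in "
                        f"{snapshot.release_label}"
                    )
                rec = replace(m, accession=acc)
            new_matures[rec.key()] = rec
            name_seq_to_acc[(rec.name, rec.sequence)] = rec.accession
        new_precursors: dict[str, PrecursorRecord] = {}
        for p in snapshot.precursors.values():
            fts = []
            for ft in p.mature_features:
                if ft.mature_accession is None:
                    acc = name_seq_to_acc.get(
                        (ft.product_name, p.feature_substring(ft))
                    ) or next(
                        (a for (n, _s), a in name_seq_to_acc.items()
                         if n == ft.product_name), None,
                    )
                    ft = replace(ft, mature_accession=acc)
                fts.append(ft)
            new_precursors[p.accession] = replace(p, mature_features=fts)
        return replace(snapshot, precursors=new_precursors, matures=new_matures)


def _levenshtein(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _shares_overlap(a: str, b: str) -> bool:
    """Containment, or a common contiguous substring of >= 16 nt."""
    if a in b or b in a:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < _OVERLAP_MIN:
        return False
    return any(
        short[i : i + _OVERLAP_MIN] in long_
        for i in range(len(short) - _OVERLAP_MIN + 1)
    )


def provisional_accession(species: str, name: str, sequence: str) -> str:
    digest = hashlib.sha1(f"{species}|{name}|{sequence}".encode()).hexdigest()
    return f"PROV-{digest[:7]}"


def read_overrides(stream) -> dict:
    """Read an override TSV (columns release, species_code, name, sequence,
    accession) into the mapping consumed by :func:`assign_retro_accessions`."""
    from .mirbase_io import _as_text_handle

    handle = _as_text_handle(stream)
    lines = handle.read().splitlines()
    overrides: dict = {}
    for line in lines:
        if not line.strip() or line.startswith("release\t") or line.startswith("#"):
            continue
        release, species, name, seq, acc = line.split("\t")[:5]
        overrides[(release, (species, name, seq))] = acc
    return overrides


def assign_retro_accessions(
    snapshots_pre6: list[ReleaseSnapshot],
    anchor: ReleaseSnapshot,
    overrides: dict | None = None,
) -> RetroAccessionMap:
    """Propagate canonical mature accessions backwards from the anchor release.

    Walking from the release nearest the anchor to the oldest, each
    unaccessioned mature is matched against the nearer (already canonical)
    release by cascade: (1) exact species+name, (2) exact sequence within
    species, (3) maximal sequence overlap (containment or >= 16 shared
    contiguous nt), ties broken by name edit distance then lexicographic
    name.  Explicit overrides are applied first and take absolute
    precedence; unmatched records get stable content-addressed ``PROV-``
    accessions, so the map is total.  Assignment is injective per release:
    an accession claimed by an earlier-sorted record falls through to the
    next rule for later ones.
    """
    overrides = overrides or {}
    known_accessions = {m.accession for m in anchor.matures.values()} | {
        d.accession for d in anchor.dead
    }
    for key, acc in overrides.items():
        if acc not in known_accessions and not acc.startswith("PROV-"):
            raise ValueError(
                f"override {key} names accession {acc} absent from the anchor"
            )

    result = RetroAccessionMap()
    # primary pool: the immediately-nearer release, already canonical
    nearer = [
        (m.species_code, m.name, m.sequence, m.accession)
        for m in anchor.matures.values()
    ]
    # fallback pool: records that are dead at the anchor (known only by
    # accession + last name from the cumulative dead file) plus every
    # assignment made at later backward steps — lets a record that
    # disappeared before the anchor, or across a dead interval, still reach
    # its canonical accession instead of leaking a provisional one.
    fallback: list[tuple[str, str, str | None, str]] = sorted({
        (d.last_name.split("-", 1)[0], d.last_name, None, d.accession)
        for snap in [anchor, *snapshots_pre6]
        for d in snap.dead
        if d.molecule_type == "mature" and d.last_name
    })

    def cascade(pool, sp, name, seq, used):
        by_name = sorted(a for s_, n_, _q, a in pool
                         if s_ == sp and n_ == name and a not in used)
        if by_name:
            return by_name[0], "rule:name"
        by_seq = sorted(a for s_, _n, q, a in pool
                        if s_ == sp and q == seq and a not in used)
        if by_seq:
            return by_seq[0], "rule:sequence"
        cands = [(n_, q, a) for s_, n_, q, a in pool
                 if s_ == sp and q is not None and a not in used
                 and _shares_overlap(seq, q)]
        if cands:
            cands.sort(key=lambda t: (_levenshtein(name, t[0]), t[0], t[2]))
            return cands[0][2], "rule:overlap"
        return None, None

    for snap in sorted(snapshots_pre6, key=lambda s: s.ordinal, reverse=True):
        used: set[str] = set()
        assigned: list[tuple[tuple[str, str, str], str]] = []
        records = sorted(
            (m for m in snap.matures.values()), key=lambda m: m.local_key()
        )
        # overrides first: absolute precedence
        pending = []
        for m in records:
            lk = m.local_key()
            if m.accession is not None:
                used.add(m.accession)
                assigned.append((lk, m.accession))
                continue
            ov = overrides.get((snap.release_label, lk))
            if ov is not None:
                if ov in used:
                    raise ValueError(
                        f"override collision on {ov} in {snap.release_label}"
                    )
                used.add(ov)
                result.entries[(snap.release_label, lk)] = ov
                result.provenance[(snap.release_label, lk)] = "override"
                assigned.append((lk, ov))
            else:
                pending.append(m)

        for m in pending:
            sp, name, seq = lk = m.local_key()
            acc, prov = cascade(nearer, sp, name, seq, used)
            if acc is None:
                acc, prov = cascade(fallback, sp, name, seq, used)
            if acc is None:
                acc, prov = provisional_accession(sp, name, seq), "provisional"
            used.add(acc)
            result.entries[(snap.release_label, lk)] = acc
            result.provenance[(snap.release_label, lk)] = prov
            assigned.append((lk, acc))

        for (sp, name, seq), acc in assigned:
            fallback.append((sp, name, seq, acc))
        fallback = sorted(set(fallback), key=lambda t: (t[0], t[1], t[3]))
        nearer = [(sp, name, seq, acc) for (sp, name, seq), acc in assigned]
    return result
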