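"""Domain types for miRBase release tracking.

A *precursor* (stem-loop) record carries an ``MI``-prefixed accession and one
or two mature products excised from it; a *mature* record carries a
``MIMAT``-prefixed accession (introduced only in release 6.0 — earlier
releases need retro-assignment, see :mod:`mirtrack.diff_engine`).  A
:class:`ReleaseSnapshot` is the complete annotation state of one release.

Coordinates on precursor features are 1-based inclusive, as in the flat-file
dialect.  Sequences are normalized to uppercase RNA (``T`` → ``U``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "MatureFeature",
    "PrecursorRecord",
    "MatureRecord",
    "DeadEntry",
    "ReleaseSnapshot",
    "QueryRow",
    "normalize_sequence",
    "species_code_of",
    "parse_ordinal",
    "InvariantError",
]

_SEQ_RE = re.compile(r"^[ACGUN]+$")
_PREC_ACC_RE = re.compile(r"^MI\d{7}$")
_MAT_ACC_RE = re.compile(r"^MIMAT\d{7}$")
_PROV_ACC_RE = re.compile(r"^PROV-[0-9a-f]{7}$")


class InvariantError(ValueError):
    """A record or snapshot violates one of its structural invariants."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert DNA to RNA (T→U); whitespace stripped."""
    s = "".join(seq.split()).upper().replace("T", "U")
    if s and not _SEQ_RE.match(s):
        bad = sorted(set(s) - set("ACGUN"))
        raise InvariantError(f"sequence contains non-[ACGUN] characters: {bad}")
    return s


def species_code_of(name: str) -> str:
    """The 3–4 letter species prefix of a miRBase name (``dme-mir-1`` → ``dme``)."""
    return name.split("-", 1)[0] if "-" in name else ""


def parse_ordinal(label: str) -> tuple[int, int]:
    """Numeric (major, minor) ordering of release labels.

    ``"9.2" < "10.0" < "21"`` numerically; lexicographic ordering of labels
    is wrong and deliberately not used.
    """
    m = re.match(r"^(\d+)(?:\.(\d+))?$", label.strip())
    if not m:
        raise ValueError(f"unparseable release label: {label!r}")
    return int(m.group(1)), int(m.group(2) or 0)


def is_mature_accession(acc: str) -> bool:
    return bool(_MAT_ACC_RE.match(acc) or _PROV_ACC_RE.match(acc))


def is_precursor_accession(acc: str) -> bool:
    return bool(_PREC_ACC_RE.match(acc))


@dataclass
class MatureFeature:
    """One ``FT miRNA`` feature of a precursor: where a mature is excised.

    ``mature_accession`` is ``None`` in releases before 6.0 (resolved later
    by retro-assignment); ``start``/``end`` are 1-based inclusive.
    """

    product_name: str
    start: int
    end: int
    mature_accession: str | None = None
    evidence: str = ""

    def key(self) -> tuple:
        return (self.mature_accession, self.product_name, self.start, self.end)


@dataclass
class PrecursorRecord:
    accession: str
    name: str
    sequence: str
    description: str = ""
    species_name: str = ""
    mature_features: list[MatureFeature] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)

    @property
    def species_code(self) -> str:
        return species_code_of(self.name)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not is_precursor_accession(self.accession):
            raise InvariantError(f"bad precursor accession {self.accession!r}")
        if not _SEQ_RE.match(self.sequence or ""):
            raise InvariantError(f"{self.accession}: empty or non-RNA sequence")
        for ft in self.mature_features:
            if not (1 <= ft.start <= ft.end <= self.length_nt):
                raise InvariantError(
                    f"{self.accession}: feature {ft.product_name} span "
                    f"{ft.start}..{ft.end} outside 1..{self.length_nt}"
                )

    def feature_substring(self, ft: MatureFeature) -> str:
        return self.sequence[ft.start - 1 : ft.end]


@dataclass
class MatureRecord:
    """A mature miRNA in one release.

    ``accession`` may be ``None`` for releases before 6.0; such records are
    keyed locally by (species, name, sequence) until retro-assignment.
    """

    name: str
    sequence: str
    accession: str | None = None
    parent_precursors: list[str] = field(default_factory=list)

    @property
    def species_code(self) -> str:
        return species_code_of(self.name)

    def key(self) -> str:
        if self.accession is not None:
            return self.accession
        return f"UNACC:{self.species_code}|{self.name}|{self.sequence}"

    def local_key(self) -> tuple[str, str, str]:
        """(species_code, name, sequence) — the retro-assignment join key."""
        return (self.species_code, self.name, self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise InvariantError(f"mature {self.name!r}: empty sequence")
        if not _SEQ_RE.match(self.sequence):
            raise InvariantError(f"mature {self.name!r}: non-RNA sequence")
        if self.accession is not None and not is_mature_accession(self.accession):
            raise InvariantError(f"bad mature accession {self.accession!r}")


@dataclass
class DeadEntry:
    accession: str
    last_name: str = ""
    forward_to: str | None = None
    comment: str = ""

    @property
    def molecule_type(self) -> str:
        return "mature" if self.accession.startswith(("MIMAT", "PROV-")) else "precursor"

    def validate(self) -> None:
        if self.forward_to is not None and self.forward_to == self.accession:
            raise InvariantError(f"dead entry {self.accession} forwards to itself")


@dataclass
class ReleaseSnapshot:
    """The complete annotation state of one miRBase release.

    ``dead`` is cumulative up to this release and contains only entries that
    are currently dead (a resurrected accession is removed from it).
    """

    release_label: str
    precursors: dict[str, PrecursorRecord] = field(default_factory=dict)
    matures: dict[str, MatureRecord] = field(default_factory=dict)
    dead: list[DeadEntry] = field(default_factory=list)
    release_date: str | None = None

    @property
    def ordinal(self) -> tuple[int, int]:
        return parse_ordinal(self.release_label)

    def validate(self) -> None:
        dead_accs = {d.accession for d in self.dead}
        for acc, p in self.precursors.items():
            if acc != p.accession:
                raise InvariantError(f"precursor map key {acc} != accession {p.accession}")
            p.validate()
            if acc in dead_accs:
                raise InvariantError(f"{acc} both active and dead in {self.release_label}")
        for key, m in self.matures.items():
            if key != m.key():
                raise InvariantError(f"mature map key {key} != record key {m.key()}")
            m.validate()
            if m.accession in dead_accs:
                raise InvariantError(
                    f"{m.accession} both active and dead in {self.release_label}"
                )
            for pacc in m.parent_precursors:
                if pacc not in self.precursors:
                    raise InvariantError(
                        f"mature {m.name}: parent {pacc} missing from snapshot"
                    )
        for d in self.dead:
            d.validate()

    def mature_by_accession(self, accession: str) -> MatureRecord | None:
        return self.matures.get(accession)


@dataclass
class QueryRow:
    """One line of a batch reannotation query."""

    raw_query: str
    id_type: str = "auto"  # name | accession | sequence | auto
    molecule_type: str = "auto"  # mature | precursor | auto
    release_context: str | None = None

    def __post_init__(self) -> None:
        self.raw_query = self.raw_query.strip()
        if not self.raw_query:
            raise InvariantError("empty query string")
        if self.id_type not in {"name", "accession", "sequence", "auto"}:
            raise InvariantError(f"unknown id_type {self.id_type!r}")
        if self.molecule_type not in {"mature", "precursor", "auto"}:
            raise InvariantError(f"unknown molecule_type {self.molecule_type!r}")


def snapshots_equal(
    a: ReleaseSnapshot, b: ReleaseSnapshot, *, include_opaque: bool = True
) -> bool:
    """Field-for-field snapshot equality.

    With ``include_opaque=False``, verbatim-retained annotation (xrefs,
    literature references, dead-entry comments) is excluded — the equality
    used for event-store reconstruction, which does not persist opaque text.
    """
    if a.release_label != b.release_label:
        return False
    if set(a.precursors) != set(b.precursors) or set(a.matures) != set(b.matures):
        return False
    for acc, pa in a.precursors.items():
        pb = b.precursors[acc]
        if not include_opaque:
            pa = replace(pa, xrefs=[], references=[])
            pb = replace(pb, xrefs=[], references=[])
        if pa != pb:
            return False
    for key, ma in a.matures.items():
        mb = b.matures[key]
        if ma.name != mb.name or ma.sequence != mb.sequence:
            return False
        if sorted(ma.parent_precursors) != sorted(mb.parent_precursors):
            return False
    def dead_view(s: ReleaseSnapshot):
        return sorted(
            (d.accession, d.last_name, d.forward_to, d.comment if include_opaque else "")
            for d in s.dead
        )
    return dead_view(a) == dead_view(b)
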