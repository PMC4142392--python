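"""Readers and writers for the three miRBase release file dialects.

A miRBase release ships three plain-text files:

``miRNA.dat``
    EMBL-style flat file of precursor (stem-loop) records.  ``ID``/``AC``/
    ``DE`` header lines, ``FT miRNA`` features locating the mature products
    (1-based inclusive coordinates, ``/product`` and — from release 6.0 —
    ``/accession`` qualifiers), and an ``SQ`` sequence block; records are
    delimited by ``//``.
``mature.fa``
    FASTA of mature sequences, headers ``>name [accession] species words``;
    the accession token is recognized by its ``MIMAT`` (or provisional
    ``PROV-``) prefix and may be absent in releases before 6.0.
``miRNA.dead``
    Entries removed from the database: ``AC``/``ID``/``FW``/``CO`` line
    blocks delimited by ``//``; ``FW`` points to the surviving accession
    when the record was merged rather than simply deleted.

Parsing is tolerant of the dialect drift across old releases: required
fields are ``ID``/``AC``/``SQ`` for precursors and the header name for
matures; every unrecognized line is retained verbatim (never an error) so
that records round-trip through :func:`write_release`.
"""

from __future__ import annotations

import io
import json
import logging
import re
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .records import (
    DeadEntry,
    InvariantError,
    MatureFeature,
    MatureRecord,
    PrecursorRecord,
    QueryRow,
    ReleaseSnapshot,
    normalize_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "parse_precursor_flatfile",
    "parse_mature_fasta",
    "parse_dead_file",
    "load_release",
    "write_release",
    "read_batch_queries",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


class ParseError(ValueError):
    """Malformed release file; message names the record and line number."""


def _as_text_handle(stream) -> IO[str]:
    if isinstance(stream, (str, Path)):
        return open(stream, "r", encoding="utf-8")
    if isinstance(stream, bytes):
        return io.StringIO(stream.decode("utf-8"))
    if hasattr(stream, "read"):
        data = stream.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        return io.StringIO(data)
    raise TypeError(f"cannot read from {type(stream)!r}")


# ---------------------------------------------------------------------------
# miRNA.dat

_FT_FEATURE_RE = re.compile(r"^FT\s{3}(\S+)\s+(?:<?(\d+)\.\.>?(\d+))\s*$")
_FT_QUAL_RE = re.compile(r'^FT\s{10,}/(\w+)=?"?([^"]*)"?\s*$')
_BINOMIAL_RE = re.compile(r"^([A-Z][a-z]+ [a-z]+)")


def parse_precursor_flatfile(stream, release_label: str = "") -> list[PrecursorRecord]:
    """Parse an ``miRNA.dat`` stream into precursor records.

    One record per ``//``-delimited block.  The sequence is assembled from
    the ``SQ`` continuation lines with digits and whitespace stripped, then
    T→U and uppercase normalized.  Features missing an ``/accession``
    qualifier (releases < 6.0) get ``mature_accession=None``.
    """
    handle = _as_text_handle(stream)
    records: list[PrecursorRecord] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if line.strip() == "//":
            if any(l.strip() for _, l in block):
                records.append(_parse_dat_block(block))
            block = []
        else:
            block.append((lineno, line))
    if any(l.strip() for _, l in block):
        records.append(_parse_dat_block(block))
    return records


def _parse_dat_block(block: list[tuple[int, str]]) -> PrecursorRecord:
    name = accession = None
    desc_parts: list[str] = []
    xrefs: list[str] = []
    retained: list[str] = []
    features: list[MatureFeature] = []
    seq_parts: list[str] = []
    in_sq = False
    in_feature = False  # inside an FT miRNA feature's qualifier lines
    first_lineno = block[0][0]

    for lineno, line in block:
        tag = line[:2]
        if in_sq:
            seq_parts.append(re.sub(r"[\d\s]", "", line))
            continue
        if tag == "ID":
            toks = line[2:].split()
            if toks:
                name = toks[0]
        elif tag == "AC":
            toks = line[2:].replace(";", " ").split()
            if toks:
                accession = toks[0]
        elif tag == "DE":
            desc_parts.append(line[2:].strip())
        elif tag == "DR":
            xrefs.append(line)
        elif tag == "FT":
            m = _FT_FEATURE_RE.match(line)
            if m:
                key, start, end = m.group(1), int(m.group(2)), int(m.group(3))
                if key == "miRNA":
                    features.append(MatureFeature("", start, end))
                    in_feature = True
                else:
                    in_feature = False
                    retained.append(line)
            else:
                q = _FT_QUAL_RE.match(line)
                if q and in_feature and features:
                    qual, value = q.group(1), q.group(2)
                    if qual == "accession":
                        features[-1].mature_accession = value or None
                    elif qual == "product":
                        features[-1].product_name = value
                    elif qual == "evidence":
                        features[-1].evidence = value
                    else:
                        retained.append(line)
                else:
                    retained.append(line)
        elif tag == "SQ":
            in_sq = True
        elif tag in ("XX", "FH") or not line.strip():
            continue
        else:
            retained.append(line)

    label = accession or name or f"block at line {first_lineno}"
    if name is None or accession is None:
        raise ParseError(f"record {label} (line {first_lineno}): missing ID or AC line")
    if not in_sq:
        raise ParseError(f"record {label} (line {first_lineno}): missing SQ block")
    try:
        sequence = normalize_sequence("".join(seq_parts))
    except InvariantError as exc:
        raise ParseError(f"record {label} (line {first_lineno}): {exc}") from exc
    if not sequence:
        raise ParseError(f"record {label} (line {first_lineno}): empty sequence")
    for ft in features:
        if not (1 <= ft.start <= ft.end <= len(sequence)):
            raise ParseError(
                f"record {label} (line {first_lineno}): feature "
                f"{ft.product_name!r} span {ft.start}..{ft.end} outside sequence "
                f"of length {len(sequence)}"
            )
    description = " ".join(p for p in desc_parts if p)
    bm = _BINOMIAL_RE.match(description)
    return PrecursorRecord(
        accession=accession,
        name=name,
        sequence=sequence,
        description=description,
        species_name=bm.group(1) if bm else "",
        mature_features=features,
        xrefs=xrefs,
        references=retained,
    )


# ---------------------------------------------------------------------------
# mature.fa

_MAT_ACC_TOKEN_RE = re.compile(r"^(MIMAT\d{7}|PROV-[0-9a-f]{7})$")


def parse_mature_fasta(stream) -> list[tuple[str, str | None, str, str]]:
    """Parse a ``mature.fa`` stream.

    Returns ``(name, accession_or_None, species_text, sequence)`` tuples.
    The accession token is recognized anywhere in the header by its pattern;
    headers of releases before 6.0 simply lack it.
    """
    handle = _as_text_handle(stream)
    out: list[tuple[str, str | None, str, str]] = []
    seen_acc: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        words = rec.description.split()
        name = words[0]
        accession = None
        rest: list[str] = []
        for w in words[1:]:
            if accession is None and _MAT_ACC_TOKEN_RE.match(w):
                accession = w
            else:
                rest.append(w)
        if accession is not None:
            if accession in seen_acc:
                raise ParseError(f"duplicate mature accession {accession}")
            seen_acc.add(accession)
        try:
            seq = normalize_sequence(str(rec.seq))
        except InvariantError as exc:
            raise ParseError(f"mature {name!r}: {exc}") from exc
        out.append((name, accession, " ".join(rest), seq))
    return out


# ---------------------------------------------------------------------------
# miRNA.dead


def parse_dead_file(stream) -> list[DeadEntry]:
    """Parse ``miRNA.dead``: AC/ID/FW/CO blocks delimited by ``//``."""
    handle = _as_text_handle(stream)
    entries: list[DeadEntry] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if line.strip() == "//":
            if any(l.strip() for _, l in block):
                entries.append(_parse_dead_block(block))
            block = []
        else:
            block.append((lineno, line))
    if any(l.strip() for _, l in block):
        entries.append(_parse_dead_block(block))
    return entries


def _parse_dead_block(block: list[tuple[int, str]]) -> DeadEntry:
    acc = None
    name = ""
    fw = None
    comments: list[str] = []
    for _, line in block:
        tag = line[:2]
        body = line[2:].strip().rstrip(";")
        if tag == "AC":
            acc = body.split()[0] if body else None
        elif tag == "ID":
            name = body.split()[0] if body else ""
        elif tag == "FW":
            fw = body.split()[0] if body else None
        elif tag == "CO":
            comments.append(body)
    if acc is None:
        raise ParseError(
            f"dead entry block at line {block[0][0]}: missing AC line"
        )
    return DeadEntry(accession=acc, last_name=name, forward_to=fw,
                     comment=" ".join(comments))


# ---------------------------------------------------------------------------
# release assembly


def load_release(
    directory, release_label: str, warnings_out: list[str] | None = None
) -> ReleaseSnapshot:
    """Assemble a validated :class:`ReleaseSnapshot` from a release directory.

    Mature records are built by joining ``mature.fa`` entries to the ``FT``
    features of ``miRNA.dat`` — by accession when present, otherwise by
    product name plus sequence identity.  When a mature sequence disagrees
    with the precursor substring at the linked coordinates, a warning is
    recorded and the ``mature.fa`` sequence wins (it is the file the
    community consumes).  ``miRNA.dead`` is optional.
    """
    directory = Path(directory)
    warnings = warnings_out if warnings_out is not None else []
    precursors = {
        p.accession: p
        for p in parse_precursor_flatfile(directory / "miRNA.dat", release_label)
    }
    fasta = parse_mature_fasta(directory / "mature.fa")

    by_acc: dict[str, list[tuple[str, MatureFeature]]] = {}
    by_name: dict[str, list[tuple[str, MatureFeature]]] = {}
    for p in precursors.values():
        for ft in p.mature_features:
            if ft.mature_accession:
                by_acc.setdefault(ft.mature_accession, []).append((p.accession, ft))
            by_name.setdefault(ft.product_name, []).append((p.accession, ft))

    matures: dict[str, MatureRecord] = {}
    orphans: list[str] = []
    for name, accession, _species, seq in fasta:
        if accession is not None:
            hits = by_acc.get(accession, [])
        else:
            hits = [
                (pacc, ft)
                for pacc, ft in by_name.get(name, [])
                if precursors[pacc].feature_substring(ft) == seq
            ]
        if not hits:
            orphans.append(f"{name} ({accession or 'no accession'})")
            continue
        for pacc, ft in hits:
            sub = precursors[pacc].feature_substring(ft)
            if sub != seq:
                warnings.append(
                    f"{release_label}: mature {name} ({accession}) sequence differs "
                    f"from {pacc} substring {ft.start}..{ft.end}; mature.fa wins"
                )
        rec = MatureRecord(
            name=name,
            sequence=seq,
            accession=accession,
            parent_precursors=sorted({pacc for pacc, _ in hits}),
        )
        matures[rec.key()] = rec
    if orphans:
        raise ParseError(
            f"release {release_label}: mature.fa entries with no matching "
            f"miRNA.dat feature: {', '.join(orphans)}"
        )

    dead_path = directory / "miRNA.dead"
    dead = parse_dead_file(dead_path) if dead_path.exists() else []
    for w in warnings:
        logger.warning(w)
    snap = ReleaseSnapshot(
        release_label=release_label, precursors=precursors, matures=matures, dead=dead
    )
    snap.validate()
    return snap


def write_release(snapshot: ReleaseSnapshot, directory) -> None:
    """Emit ``miRNA.dat``, ``mature.fa`` and ``miRNA.dead`` for a snapshot.

    The emitted files re-parse to an equal snapshot; SQ blocks are wrapped
    at 60 nt in 10-nt groups with trailing position numbers, matching the
    dialect.  Refuses to write a snapshot violating its invariants.
    """
    snapshot.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "miRNA.dat", "w", encoding="utf-8") as fh:
        for acc in sorted(snapshot.precursors):
            _write_dat_record(fh, snapshot.precursors[acc])

    with open(directory / "mature.fa", "w", encoding="utf-8") as fh:
        for key in sorted(snapshot.matures):
            m = snapshot.matures[key]
            species = ""
            if m.parent_precursors:
                species = snapshot.precursors[m.parent_precursors[0]].species_name
            parts = [m.name]
            if m.accession is not None:
                parts.append(m.accession)
            if species:
                parts.append(species)
            fh.write(">" + " ".join(parts) + "\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")

    with open(directory / "miRNA.dead", "w", encoding="utf-8") as fh:
        for d in sorted(snapshot.dead, key=lambda d: d.accession):
            fh.write(f"AC   {d.accession}\n")
            if d.last_name:
                fh.write(f"ID   {d.last_name}\n")
            if d.forward_to:
                fh.write(f"FW   {d.forward_to}\n")
            if d.comment:
                fh.write(f"CO   {d.comment}\n")
            fh.write("//\n")


def _write_dat_record(fh: IO[str], p: PrecursorRecord) -> None:
    seq = p.sequence
    fh.write(f"ID   {p.name}    standard; RNA; {p.species_code.upper()}; "
             f"{len(seq)} BP.\nXX\n")
    fh.write(f"AC   {p.accession};\nXX\n")
    if p.description:
        fh.write(f"DE   {p.description}\nXX\n")
    for line in p.references:
        fh.write(line + "\n")
    for line in p.xrefs:
        fh.write(line + "\n")
    if p.mature_features:
        fh.write("FH   Key             Location/Qualifiers\nFH\n")
    for ft in p.mature_features:
        fh.write(f"FT   miRNA           {ft.start}..{ft.end}\n")
        if ft.mature_accession:
            fh.write(f'FT                   /accession="{ft.mature_accession}"\n')
        fh.write(f'FT                   /product="{ft.product_name}"\n')
        if ft.evidence:
            fh.write(f'FT                   /evidence={ft.evidence}\n')
    counts = {b: seq.count(b) for b in "ACG"}
    other = len(seq) - sum(counts.values())
    fh.write(
        f"SQ   Sequence {len(seq)} BP; {counts['A']} A; {counts['C']} C; "
        f"{counts['G']} G; 0 T; {other} other;\n"
    )
    low = seq.lower()
    for i in range(0, len(low), 60):
        chunk = low[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        pos = min(i + 60, len(low))
        fh.write(f"     {groups:<66}{pos:>8}\n")
    fh.write("//\n")


# ---------------------------------------------------------------------------
# batch queries and reports

REPORT_COLUMNS = [
    "query",
    "matched_accession",
    "molecule_type",
    "status",
    "latest_name",
    "latest_sequence",
    "latest_relations",
    "last_change_release",
    "note",
]


def read_batch_queries(stream) -> list[QueryRow]:
    """Read a batch TSV (header ``query, id_type?, molecule_type?, release?``)."""
    handle = _as_text_handle(stream)
    lines = handle.read().splitlines()
    if not lines:
        return []
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if "query" not in header:
        raise ParseError("batch file: header must contain a 'query' column")
    idx = {col: header.index(col) for col in header}
    rows: list[QueryRow] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")

        def cell(col: str, default: str = "") -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else default

        try:
            rows.append(
                QueryRow(
                    raw_query=cell("query"),
                    id_type=cell("id_type", "auto") or "auto",
                    molecule_type=cell("molecule_type", "auto") or "auto",
                    release_context=cell("release") or None,
                )
            )
        except InvariantError as exc:
            raise ParseError(f"batch file line {lineno}: {exc}") from exc
    return rows


def write_report(rows: Iterable[dict], stream, format: str = "tsv",
                 columns: list[str] | None = None) -> None:
    """Write report rows (dicts) as TSV or JSON (UTF-8, LF)."""
    rows = list(rows)
    columns = columns or (sorted({k for r in rows for k in r}) if rows else REPORT_COLUMNS)
    if format == "json":
        json.dump(rows, stream, indent=1, ensure_ascii=False)
        stream.write("\n")
    elif format == "tsv":
        stream.write("\t".join(columns) + "\n")
        for r in rows:
            stream.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(stream, format: str = "tsv") -> list[dict]:
    handle = _as_text_handle(stream)
    if format == "json":
        return json.load(handle)
    lines = handle.read().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line.strip()]
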