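"""Canonical seed-site target prediction and the prediction-overlap ratio.

A mature miRNA recognizes targets chiefly through its *seed*, positions
2–8 of the mature sequence.  The canonical site hierarchy on a 3'UTR
(Watson–Crick pairing only, no G:U wobble):

6mer
    the UTR carries the reverse complement of seed positions 2–7.
7mer-m8
    reverse complement of positions 2–8.
7mer-A1
    reverse complement of 2–7 followed by an ``A`` opposite miRNA
    position 1 (the A is a UTR identity, not a pairing requirement).
8mer
    7mer-m8 plus that ``A``.

An *interaction* is a unique (miRNA, transcript) pair — multiple sites on
one transcript count as one interaction with a site tally.  For two
prediction sets (e.g. from two releases of the same miRNAs), the overlap
ratio is ``|common| / |union|`` over interactions, restricted — when
comparing releases — to records present in both releases whose sequence
changed; the nonoverlap percentage ``100 * (1 - ratio)`` summarizes how
much of the targetome turned over purely from sequence-annotation changes.

This is a transparent canonical seed matcher, not a trained prediction
model: it exposes the turnover statistic's definition and properties, not
any particular tool's target calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .records import normalize_sequence

__all__ = [
    "Interaction",
    "OverlapResult",
    "SITE_TYPES",
    "seed_of",
    "site_string",
    "predict_targets",
    "prediction_overlap",
    "impact_report",
    "read_utr_fasta",
]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_RC = {"A": "U", "U": "A", "C": "G", "G": "C", "N": "N"}


class UndefinedOverlapError(ValueError):
    """Overlap ratio is undefined when the union of interactions is empty."""


@dataclass(frozen=True)
class Interaction:
    mirna_id: str
    transcript_id: str
    site_types: frozenset = field(default_factory=frozenset)
    site_count: int = 0

    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.transcript_id)


@dataclass(frozen=True)
class OverlapResult:
    n_common: int
    n_union: int
    restricted_mirna_set: frozenset | None = None

    @property
    def ratio(self) -> float:
        return self.n_common / self.n_union

    @property
    def nonoverlap_percent(self) -> float:
        return 100.0 * (1.0 - self.ratio)


def seed_of(sequence: str, span: tuple[int, int] = (2, 8)) -> str:
    """The seed region: positions 2–8 (1-based) of the mature sequence."""
    seq = normalize_sequence(sequence)
    lo, hi = span
    if len(seq) < hi:
        raise ValueError(
            f"sequence of length {len(seq)} too short for seed span {lo}..{hi}"
        )
    return seq[lo - 1 : hi]


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def site_string(mature_sequence: str, site_type: str) -> str:
    """The exact UTR substring that constitutes a site of the given type."""
    seq = normalize_sequence(mature_sequence)
    if len(seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no seed sites")
    if site_type == "6mer":
        return _revcomp(seq[1:7])
    if site_type == "7mer-m8":
        return _revcomp(seq[1:8])
    if site_type == "7mer-A1":
        return _revcomp(seq[1:7]) + "A"
    if site_type == "8mer":
        return _revcomp(seq[1:8]) + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def predict_targets(
    matures: dict[str, str] | list[tuple[str, str]],
    utrs: dict[str, str] | list[tuple[str, str]],
    site_types: tuple[str, ...] = SITE_TYPES,
) -> set[Interaction]:
    """Scan 3'UTRs for canonical seed sites of each mature sequence.

    *matures* and *utrs* map identifiers to sequences (dict or pairs); UTRs
    are normalized T→U.  Overlapping occurrences each count toward the site
    tally; an interaction is emitted if any requested site type occurs at
    least once.  An empty UTR set yields an empty prediction.
    """
    if not site_types:
        raise ValueError("site_types must be non-empty")
    unknown = set(site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types {sorted(unknown)}")
    mat_items = matures.items() if isinstance(matures, dict) else matures
    utr_items = list(utrs.items() if isinstance(utrs, dict) else utrs)
    utr_norm = [(tid, normalize_sequence(seq)) for tid, seq in utr_items]

    out: set[Interaction] = set()
    for mid, mseq in mat_items:
        needles = {st: site_string(mseq, st) for st in site_types}
        for tid, useq in utr_norm:
            found = {}
            for st, needle in needles.items():
                n = _count_overlapping(useq, needle)
                if n:
                    found[st] = n
            if found:
                out.add(Interaction(
                    mirna_id=mid, transcript_id=tid,
                    site_types=frozenset(found),
                    site_count=sum(found.values()),
                ))
    return out


def prediction_overlap(
    set_a: set[Interaction],
    set_b: set[Interaction],
    restrict_to: set[str] | None = None,
) -> OverlapResult:
    """Ratio of common to total unique (miRNA, transcript) interactions.

    With *restrict_to*, both sets are first filtered to those miRNA ids —
    the release-comparison rule that only records present in both releases
    with a sequence change contribute.  Symmetric in its two inputs; an
    empty union is an explicit undefined-result error, never 0/0.
    """
    pairs_a = {i.pair() for i in set_a}
    pairs_b = {i.pair() for i in set_b}
    if restrict_to is not None:
        pairs_a = {p for p in pairs_a if p[0] in restrict_to}
        pairs_b = {p for p in pairs_b if p[0] in restrict_to}
    union = pairs_a | pairs_b
    if not union:
        raise UndefinedOverlapError(
            "no interactions in either set after restriction; overlap undefined"
        )
    return OverlapResult(
        n_common=len(pairs_a & pairs_b),
        n_union=len(union),
        restricted_mirna_set=frozenset(restrict_to) if restrict_to is not None
        else None,
    )


def read_utr_fasta(stream) -> dict[str, str]:
    """Read transcript 3'UTR sequences from FASTA, T→U normalized."""
    from .mirbase_io import _as_text_handle

    return {
        rec.id: normalize_sequence(str(rec.seq))
        for rec in SeqIO.parse(_as_text_handle(stream), "fasta")
    }


def impact_report(
    store,
    release_a: str,
    release_b: str,
    utrs: dict[str, str],
    site_types: tuple[str, ...] = SITE_TYPES,
) -> tuple[pd.DataFrame, OverlapResult | None]:
    """Targetome turnover caused purely by sequence-annotation changes.

    Selects mature records active in both releases whose sequences differ,
    predicts targets for both sequence versions, and reports per-miRNA the
    seed-changed flag and overlap ratio plus the aggregate overlap and
    nonoverlap percentage.  Newly added or deleted records never
    contribute.  With no sequence-changed records the table is empty and
    the aggregate is ``None``.
    """
    snap_a = store.reconstruct(release_a)
    snap_b = store.reconstruct(release_b)
    common = set(snap_a.matures) & set(snap_b.matures)
    changed = sorted(
        acc for acc in common
        if snap_a.matures[acc].sequence != snap_b.matures[acc].sequence
        and len(snap_a.matures[acc].sequence) >= 8
        and len(snap_b.matures[acc].sequence) >= 8
    )
    columns = ["accession", "name_a", "name_b", "sequence_a", "sequence_b",
               "seed_changed", "n_targets_a", "n_targets_b", "overlap_ratio"]
    if not changed:
        return pd.DataFrame(columns=columns), None

    old = {acc: snap_a.matures[acc].sequence for acc in changed}
    new = {acc: snap_b.matures[acc].sequence for acc in changed}
    pred_a = predict_targets(old, utrs, site_types)
    pred_b = predict_targets(new, utrs, site_types)

    rows = []
    for acc in changed:
        sub_a = {i for i in pred_a if i.mirna_id == acc}
        sub_b = {i for i in pred_b if i.mirna_id == acc}
        try:
            ratio = prediction_overlap(sub_a, sub_b).ratio
        except UndefinedOverlapError:
            ratio = float("nan")
        rows.append({
            "accession": acc,
            "name_a": snap_a.matures[acc].name,
            "name_b": snap_b.matures[acc].name,
            "sequence_a": old[acc],
            "sequence_b": new[acc],
            "seed_changed": seed_of(old[acc]) != seed_of(new[acc]),
            "n_targets_a": len(sub_a),
            "n_targets_b": len(sub_b),
            "overlap_ratio": ratio,
        })
    try:
        aggregate = prediction_overlap(pred_a, pred_b, restrict_to=set(changed))
    except UndefinedOverlapError:
        aggregate = None
    return pd.DataFrame(rows, columns=columns), aggregate
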