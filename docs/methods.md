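# Methods

## The tracking model

The unit of identity is the accession number.  A precursor (stem-loop)
carries an `MI`-prefixed accession from the first release onward; a mature
miRNA carries a `MIMAT`-prefixed accession only from release 6.0.  A
record's *annotation state* is its name, sequence and linkage (for a
mature, its parent precursor set; for a precursor, its ordered feature
list: mature accession, product name, 1-based inclusive span, evidence
text).  Between two consecutive ingested releases, each accession is in
exactly one of four situations — new, gone, changed, unchanged — refined
into seven change types:

| type | fires when |
|---|---|
| ADDED | accession appears for the first time |
| RESURRECTED | accession returns after being in the cumulative dead list |
| NAME_CHANGE | names differ |
| SEQUENCE_CHANGE | normalized sequences differ |
| RELATION_CHANGE | linkage differs (see below) |
| DELETED | accession leaves the active set, no forward pointer |
| MERGED | accession leaves the active set, dead file forwards to a survivor |

One event groups all change types of one accession at one transition.
MERGED is distinguished from DELETED *solely* by the dead-file forward
pointer.  Names never join records: a name that disappears from one
accession and reappears on another is a deletion plus an addition.

**Scope of RELATION_CHANGE.**  For precursors the trigger is the full
feature list — including coordinate spans and product names — not merely
the set of linked mature accessions.  This is required for event-sourcing
soundness: every field the store persists must be covered by some change
type, otherwise a mature 3'-end shift (coordinates move, accession set
constant) would leave a stale precursor state and replay could not
reproduce the release.  The comparison query collapses all three `*_changed`
categories into a single "changed" bucket, so this granularity never leaks
into summary semantics.

## Event store and replay

Two logical tables: `CHANGES(event_id, accession, molecule_type,
change_type, release_label)` — one row per change type — and
`STATES(event_id, accession, name, sequence, species_code, relations,
release_label)` — the annotation after the change, with linkage,
description and species serialized as JSON in `relations`.  Auxiliary
tables: the release registry (label, numeric (major, minor) ordinal,
ingest position), retro-assignment provenance, `DEAD_DETAILS` (last name,
forward pointer, comment of removed records — `CHANGES` has no columns for
these and the cumulative dead list cannot be replayed without them) and a
build manifest with per-file sha256 checksums.  The engine is sqlite3; the
schema, not the engine, is the contract, and every table dumps to sorted
TSV so two stores can be diffed textually.

Release ordering is numeric on (major, minor): "9.2" < "10.0" < "21".
Lexicographic ordering is wrong and rejected.  Gaps in the ingested series
are legal — "consecutive" means adjacent in the provided set — and replay
stays exact across them because a record added and removed inside a gap
still surfaces in the later release's cumulative dead file; such dead-file-
only entries get their terminal event at the release where they first
appear.

Replaying all events in release order from the empty state reproduces
every ingested release field-for-field (opaque verbatim-retained
annotation excluded, since the store does not persist it).  This equality
is the module's central test and also certifies the diff engine: any
missed or spurious event breaks it.

## File dialects

Required fields are deliberately minimal (tolerant parsing for old-release
drift): `ID`/`AC`/`SQ` for a precursor block, the header name for a mature
FASTA entry.  Everything unrecognized — reference lines, database
cross-references, unknown feature qualifiers — is retained verbatim and
re-emitted, so `parse(write(snapshot)) == snapshot` including opaque text.
Sequences are normalized to uppercase RNA (T→U) on input; coordinates stay
1-based inclusive as in the dialect.  `mature.fa` is authoritative when a
mature sequence disagrees with the precursor substring at the linked
coordinates: the conflict is logged as a warning, never silently dropped,
and the `mature.fa` sequence wins (it is the file the community consumes).
The writer wraps `SQ` blocks at 60 nt in 10-nt groups with trailing
position numbers and keeps `mature.fa` lines within 80 columns.

## Retro-accession assignment

Walking backwards from the anchor (the earliest fully accessioned
release), each unaccessioned mature is matched against the immediately
nearer, already-canonical release by cascade: (1) exact species + name,
(2) exact sequence within species, (3) maximal sequence overlap
(containment, or ≥ 16 shared contiguous nucleotides), ties broken by name
edit distance then lexicographic name.  If the primary pool fails, the
same cascade runs over a fallback pool holding all assignments from later
backward steps plus dead-file entries (known by accession and last name
only, hence rule-1 matchable) — this lets a record that disappeared before
the anchor, or across a dead interval, still reach its canonical
accession.  Assignment is injective per release: an accession claimed by
an earlier-sorted record falls through to the next rule.  Explicit
overrides (TSV: release, species, name, sequence → accession) are applied
first and take absolute precedence; they are the escape hatch for
genuinely ambiguous histories, such as a name retired and reissued to a
different molecule within the pre-accession era, which no name-first
cascade can resolve.  Unmatched records get provisional accessions,
content-addressed as `PROV-` + 7 hex chars of sha1(species|name|sequence),
so they are total, stable across rebuilds, and unaffected by unrelated
records.

## The synthetic release generator

The simulator emulates the annotation dynamics of the real database, not
its biology: precursor sequences are i.i.d. uniform over {A,C,G,U} at
60–120 nt with mature features of 20–24 nt (one or two arms), and no
hairpin thermodynamics or expression realism is attempted — tracking, not
folding, is under test.  Names follow the miRBase grammar (species prefix,
`mir`/`miR` capitalization, `-5p`/`-3p` arms, family letters, locus
numbers); renames apply grammar-preserving mutations.  Per transition,
each record independently undergoes at most one primary mutation
(deletion 0.02, merge 0.01, rename 0.06, sequence change 0.05, relink
0.01, resurrection 0.02, addition 0.04 per existing precursor, by
default), with cascaded effects applied consistently: a point substitution
in a mature edits the precursor sequence; an isomiR-like 1–2 nt 3'-end
shift moves the feature span (precursor sequence untouched); a mature
rename rewrites the parent's `FT /product`; a merged precursor forwards
its orphaned matures to a mature of the merge target.  A sequence change
hits the seed (positions 2–8) with probability 0.3.  The ground-truth log
is written constructively as mutations are applied — never by running the
diff engine — so diff-vs-log comparison is a genuine dual-route check.
Identical parameters and seed give byte-identical files.

Two scenario controls: `accession_epoch` emits releases before a given
index without mature accessions (the pre-6.0 era), and
`reissue_retired_name` re-issues a retired name to a new accession (the
known name-reuse hazard).  Combining both is deliberately adversarial for
retro-assignment and is resolved in tests via the override table, mirroring
manual curation.

What passing on synthetic data does *not* show: robustness to the full
header-wording drift of archived early releases, to records whose name and
sequence both change in one transition (explicitly non-adversarial
conditions), or to any property of real hairpin sequences.

## Seed sites and the overlap statistic

Site strings are the reverse complements of seed subsequences: 6mer =
rc(2–7), 7mer-m8 = rc(2–8), 7mer-A1 = rc(2–7)+A, 8mer = rc(2–8)+A, matched
as exact substrings of T→U-normalized 3'UTRs; G:U wobble pairing is
excluded (canonical-site convention, the simplest defensible choice).
Overlapping occurrences each count toward the site tally; an interaction
is the deduplicated (miRNA, transcript) pair — the quoted unit of the
statistic counts interactions, not sites.  The overlap of two prediction
sets is |common| / |union| over pairs, after restricting both sets to the
miRNA ids under study (for release comparisons: records present in both
releases whose sequence changed — newly added or deleted records never
contribute).  An empty union is an explicit error, not 0.  The scanner is
a plain substring scan verified against a brute-force window oracle; the
matcher is deliberately transparent rather than a trained target-prediction
model, so the statistic's definition and properties, not any tool's
specific percentages, are what this module reproduces.

## Numerical and design choices

- Sequence alphabet after normalization is strictly `[ACGUN]`; anything
  else is a parse error naming the record.
- Name lookups are case-insensitive by default (users paste
  `HSA-MIR-21`), with a case-sensitive override; storage is always
  case-sensitive since `mir`/`miR` distinguishes precursor from mature
  names.  A case-insensitive query can therefore legitimately resolve to
  both a precursor and its mature; the molecule-type filter disambiguates.
- Update queries with multiple matches report `ambiguous` rather than
  guessing; a release context disambiguates.  Merge chains are chased
  transitively; a pointer cycle is an error naming the cycle.
- Comparison reports are computed from reconstructed snapshots, never by
  summing events, so they are correct across series gaps and in either
  direction (`compare(A,B).added == compare(B,A).removed`).
- Deterministic everywhere: events sort by accession; simulator draws
  follow sorted iteration orders; rebuilding a store from identical inputs
  dumps byte-identically.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
ground-truth recovery over 20 five-release series of 30 precursors,
replay/round-trip on one 8-release series of 200 initial precursors
(~300 precursor and ~450 mature records by the last release), retro
assignment on a 6-release series with the accession era starting at
release 4, and targetome turnover for ~25 sequence-changed matures against
120 random 1.5 kb UTRs.  These sizes exercise every code path while
keeping the full suite under a few seconds.

## Known limitations

- Genomic coordinates (GFF/BED), `aliases.txt` and literature-reference
  parsing beyond verbatim retention are out of scope.
- Retro-assignment quality on real pre-6.0 files ultimately depends on the
  override table where histories are ambiguous; discrepancies surface as
  provisional accessions and per-record provenance rows, never silently.
- The seed matcher ignores pairing context, conservation and site
  accessibility; its overlap numbers on random UTRs characterize the
  statistic, not biological targetomes.
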