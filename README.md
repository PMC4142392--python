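# mirtrack

Track microRNA annotation changes across miRBase releases.

miRBase is the reference database for miRNA annotation, and it is highly
dynamic: records are added as new miRNAs are discovered, deleted when the
evidence no longer holds up, merged when two records turn out to cover the
same molecule, renamed as nomenclature conventions evolve (arm suffixes,
family letters, locus numbers), and their sequences are revised as
sequencing accuracy improves or predominant isomiRs shift.  Because a plain
miRBase download is a snapshot with no memory, a name or sequence quoted in
a paper, a probe list or a target-prediction database can silently refer to
a different molecule — or a different sequence of the same molecule — than
the current release.  `mirtrack` is for anyone who needs to reconcile miRNA
identifiers across time: it ingests a series of miRBase releases, detects
and classifies every per-record change, stores the changes in a replayable
event store, and answers history, update/reannotation and release-comparison
queries.

## What it does

**Parsing.** Each release consists of `miRNA.dat` (EMBL-style flat file of
precursor stem-loops with `FT miRNA` features locating the mature
products), `mature.fa` (mature sequences, headers `>name [accession]
species …`) and `miRNA.dead` (removed entries, with an `FW` forward pointer
when the record was merged into a survivor).  Parsing is tolerant of the
dialect drift across old releases and retains unrecognized annotation
verbatim.

**Diffing.** Records are reconciled between consecutive releases using
accession numbers as the unique identifier (`MI…` for precursors, `MIMAT…`
for matures), never names — a reused name is a deletion plus an addition,
not a rename.  Every change is classified into a typed event: `ADDED`,
`NAME_CHANGE`, `SEQUENCE_CHANGE`, `RELATION_CHANGE` (linkage between
precursors and matures), `DELETED`, `MERGED` (with its target) or
`RESURRECTED`.  Mature accessions exist only from release 6.0; older
releases are resolved by retro-assignment: canonical accessions are
propagated backwards through a name → sequence → sequence-overlap rule
cascade, with an explicit override table (the curation escape hatch) taking
absolute precedence and stable provisional accessions guaranteeing every
record an identifier.

**Event store.** Events and post-change annotation live in a two-table
relational schema (sqlite3): `CHANGES` (one row per change type per
accession per release) and `STATES` (the record's annotation after the
change), plus release registry, retro-assignment provenance and dead-record
details.  Replaying all events from the empty state reproduces any
ingested release exactly — the store's central correctness property.

**Queries.** History (the full timeline of one record), update (the latest
annotation for any name, sequence or accession from any release, chasing
merge pointers transitively — the batch reannotation workhorse) and
comparison (which records were added, removed, changed or unchanged
between any two releases, per species and molecule type).

**Synthetic releases.** A simulator emits multi-release series in the exact
file dialects with controlled add/rename/sequence-change/delete/merge/
resurrect events and a machine-readable ground-truth log, so the whole
pipeline is testable with no download.

**Targetome turnover.** A sequence change — especially one touching the
seed (positions 2–8) — reshuffles a miRNA's predicted targets.  For mature
records present in two releases with different sequences, `mirtrack`
predicts canonical seed sites (6mer, 7mer-A1, 7mer-m8, 8mer; Watson–Crick
only) on a 3'UTR set for both sequence versions and reports the overlap
ratio over unique (miRNA, transcript) interactions,

&emsp; overlap = |common interactions| / |union of interactions|,

and the nonoverlap percentage 100·(1 − overlap).  This is a transparent
seed matcher, not a trained prediction model: it measures how much of a
targetome survives an annotation change under canonical site rules.

## Worked example

Simulate a 5-release series, build a store, and query it:

```sh
$ mirtrack simulate --seed 42 --out series
wrote 5 releases and 138 ground-truth events to series
$ mirtrack build --releases series/1.0,series/2.0,series/3.0,series/4.0,series/5.0 --out store.db
built store store.db with 5 releases: 1.0, 2.0, 3.0, 4.0, 5.0
$ mirtrack history --store store.db --query MIMAT0000011
accession     molecule_type  release  name          sequence                change_types     status
MIMAT0000011  mature         1.0      hsa-miR-3-3p  UAUGUGGACGUUGUAUAGGGAU  ADDED            active
MIMAT0000011  mature         3.0      hsa-miR-3-3p  UAUGUGGACGUUGUAUAGGGAC  SEQUENCE_CHANGE  active
```

The record entered the database in release 1.0 and its sequence was revised
in release 3.0 (a 3' terminal change, so the seed is intact); it is still
active.  An update query on the *name* returns the current annotation —
anyone holding the 1.0 sequence is one base out of date:

```sh
$ mirtrack update --store store.db --query hsa-miR-3-3p --id-type name
query         matched_accession  ...  status   latest_name   latest_sequence         last_change_release
hsa-miR-3-3p  MIMAT0000011       ...  current  hsa-miR-3-3p  UAUGUGGACGUUGUAUAGGGAC  3.0
```

Comparing releases 2.0 and 5.0 for mature records:

```sh
$ mirtrack compare --store store.db --from 2.0 --to 5.0 --type mature
{"added": 10, "removed": 2, "removed_deleted": 1, "removed_merged": 1,
 "changed": 13, "name_changed": 6, "sequence_changed": 5,
 "relation_changed": 2, "unchanged": 26}
```

Ten matures were added between the two releases, one was deleted, one was
merged into a surviving record, thirteen changed in place (a record may be
both renamed and sequence-revised, so the per-field counts can exceed the
union) and twenty-six are identical in both releases.

The same store drives the targetome-turnover report
(`mirtrack overlap --store store.db --from 1.0 --to 5.0 --utrs utrs.fa`),
which lists every sequence-changed mature with a seed-changed flag and its
per-miRNA overlap ratio, plus the aggregate ratio over all of them.

Real miRBase releases are ingested the same way: download a release's
`miRNA.dat`, `mature.fa` and `miRNA.dead` into a directory named after the
release label and pass the directories to `mirtrack build` (with
`--overrides` supplying manual retro-accession curation for pre-6.0
releases where the automatic cascade is ambiguous, e.g. names that were
retired and reissued).

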