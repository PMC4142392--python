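"""Generate synthetic multi-release miRBase series with known ground truth.

The simulator emits a series of release directories in the exact three-file
dialect (``miRNA.dat`` / ``mature.fa`` / ``miRNA.dead``) together with a
machine-readable :class:`GroundTruthLog` of every injected change, so the
parser, diff engine, event store and query layer are all testable with no
download.  The log is built *constructively* as mutations are applied —
including their cascaded effects (a point substitution in a mature edits
the precursor sequence; an end-shift moves the FT span; a mature rename
rewrites the FT ``/product``) — never by running the diff engine, so it is
an independent oracle.

Precursor sequences are i.i.d. uniform over {A,C,G,U} at 60–120 nt with
mature features of 20–24 nt; no hairpin realism is attempted (tracking, not
folding, is under test).  Names follow miRBase conventions: species prefix,
``mir`` (precursor) vs ``miR`` (mature) capitalization, ``-5p``/``-3p`` arm
suffixes, family letters and locus numbers for duplicates.

``accession_epoch`` controls the release index before which mature records
are written *without* accessions, emulating the pre-6.0 era and exercising
retro-accession assignment.
"""

from __future__ import annotations

import copy
import json
import random
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .records import (
    DeadEntry,
    MatureFeature,
    MatureRecord,
    PrecursorRecord,
    ReleaseSnapshot,
)
from .mirbase_io import write_release

__all__ = [
    "SimulationParams",
    "GroundTruthEvent",
    "GroundTruthLog",
    "simulate_release_series",
    "simulate_snapshots",
    "name_mutator",
    "name_is_valid",
]

_SPECIES_POOL = ["hsa", "mmu", "rno", "dme", "cel", "gga", "dre", "bta", "xla", "ssc"]
_BINOMIALS = {
    "hsa": "Homo sapiens", "mmu": "Mus musculus", "rno": "Rattus norvegicus",
    "dme": "Drosophila melanogaster", "cel": "Caenorhabditis elegans",
    "gga": "Gallus gallus", "dre": "Danio rerio", "bta": "Bos taurus",
    "xla": "Xenopus laevis", "ssc": "Sus scrofa",
}
_BASES = "ACGU"

_NAME_RE = re.compile(
    r"^(?P<prefix>[a-z]{3,4})-(?P<tag>miR|mir|let|lin)-(?P<num>\d+)"
    r"(?P<fam>[a-z]?)(?:-(?P<locus>\d+))?(?:-(?P<arm>[53]p))?(?P<star>\*)?$"
)


def name_is_valid(name: str) -> bool:
    """Membership in the miRBase name grammar (star names included)."""
    return bool(_NAME_RE.match(name))


def name_mutator(name: str, mode: str, *, arm: str = "3p", locus: int = 1) -> str:
    """Apply one nomenclature evolution step to a miRBase name.

    Modes: ``add-arm-suffix`` (``hsa-miR-378`` → ``hsa-miR-378-3p``),
    ``add-family-letter`` (→ ``hsa-miR-378a``, or bump an existing letter),
    ``add-locus-number`` (→ ``hsa-miR-378-1``), ``star-to-arm`` (legacy
    ``hsa-miR-378*`` → ``hsa-miR-378-3p``).  Output always re-validates
    against the grammar.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"name {name!r} does not match the miRBase grammar")
    g = m.groupdict()

    def rebuild(fam=None, loc=None, arm_=None, star=False):
        out = f"{g['prefix']}-{g['tag']}-{g['num']}"
        out += fam if fam is not None else g["fam"]
        loc = loc if loc is not None else g["locus"]
        if loc:
            out += f"-{loc}"
        arm_ = arm_ if arm_ is not None else g["arm"]
        if arm_:
            out += f"-{arm_}"
        if star:
            out += "*"
        return out

    if mode == "add-arm-suffix":
        if g["arm"]:
            raise ValueError(f"{name!r} already carries an arm suffix")
        if arm not in {"5p", "3p"}:
            raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
        return rebuild(arm_=arm)
    if mode == "add-family-letter":
        fam = "a" if not g["fam"] else chr(ord(g["fam"]) + 1)
        if fam > "z":
            raise ValueError(f"family letters exhausted for {name!r}")
        return rebuild(fam=fam)
    if mode == "add-locus-number":
        return rebuild(loc=str(locus))
    if mode == "star-to-arm":
        if not g["star"]:
            raise ValueError(f"{name!r} is not a star name")
        return rebuild(arm_="3p" if not g["arm"] else g["arm"], star=False)
    raise ValueError(f"unknown mutation mode {mode!r}")


@dataclass
class SimulationParams:
    """Knobs of the synthetic annotation-evolution model.

    Per-transition rates are per-record Bernoulli probabilities; an
    end-shift moves the mature 3' end by 1–2 nt, a substitution flips one
    base, hitting the seed region (positions 2–8) with probability
    ``p_seed_region_hit``.  ``accession_epoch`` is the 1-based release index
    before which matures are emitted without accessions.
    """

    n_species: int = 3
    n_initial_precursors: int = 30
    matures_per_precursor: int = 2  # 1: single mature; 2: randomly 1 or 2 arms
    n_releases: int = 5
    p_add: float = 0.04
    p_delete: float = 0.02
    p_merge: float = 0.01
    p_rename: float = 0.06
    p_seqchange: float = 0.05
    p_relink: float = 0.01
    p_resurrect: float = 0.02
    p_seed_region_hit: float = 0.3
    rng_seed: int = 0
    accession_epoch: int = 1
    reissue_retired_name: bool = False

    def validate(self) -> None:
        for f_ in ("p_add", "p_delete", "p_merge", "p_rename", "p_seqchange",
                   "p_relink", "p_resurrect", "p_seed_region_hit"):
            v = getattr(self, f_)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f_}={v} outside [0, 1]")
        if self.n_releases < 1:
            raise ValueError("n_releases must be >= 1")
        if self.matures_per_precursor not in (1, 2):
            raise ValueError("matures_per_precursor must be 1 or 2")
        if not 1 <= self.n_species <= len(_SPECIES_POOL):
            raise ValueError(f"n_species must be in 1..{len(_SPECIES_POOL)}")


@dataclass(frozen=True)
class GroundTruthEvent:
    release_label: str
    accession: str
    molecule_type: str
    change_types: frozenset
    old_name: str = ""
    new_name: str = ""
    old_sequence: str = ""
    new_sequence: str = ""
    merge_target: str = ""

    def comparable(self) -> tuple:
        return (self.release_label, self.accession,
                frozenset(self.change_types), self.merge_target or "")


@dataclass
class GroundTruthLog:
    """Ordered log of every injected change; the diff engine's oracle."""

    events: list = field(default_factory=list)

    def comparable_set(self) -> set:
        return {e.comparable() for e in self.events}

    def after_first_release(self) -> list:
        first = min((e.release_label for e in self.events), default=None)
        return [e for e in self.events if e.release_label != first]

    def counts_by_type(self) -> dict:
        out: dict[str, int] = {}
        for e in self.events:
            for t in e.change_types:
                out[t] = out.get(t, 0) + 1
        return out

    def write(self, directory) -> None:
        directory = Path(directory)
        rows = [
            {
                "release": e.release_label, "accession": e.accession,
                "molecule_type": e.molecule_type,
                "change_types": ",".join(sorted(e.change_types)),
                "old_name": e.old_name, "new_name": e.new_name,
                "old_sequence": e.old_sequence, "new_sequence": e.new_sequence,
                "merge_target": e.merge_target,
            }
            for e in self.events
        ]
        cols = ["release", "accession", "molecule_type", "change_types",
                "old_name", "new_name", "old_sequence", "new_sequence",
                "merge_target"]
        with open(directory / "ground_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
        with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")


class _Simulator:
    def __init__(self, params: SimulationParams):
        params.validate()
        self.p = params
        self.rng = random.Random(params.rng_seed)
        self.species = _SPECIES_POOL[: params.n_species]
        self.next_mi = 1
        self.next_mimat = 1
        self.locus_counter = {sp: 0 for sp in self.species}
        self.log = GroundTruthLog()
        # dead records kept for potential resurrection (non-merged only)
        self.dead_payload: dict[str, tuple[PrecursorRecord, list[MatureRecord]]] = {}

    # -- naming and sequence helpers ---------------------------------------

    def _new_accessions(self) -> str:
        acc = f"MI{self.next_mi:07d}"
        self.next_mi += 1
        return acc

    def _new_mimat(self) -> str:
        acc = f"MIMAT{self.next_mimat:07d}"
        self.next_mimat += 1
        return acc

    def _random_sequence(self, length: int) -> str:
        return "".join(self.rng.choice(_BASES) for _ in range(length))

    def _new_precursor(self, snap: ReleaseSnapshot, species: str,
                       name: str | None = None) -> tuple[PrecursorRecord, list[MatureRecord]]:
        if name is None:
            self.locus_counter[species] += 1
            num = self.locus_counter[species]
            name = f"{species}-mir-{num}"
        m = _NAME_RE.match(name)
        num = m.group("num") + (m.group("fam") or "")
        L = self.rng.randint(60, 120)
        seq = self._random_sequence(L)
        acc = self._new_accessions()
        two_arms = self.p.matures_per_precursor == 2 and self.rng.random() < 0.5
        features: list[MatureFeature] = []
        matures: list[MatureRecord] = []

        def add_arm(arm: str | None):
            mlen = self.rng.randint(20, 24)
            if arm == "5p":
                start = self.rng.randint(1, 3)
            elif arm == "3p":
                start = L - mlen + 1 - self.rng.randint(0, 2)
            else:
                start = self.rng.choice([1, L - mlen + 1])
            end = start + mlen - 1
            mname = f"{species}-miR-{num}" + (f"-{arm}" if arm else "")
            macc = self._new_mimat()
            features.append(MatureFeature(
                product_name=mname, start=start, end=end,
                mature_accession=macc, evidence="experimental",
            ))
            matures.append(MatureRecord(
                name=mname, sequence=seq[start - 1: end], accession=macc,
                parent_precursors=[acc],
            ))

        if two_arms:
            add_arm("5p")
            add_arm("3p")
        else:
            add_arm(None)
        binomial = _BINOMIALS[species]
        prec = PrecursorRecord(
            accession=acc, name=name, sequence=seq,
            description=f"{binomial} {name.split('-', 1)[1]} stem-loop",
            species_name=binomial, mature_features=features,
        )
        return prec, matures

    # -- build --------------------------------------------------------------

    def initial_snapshot(self) -> ReleaseSnapshot:
        snap = ReleaseSnapshot(release_label="1.0")
        for i in range(self.p.n_initial_precursors):
            species = self.species[i % len(self.species)]
            prec, mats = self._new_precursor(snap, species)
            snap.precursors[prec.accession] = prec
            for mrec in mats:
                snap.matures[mrec.accession] = mrec
        for acc in sorted(snap.precursors):
            p = snap.precursors[acc]
            self.log.events.append(GroundTruthEvent(
                "1.0", acc, "precursor", frozenset({"ADDED"}),
                new_name=p.name, new_sequence=p.sequence))
        for acc in sorted(snap.matures):
            mrec = snap.matures[acc]
            self.log.events.append(GroundTruthEvent(
                "1.0", acc, "mature", frozenset({"ADDED"}),
                new_name=mrec.name, new_sequence=mrec.sequence))
        snap.validate()
        return snap

    def run(self) -> tuple[list[ReleaseSnapshot], GroundTruthLog]:
        snapshots = [self.initial_snapshot()]
        for t in range(2, self.p.n_releases + 1):
            snapshots.append(self.transition(snapshots[-1], f"{t}.0"))
            if not snapshots[-1].precursors and t < self.p.n_releases:
                raise ValueError(
                    f"simulation emptied the database at release {t}.0 "
                    f"before the last release; lower the deletion rates"
                )
        return snapshots, self.log

    # -- one release transition ---------------------------------------------

    def transition(self, prev: ReleaseSnapshot, label: str) -> ReleaseSnapshot:
        rng, p = self.rng, self.p
        snap = ReleaseSnapshot(
            release_label=label,
            precursors=copy.deepcopy(prev.precursors),
            matures=copy.deepcopy(prev.matures),
            dead=copy.deepcopy(prev.dead),
        )
        dead = {d.accession: d for d in snap.dead}
        touched: set[str] = set()
        noted: dict[str, dict] = {}

        def note(acc, mol, types, old=None, new=None, merge_target=""):
            e = noted.setdefault(acc, {
                "mol": mol, "types": set(), "old_name": "", "new_name": "",
                "old_seq": "", "new_seq": "", "merge_target": ""})
            e["types"] |= set(types)
            if old is not None and not e["old_name"]:
                e["old_name"], e["old_seq"] = old
            if new is not None:
                e["new_name"], e["new_seq"] = new
            if merge_target:
                e["merge_target"] = merge_target

        def remove_precursor(pacc: str, forward: str | None):
            prec = snap.precursors.pop(pacc)
            dead[pacc] = DeadEntry(pacc, last_name=prec.name, forward_to=forward)
            note(pacc, "precursor", {"MERGED"} if forward else {"DELETED"},
                 old=(prec.name, prec.sequence), merge_target=forward or "")
            orphan_matures = []
            for ft in prec.mature_features:
                macc = ft.mature_accession
                mrec = snap.matures.get(macc)
                if mrec is None:
                    continue
                mrec.parent_precursors = [x for x in mrec.parent_precursors
                                          if x != pacc]
                if mrec.parent_precursors:
                    note(macc, "mature", {"RELATION_CHANGE"},
                         old=(mrec.name, mrec.sequence),
                         new=(mrec.name, mrec.sequence))
                    touched.add(macc)
                else:
                    snap.matures.pop(macc)
                    orphan_matures.append(mrec)
                    touched.add(macc)
            return prec, orphan_matures

        # 1. deletions and merges ------------------------------------------
        for pacc in sorted(prev.precursors):
            if pacc in touched:
                continue
            u = rng.random()
            if u < p.p_delete:
                touched.add(pacc)
                prec, orphans = remove_precursor(pacc, None)
                for mrec in orphans:
                    dead[mrec.accession] = DeadEntry(
                        mrec.accession, last_name=mrec.name)
                    note(mrec.accession, "mature", {"DELETED"},
                         old=(mrec.name, mrec.sequence))
                self.dead_payload[pacc] = (prec, orphans)
            elif u < p.p_delete + p.p_merge:
                targets = [a for a in sorted(snap.precursors)
                           if a != pacc and a not in touched]
                if not targets:
                    continue
                target = rng.choice(targets)
                touched.add(pacc)
                touched.add(target)
                _, orphans = remove_precursor(pacc, target)
                tmat = sorted(
                    ft.mature_accession
                    for ft in snap.precursors[target].mature_features
                    if ft.mature_accession in snap.matures
                )
                for mrec in orphans:
                    fw = tmat[0] if tmat else None
                    dead[mrec.accession] = DeadEntry(
                        mrec.accession, last_name=mrec.name, forward_to=fw)
                    note(mrec.accession, "mature",
                         {"MERGED"} if fw else {"DELETED"},
                         old=(mrec.name, mrec.sequence), merge_target=fw or "")

        # 2. resurrections --------------------------------------------------
        for pacc in sorted(self.dead_payload):
            if pacc not in dead or pacc in touched:
                continue
            if rng.random() >= p.p_resurrect:
                continue
            prec, orphans = self.dead_payload.pop(pacc)
            prec = copy.deepcopy(prec)
            revived = [copy.deepcopy(m) for m in orphans
                       if m.accession in dead and m.accession not in touched]
            prec.mature_features = [ft for ft in prec.mature_features
                                    if ft.mature_accession in
                                    {m.accession for m in revived}]
            if not revived:
                continue
            snap.precursors[pacc] = prec
            dead.pop(pacc)
            touched.add(pacc)
            note(pacc, "precursor", {"RESURRECTED"},
                 new=(prec.name, prec.sequence))
            for mrec in revived:
                mrec.parent_precursors = [pacc]
                snap.matures[mrec.accession] = mrec
                dead.pop(mrec.accession)
                touched.add(mrec.accession)
                note(mrec.accession, "mature", {"RESURRECTED"},
                     new=(mrec.name, mrec.sequence))

        # 3. precursor renames ---------------------------------------------
        active_names = {r.name for r in snap.precursors.values()} | {
            r.name for r in snap.matures.values()}
        for pacc in sorted(snap.precursors):
            if pacc in touched or rng.random() >= p.p_rename:
                continue
            prec = snap.precursors[pacc]
            g = _NAME_RE.match(prec.name).groupdict()
            mode = "add-family-letter" if not g["fam"] else "add-locus-number"
            try:
                new_name = name_mutator(prec.name, mode,
                                        locus=rng.randint(1, 3))
            except ValueError:
                continue
            if new_name == prec.name or new_name in active_names:
                continue
            note(pacc, "precursor", {"NAME_CHANGE"},
                 old=(prec.name, prec.sequence), new=(new_name, prec.sequence))
            active_names.discard(prec.name)
            active_names.add(new_name)
            prec.name = new_name
            touched.add(pacc)

        # 4. mature renames (rewrites parent FT /product too) ---------------
        for macc in sorted(snap.matures):
            if macc in touched or rng.random() >= p.p_rename:
                continue
            mrec = snap.matures[macc]
            g = _NAME_RE.match(mrec.name).groupdict()
            if not g["arm"]:
                mode, kw = "add-arm-suffix", {"arm": rng.choice(["5p", "3p"])}
            elif not g["fam"]:
                mode, kw = "add-family-letter", {}
            else:
                mode, kw = "add-locus-number", {"locus": rng.randint(1, 3)}
            try:
                new_name = name_mutator(mrec.name, mode, **kw)
            except ValueError:
                continue
            if new_name == mrec.name or new_name in active_names:
                continue
            note(macc, "mature", {"NAME_CHANGE"},
                 old=(mrec.name, mrec.sequence), new=(new_name, mrec.sequence))
            for pacc in mrec.parent_precursors:
                prec = snap.precursors[pacc]
                for ft in prec.mature_features:
                    if ft.mature_accession == macc:
                        ft.product_name = new_name
                note(pacc, "precursor", {"RELATION_CHANGE"},
                     old=(prec.name, prec.sequence),
                     new=(prec.name, prec.sequence))
            active_names.discard(mrec.name)
            active_names.add(new_name)
            mrec.name = new_name
            touched.add(macc)

        # 5. mature sequence changes ---------------------------------------
        for macc in sorted(snap.matures):
            if macc in touched or rng.random() >= p.p_seqchange:
                continue
            mrec = snap.matures[macc]
            if len(mrec.parent_precursors) != 1:
                continue
            pacc = mrec.parent_precursors[0]
            if pacc in touched:
                continue
            prec = snap.precursors[pacc]
            ft = next(f for f in prec.mature_features
                      if f.mature_accession == macc)
            old = (mrec.name, mrec.sequence)
            old_prec_seq = prec.sequence
            if rng.random() < 0.5:
                # end-shift of 1-2 nt at the 3' end (isomiR-like)
                delta = rng.choice([-2, -1, 1, 2])
                new_end = ft.end + delta
                mlen = new_end - ft.start + 1
                others = [f for f in prec.mature_features if f is not ft]
                if not (18 <= mlen <= 26) or new_end > len(prec.sequence):
                    continue
                if any(f.start <= new_end <= f.end for f in others):
                    continue
                ft.end = new_end
                mrec.sequence = prec.feature_substring(ft)
                note(macc, "mature", {"SEQUENCE_CHANGE"}, old=old,
                     new=(mrec.name, mrec.sequence))
                note(pacc, "precursor", {"RELATION_CHANGE"},
                     old=(prec.name, old_prec_seq),
                     new=(prec.name, prec.sequence))
            else:
                # one point substitution, in the seed (positions 2-8) with
                # probability p_seed_region_hit
                if rng.random() < p.p_seed_region_hit:
                    pos = rng.randint(2, 8)  # 1-based within the mature
                else:
                    pos = rng.randint(9, len(mrec.sequence))
                offset = ft.start - 1 + pos - 1  # 0-based in the precursor
                old_base = prec.sequence[offset]
                new_base = rng.choice([b for b in _BASES if b != old_base])
                prec.sequence = (prec.sequence[:offset] + new_base
                                 + prec.sequence[offset + 1:])
                mrec.sequence = prec.feature_substring(ft)
                # other arm is disjoint by construction; refresh defensively
                for f in prec.mature_features:
                    if f is not ft and f.mature_accession in snap.matures:
                        snap.matures[f.mature_accession].sequence = \
                            prec.feature_substring(f)
                note(macc, "mature", {"SEQUENCE_CHANGE"}, old=old,
                     new=(mrec.name, mrec.sequence))
                note(pacc, "precursor", {"SEQUENCE_CHANGE"},
                     old=(prec.name, old_prec_seq),
                     new=(prec.name, prec.sequence))
            touched.add(macc)
            touched.add(pacc)

        # 6. relink: a mature gains a second parent precursor ---------------
        for macc in sorted(snap.matures):
            if macc in touched or rng.random() >= p.p_relink:
                continue
            mrec = snap.matures[macc]
            if len(mrec.parent_precursors) != 1:
                continue
            sp = mrec.species_code
            cands = [a for a in sorted(snap.precursors)
                     if a not in touched and a not in mrec.parent_precursors
                     and snap.precursors[a].species_code == sp]
            if not cands:
                continue
            qacc = rng.choice(cands)
            q = snap.precursors[qacc]
            mlen = len(mrec.sequence)
            spans = [(f.start, f.end) for f in q.mature_features]
            valid = [s for s in range(1, len(q.sequence) - mlen + 2)
                     if not any(s <= e and s + mlen - 1 >= b for b, e in spans)]
            if not valid:
                continue
            start = rng.choice(valid)
            old_q_seq = q.sequence
            q.sequence = (q.sequence[:start - 1] + mrec.sequence
                          + q.sequence[start - 1 + mlen:])
            q.mature_features.append(MatureFeature(
                product_name=mrec.name, start=start, end=start + mlen - 1,
                mature_accession=macc, evidence="experimental"))
            mrec.parent_precursors = sorted(mrec.parent_precursors + [qacc])
            note(macc, "mature", {"RELATION_CHANGE"},
                 old=(mrec.name, mrec.sequence), new=(mrec.name, mrec.sequence))
            note(qacc, "precursor", {"SEQUENCE_CHANGE", "RELATION_CHANGE"},
                 old=(q.name, old_q_seq), new=(q.name, q.sequence))
            touched.add(macc)
            touched.add(qacc)

        # 7. additions ------------------------------------------------------
        n_add = sum(1 for _ in range(len(prev.precursors))
                    if rng.random() < p.p_add)
        retired = sorted(
            d.last_name for d in dead.values()
            if d.accession.startswith("MI") and not d.accession.startswith("MIMAT")
            and d.last_name and d.last_name not in active_names
        )
        for i in range(n_add):
            species = rng.choice(self.species)
            reuse = None
            if p.reissue_retired_name and i == 0 and retired:
                reuse = rng.choice(retired)
                species = reuse.split("-", 1)[0]
            prec, mats = self._new_precursor(snap, species, name=reuse)
            snap.precursors[prec.accession] = prec
            note(prec.accession, "precursor", {"ADDED"},
                 new=(prec.name, prec.sequence))
            active_names.add(prec.name)
            for mrec in mats:
                snap.matures[mrec.accession] = mrec
                note(mrec.accession, "mature", {"ADDED"},
                     new=(mrec.name, mrec.sequence))
                active_names.add(mrec.name)

        snap.dead = sorted(dead.values(), key=lambda d: d.accession)
        snap.validate()
        for acc in sorted(noted):
            e = noted[acc]
            # a terminal removal supersedes changes accumulated earlier in
            # the same transition (e.g. RELATION_CHANGE from losing one
            # parent, then DELETED on losing the last)
            types = e["types"]
            if "DELETED" in types:
                types = {"DELETED"}
            elif "MERGED" in types:
                types = {"MERGED"}
            self.log.events.append(GroundTruthEvent(
                label, acc, e["mol"], frozenset(types),
                old_name=e["old_name"], new_name=e["new_name"],
                old_sequence=e["old_seq"], new_sequence=e["new_seq"],
                merge_target=e["merge_target"]))
        return snap


def simulate_snapshots(
    params: SimulationParams,
) -> tuple[list[ReleaseSnapshot], GroundTruthLog]:
    """In-memory simulation: canonical-accession snapshots plus ground truth."""
    return _Simulator(params).run()


def _strip_mature_accessions(snap: ReleaseSnapshot) -> ReleaseSnapshot:
    out = copy.deepcopy(snap)
    matures = {}
    for m in out.matures.values():
        m.accession = None
        if m.key() in matures:
            raise ValueError(
                f"cannot strip accessions in {snap.release_label}: two matures "
                f"share local key {m.local_key()}"
            )
        matures[m.key()] = m
    out.matures = matures
    for p in out.precursors.values():
        for ft in p.mature_features:
            ft.mature_accession = None
    return out


def simulate_release_series(
    params: SimulationParams, out_dir
) -> tuple[list[Path], GroundTruthLog]:
    """Simulate and write a release series in the three-file dialect.

    Returns the per-release directories (named by release label) and the
    ground-truth log, which is also written to ``ground_truth.tsv`` and
    ``ground_truth.json`` under *out_dir*.  Deterministic given
    ``params.rng_seed``: identical params and seed give byte-identical files.
    Releases before ``accession_epoch`` are written without mature
    accessions (pre-6.0 era).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshots, log = simulate_snapshots(params)
    dirs = []
    for idx, snap in enumerate(snapshots, start=1):
        d = out_dir / snap.release_label
        emit = _strip_mature_accessions(snap) if idx < params.accession_epoch else snap
        write_release(emit, d)
        dirs.append(d)
    log.write(out_dir)
    return dirs, log
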