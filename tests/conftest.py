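import pytest

from mirtrack.event_store import build_store_from_snapshots
from mirtrack.records import (
    MatureFeature,
    MatureRecord,
    PrecursorRecord,
    ReleaseSnapshot,
)
from mirtrack.synthetic_releases import SimulationParams, simulate_snapshots


def make_precursor(accession="MI0000001", name="hsa-mir-1",
                   sequence="ACGU" * 20, features=()):
    return PrecursorRecord(
        accession=accession, name=name, sequence=sequence,
        description="Homo sapiens mir-1 stem-loop",
        species_name="Homo sapiens",
        mature_features=list(features),
    )


def make_snapshot(label="1.0"):
    """Two precursors, three matures; enough to exercise joins and diffs."""
    p1 = make_precursor(
        "MI0000001", "hsa-mir-1", "ACGUACGUACGUACGUACGUACGUACGUACGU"
        "GGGCCCAAAUUUGGGCCCAAAUUUGGGCCCAA",
        [MatureFeature("hsa-miR-1-5p", 2, 23, "MIMAT0000001", "experimental"),
         MatureFeature("hsa-miR-1-3p", 40, 61, "MIMAT0000002", "experimental")],
    )
    p2 = make_precursor(
        "MI0000002", "mmu-mir-2",
        "UUUUAAAACCCCGGGGUUUUAAAACCCCGGGGUUUUAAAACCCCGGGGUUUUAAAACCCC",
        [MatureFeature("mmu-miR-2", 5, 26, "MIMAT0000003", "experimental")],
    )
    p2.description = "Mus musculus mir-2 stem-loop"
    p2.species_name = "Mus musculus"
    snap = ReleaseSnapshot(release_label=label)
    for p in (p1, p2):
        snap.precursors[p.accession] = p
        for ft in p.mature_features:
            m = MatureRecord(
                name=ft.product_name, sequence=p.feature_substring(ft),
                accession=ft.mature_accession, parent_precursors=[p.accession],
            )
            snap.matures[m.accession] = m
    snap.validate()
    return snap


@pytest.fixture
def tiny_snapshot():
    return make_snapshot()


@pytest.fixture(scope="session")
def default_series():
    """A 6-release simulated series with every event type enabled."""
    params = SimulationParams(
        n_releases=6, n_initial_precursors=40, rng_seed=7,
        p_delete=0.03, p_merge=0.02, p_relink=0.02, p_resurrect=0.05,
    )
    return simulate_snapshots(params)


@pytest.fixture(scope="session")
def default_store(default_series):
    snaps, _log = default_series
    return build_store_from_snapshots(snaps)
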