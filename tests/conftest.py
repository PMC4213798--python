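"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mlclust import (
    ComparisonLedger,
    FamilySpec,
    ReferencePartition,
    SequenceRecord,
    SimilarityEngine,
    generate_families,
)


def make_record(sid: str, length: int = 10, residues: str | None = None) -> SequenceRecord:
    """Dummy record for tests driven by stipulated similarities."""
    return SequenceRecord(sid, residues if residues is not None else "A" * length)


def dict_engine(sims: dict, ledger: ComparisonLedger | None = None, default: float = 0.0):
    """Engine over stipulated similarities keyed by (id, id) pairs."""
    return SimilarityEngine.from_table(sims, ledger=ledger, default=default)


def random_instance(rng: np.random.Generator, n: int):
    """Random similarity table over n dummy records."""
    recs = [make_record(f"s{i:03d}") for i in range(n)]
    sims = {
        (recs[i].id, recs[j].id): float(rng.random())
        for i in range(n)
        for j in range(i + 1, n)
    }
    return recs, sims


def two_tier_families(
    n_super: int = 5,
    families: int = 5,
    per_family: int = 20,
    length=(130, 160),
    seed: int = 7,
):
    """Hierarchical planted structure: superfamilies of families.

    Superfamily roots are mutually unrelated (independent draws); families
    inside a superfamily sit at the generator's between-identity; members at
    its within-identity.  Ids and labels are prefixed per superfamily.
    """
    records, labels = [], {}
    for s in range(n_super):
        spec = FamilySpec(
            num_families=families,
            seqs_per_family=per_family,
            seq_length=length,
            within_identity=0.99,
            between_identity=0.70,
            seed=seed + s,
        )
        recs, truth = generate_families(spec)
        lab = truth.labels
        for r in recs:
            nid = f"G{s}{r.id}"
            records.append(SequenceRecord(nid, r.residues, r.description))
            labels[nid] = f"G{s}" + lab[r.id]
    return records, ReferencePartition(labels)


@pytest.fixture(scope="session")
def small_planted():
    """Flat planted dataset small enough for full-matrix runs in tests."""
    spec = FamilySpec(
        num_families=6, seqs_per_family=6, seq_length=(90, 110),
        within_identity=0.99, between_identity=0.70, seed=42,
    )
    return generate_families(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140630)
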