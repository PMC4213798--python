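"""Clustering quality (F-measure) and cost (f-value) statistics.

Quality is judged against a curated reference partition with the clustering
F-measure: for each reference class, the best harmonic-mean overlap with
any predicted cluster is found, and the class scores are averaged weighted
by class size,

    F(K, C) = (1/n) * sum_j n^j * max_i [ 2 * n_i^j / (n_i + n^j) ]

where n_i is the size of predicted cluster K_i, n^j the size of reference
class C_j and n_i^j their overlap.  F is 1 exactly when the clustering
reproduces the reference, 0 when it shares nothing with it.

Cost is the f-value: pairwise comparisons actually performed divided by the
N(N-1)/2 needed for a full half similarity matrix.  Any full-matrix method
(CCBC, or MLC1 with blocking disabled) has f = 1 on a cold cache.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import Partition
from .errors import InvalidInputError
from .multilevel import MLCConfig, run_algorithm
from .seqsim import ComparisonLedger, SequenceRecord, SimilarityEngine, SimilarityParams

__all__ = [
    "ReferencePartition",
    "EvaluationResult",
    "f_measure",
    "f_value",
    "optimal_threshold_scan",
    "ScanResult",
]

_HEADER_TOKENS = {"id", "sequence_id", "sequence-id", "seqid", "seq_id", "name"}


class ReferencePartition:
    """Reference (gold standard) labels: every id maps to exactly one class."""

    def __init__(self, labels: dict[str, str]):
        if not all(labels.values()):
            raise InvalidInputError("reference labels must be non-empty")
        self._labels = dict(labels)

    @classmethod
    def from_pairs(cls, pairs) -> "ReferencePartition":
        labels: dict[str, str] = {}
        for sid, label in pairs:
            if sid in labels:
                raise InvalidInputError(f"duplicate id in reference: {sid!r}")
            labels[sid] = label
        return cls(labels)

    @classmethod
    def from_tsv(cls, path) -> "ReferencePartition":
        """Two-column tab-separated (sequence id, class label); optional header."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InvalidInputError(
                        f"{path}:{lineno}: expected two tab-separated columns"
                    )
                if lineno == 1 and fields[0].strip().lower() in _HEADER_TOKENS:
                    continue
                pairs.append((fields[0].strip(), fields[1].strip()))
        return cls.from_pairs(pairs)

    @property
    def labels(self) -> dict[str, str]:
        return dict(self._labels)

    def ids(self) -> set[str]:
        return set(self._labels)

    def classes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, label in self._labels.items():
            out.setdefault(label, []).append(sid)
        return out

    def __len__(self) -> int:
        return len(self._labels)


@dataclass(frozen=True)
class EvaluationResult:
    """Quality and cost of one clustering run at one threshold."""

    threshold: float
    f_measure: float
    f_value: float
    comparisons: int
    groups: int


def f_measure(partition: Partition, reference: ReferencePartition) -> float:
    """Size-weighted best harmonic-mean overlap of clusters vs classes.

    Bounded in [0, 1]; 1 for a partition identical to the reference up to
    labels; invariant under cluster relabeling.  The two partitions must
    cover the same id set.
    """
    pred = partition.labels()
    ref = reference.labels
    if set(pred) != set(ref):
        raise InvalidInputError(
            "partition and reference cover different id sets "
            f"({len(pred)} vs {len(ref)} ids)"
        )
    n = len(ref)
    if n == 0:
        raise InvalidInputError("cannot evaluate an empty partition")
    ids = sorted(ref)
    ki, _ = pd.factorize(np.asarray([pred[i] for i in ids], dtype=object))
    cj, _ = pd.factorize(np.asarray([ref[i] for i in ids], dtype=object))
    cont = np.zeros((ki.max() + 1, cj.max() + 1))
    np.add.at(cont, (ki, cj), 1)
    n_i = cont.sum(axis=1)  # predicted cluster sizes
    n_j = cont.sum(axis=0)  # reference class sizes
    harm = 2.0 * cont / (n_i[:, None] + n_j[None, :])
    return float((n_j * harm.max(axis=0)).sum() / n)


def f_value(ledger_or_count, n: int) -> float:
    """Comparisons performed divided by the half-matrix count N(N-1)/2."""
    if n < 2:
        raise InvalidInputError("f-value needs at least 2 sequences")
    count = (
        ledger_or_count.comparisons
        if isinstance(ledger_or_count, ComparisonLedger)
        else int(ledger_or_count)
    )
    if count < 0:
        raise InvalidInputError("comparison count must be non-negative")
    return count / (n * (n - 1) / 2)


@dataclass(frozen=True)
class ScanResult:
    """Outcome of an optimal-threshold scan."""

    t_star: float
    f_star: float
    table: pd.DataFrame


def optimal_threshold_scan(
    seqs: list[SequenceRecord],
    reference: ReferencePartition,
    grid,
    algorithm: str = "ccbc",
    *,
    config: MLCConfig | None = None,
    params: SimilarityParams | None = None,
    start_threshold: float | None = None,
    ordering="length",
    engine_factory=None,
) -> ScanResult:
    """Cluster at every grid threshold and pick the F-measure argmax.

    Each threshold gets a fresh ledger (cost is per run, cold cache), so
    the per-threshold table reports an honest f-value for every point.
    Ties at the maximum go to the lowest threshold.  ``engine_factory``
    (ledger -> engine) lets callers swap the similarity backend.
    """
    grid = [float(t) for t in grid]
    if not grid:
        raise InvalidInputError("threshold grid must not be empty")
    for t in grid:
        if not 0.0 <= t <= 1.0:
            raise InvalidInputError(f"grid threshold {t} outside [0, 1]")
    rows = []
    n = len(seqs)
    for t in grid:
        ledger = ComparisonLedger()
        if engine_factory is not None:
            engine = engine_factory(ledger)
        else:
            engine = SimilarityEngine(params, ledger)
        part = run_algorithm(
            algorithm, seqs, t,
            engine=engine, config=config,
            start_threshold=start_threshold, ordering=ordering,
        )
        rows.append(
            EvaluationResult(
                threshold=t,
                f_measure=f_measure(part, reference),
                f_value=f_value(ledger, n) if n >= 2 else float("nan"),
                comparisons=ledger.comparisons,
                groups=len(part),
            )
        )
    table = pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "f_measure": [r.f_measure for r in rows],
            "f_value": [r.f_value for r in rows],
            "comparisons": [r.comparisons for r in rows],
            "groups": [r.groups for r in rows],
        }
    )
    best = min(rows, key=lambda r: (-r.f_measure, r.threshold))
    return ScanResult(t_star=best.threshold, f_star=best.f_measure, table=table)
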