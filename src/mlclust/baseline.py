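"""Single-level reference clusterings: greedy (GC) and connected components (CCBC).

GC is the UCLUST/CD-HIT scheme: scan length-sorted sequences once, joining
each to the first earlier representative within the similarity threshold or
founding a new cluster — O(N·m) comparisons for m clusters, fast but not
transitive.  CCBC clusters are the connected components of the threshold
graph (edges = pairs with similarity >= t), which in the worst case needs
every one of the N(N-1)/2 pairwise similarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import InvalidInputError
from .seqsim import (
    ComparisonLedger,
    SequenceRecord,
    SimilarityEngine,
    SimilarityMatrix,
    half_matrix,
)

__all__ = [
    "Cluster",
    "Partition",
    "order_by_decreasing_length",
    "greedy_cluster",
    "ccbc_cluster",
    "preorder_by_gc",
]

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A group of sequence ids with one member acting as representative."""

    cluster_id: int
    member_ids: list[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise InvalidInputError("cluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise InvalidInputError(
                f"representative {self.representative_id!r} is not a member of "
                f"cluster {self.cluster_id}"
            )

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Partition:
    """A set of disjoint clusters covering a dataset exactly."""

    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def ids(self) -> set[str]:
        return {m for c in self.clusters for m in c.member_ids}

    def labels(self) -> dict[str, int]:
        """Mapping of sequence id to cluster id."""
        return {m: c.cluster_id for c in self.clusters for m in c.member_ids}

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def as_sets(self) -> set[frozenset]:
        return {frozenset(c.member_ids) for c in self.clusters}

    def same_grouping(self, other: "Partition") -> bool:
        """True when both partitions group ids identically, labels aside."""
        return self.as_sets() == other.as_sets()

    def validate(self, expected_ids: set[str] | None = None) -> None:
        """Check the disjoint-cover invariant; raise on violation."""
        seen: set[str] = set()
        for c in self.clusters:
            members = set(c.member_ids)
            if len(members) != len(c.member_ids):
                raise InvalidInputError(f"cluster {c.cluster_id} repeats a member")
            if members & seen:
                raise InvalidInputError(
                    f"cluster {c.cluster_id} overlaps another cluster"
                )
            seen |= members
        if expected_ids is not None and seen != set(expected_ids):
            raise InvalidInputError("partition does not cover the dataset exactly")


def _check_threshold(t: float) -> None:
    if not 0.0 <= t <= 1.0:
        raise InvalidInputError(f"threshold must be in [0, 1], got {t}")


def order_by_decreasing_length(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Sort by decreasing length, ties broken by ascending id (stable)."""
    return sorted(seqs, key=lambda s: (-s.length, s.id))


def greedy_cluster(
    seqs: list[SequenceRecord],
    t: float,
    engine: SimilarityEngine | None = None,
    *,
    best_match: bool = False,
) -> Partition:
    """Greedy clustering over an already-ordered sequence list.

    The first sequence founds the first cluster; each later sequence joins
    the first representative (in creation order) with similarity >= t, or
    founds a new cluster.  With ``best_match`` every representative is
    scored and the most similar one wins (ties to the earlier one).
    """
    _check_threshold(t)
    if engine is None:
        engine = SimilarityEngine()
    reps: list[tuple[SequenceRecord, Cluster]] = []
    clusters: list[Cluster] = []
    for rec in seqs:
        chosen: Cluster | None = None
        best = -1.0
        for rep_rec, cluster in reps:
            s = engine.similarity(rec, rep_rec)
            if s >= t:
                if not best_match:
                    chosen = cluster
                    break
                if s > best:
                    best, chosen = s, cluster
        if chosen is not None:
            chosen.member_ids.append(rec.id)
        else:
            cluster = Cluster(len(clusters), [rec.id], rec.id)
            clusters.append(cluster)
            reps.append((rec, cluster))
    return Partition(clusters)


def ccbc_cluster(
    seqs: list[SequenceRecord],
    t: float,
    engine: SimilarityEngine | None = None,
    *,
    matrix: SimilarityMatrix | None = None,
    rep_mode: str = "almost-central",
    rep_k: int = 10,
) -> Partition:
    """Connected components of the threshold graph.

    When no precomputed matrix is supplied the full half matrix is computed
    (in ledger-bounded batches), so a cold-cache run performs exactly
    N(N-1)/2 comparisons — the f-value of a full-matrix method is 1.  Each
    cluster's representative is its almost-central member, found by reading
    the already-computed similarities (no extra comparisons).
    """
    _check_threshold(t)
    if engine is None:
        engine = SimilarityEngine()
    if not seqs:
        return Partition([])
    if matrix is None:
        matrix = half_matrix(seqs, engine=engine)
    n = len(seqs)
    if n == 1:
        return Partition([Cluster(0, [seqs[0].id], seqs[0].id)])
    ii, jj = np.triu_indices(n, k=1)
    keep = matrix.values >= t
    graph = sparse.coo_matrix(
        (np.ones(int(keep.sum()), dtype=np.int8), (ii[keep], jj[keep])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    # number clusters by first member appearance in the input order
    order: dict[int, int] = {}
    members: dict[int, list[SequenceRecord]] = {}
    for rec, c in zip(seqs, comp):
        if c not in order:
            order[c] = len(order)
            members[c] = []
        members[c].append(rec)
    from .multilevel import select_representative  # deferred: avoids cycle

    mview = engine.with_matrix(matrix)
    clusters = []
    for c, idx in order.items():
        group = members[c]
        rep = select_representative(
            group, group[0].id, mode=rep_mode, k=rep_k, engine=mview
        )
        clusters.append(Cluster(idx, [r.id for r in group], rep))
    return Partition(clusters)


def preorder_by_gc(
    seqs: list[SequenceRecord],
    low_t: float,
    engine: SimilarityEngine | None = None,
) -> list[SequenceRecord]:
    """Reorder sequences by a cheap low-threshold greedy pre-clustering.

    Runs GC at ``low_t`` on the length-ordered input and emits sequences
    grouped by pre-cluster (clusters in creation order; within each, the
    representative first, then members in assignment order).  The
    comparisons spent here land on the shared ledger, so downstream
    f-values include the pre-clustering cost.
    """
    _check_threshold(low_t)
    if engine is None:
        engine = SimilarityEngine()
    ordered = order_by_decreasing_length(seqs)
    part = greedy_cluster(ordered, low_t, engine)
    recmap = {r.id: r for r in seqs}
    return [recmap[m] for c in part.clusters for m in c.member_ids]
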