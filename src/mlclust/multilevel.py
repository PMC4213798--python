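"""Multi-level threshold clustering: MLC1, MLC and rMLC.

The multi-level family avoids most pairwise comparisons by clustering
through representatives:

* **MLC1** — partition the (ordered) input into blocks, greedy-cluster each
  block at the target threshold, pick one representative per block-group,
  run CCBC over the representatives only, and finally pool the groups whose
  representatives landed in the same component.
* **MLC** — iterate MLC1 over an increasing threshold schedule ending at
  the target threshold t: coarse groups found at a low threshold are
  re-clustered at progressively higher thresholds, and any group smaller
  than the cutoff ``s`` is finalized directly at t.
* **rMLC** — MLC that recurses on itself wherever MLC1 would have to
  cluster a sequence set larger than ``M`` (a block, or the representative
  set), keeping every individual clustering problem small.

Representatives matter: a group is ideally represented by its *central*
sequence (the member maximizing summed similarity to the others), which is
quadratic in the group size; the *almost-central* sequence is the centre of
a k-element subset sampled at evenly spaced ranks of similarity to the
group's greedy representative, bounding the cost at O(k^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .baseline import (
    Cluster,
    Partition,
    _check_threshold,
    ccbc_cluster,
    greedy_cluster,
    order_by_decreasing_length,
    preorder_by_gc,
)
from .errors import InvalidInputError
from .seqsim import SequenceRecord, SimilarityEngine

__all__ = [
    "MLCConfig",
    "ThresholdSchedule",
    "central_representative",
    "almost_central_representative",
    "select_representative",
    "partition_into_blocks",
    "threshold_schedule",
    "mlc1",
    "mlc",
    "rmlc",
    "resolve_ordering",
    "run_algorithm",
    "ALGORITHMS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLCConfig:
    """Tunable knobs of the multi-level algorithms.

    ``block_size`` is the number of sequences per MLC1 block; when None,
    ``block_fraction`` of the input size is used (default 1/10, the setting
    that makes MLC1's optimal threshold reproducible).  ``block_size=0`` is
    the degenerate signal "no blocking": MLC1 then is plain CCBC and its
    f-value is 1.  ``k`` is the subset size of the almost-central
    representative; ``s`` the group size below which MLC finalizes a group
    directly at the target threshold; ``M`` the set size above which rMLC
    recurses instead of calling MLC1.
    """

    block_size: int | None = None
    block_fraction: float = 0.1
    k: int = 10
    s: int = 300
    M: int = 1000
    rep_mode: str = "almost-central"
    gc_best_match: bool = False

    def __post_init__(self) -> None:
        if self.block_size is not None and self.block_size < 0:
            raise InvalidInputError("block_size must be >= 0")
        if not 0 < self.block_fraction <= 1:
            raise InvalidInputError("block_fraction must be in (0, 1]")
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        if self.s < 1:
            raise InvalidInputError("s must be >= 1")
        if self.M < self.s:
            raise InvalidInputError("M must be >= s")
        if self.rep_mode not in ("first", "central", "almost-central"):
            raise InvalidInputError(f"unknown rep_mode {self.rep_mode!r}")

    def resolve_block_size(self, n: int) -> int:
        if self.block_size is not None:
            return self.block_size
        return max(1, math.ceil(n * self.block_fraction))


@dataclass(frozen=True)
class ThresholdSchedule:
    """Strictly increasing thresholds t1 < ... < tn, ending at the target."""

    thresholds: tuple

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if not ts:
            raise InvalidInputError("threshold schedule must not be empty")
        for t in ts:
            _check_threshold(t)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InvalidInputError(f"schedule must be strictly increasing: {ts}")
        object.__setattr__(self, "thresholds", ts)

    @property
    def final(self) -> float:
        return self.thresholds[-1]

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


def as_schedule(schedule) -> ThresholdSchedule:
    if isinstance(schedule, ThresholdSchedule):
        return schedule
    if isinstance(schedule, (int, float)):
        return ThresholdSchedule((float(schedule),))
    return ThresholdSchedule(tuple(schedule))


def threshold_schedule(t_start: float, t_final: float, rule: str = "halve") -> ThresholdSchedule:
    """Default schedule: halve the remaining gap to the target each step.

    Steps stop once the remaining gap drops below 0.005, then the target is
    appended, so the schedule always ends exactly at ``t_final``.
    """
    _check_threshold(t_start)
    _check_threshold(t_final)
    if t_start > t_final:
        raise InvalidInputError(f"start threshold {t_start} exceeds target {t_final}")
    if rule != "halve":
        raise InvalidInputError(f"unknown schedule rule {rule!r}")
    if t_start == t_final:
        return ThresholdSchedule((t_final,))
    ts = [t_start]
    cur = t_start
    while t_final - cur >= 0.005:
        cur = cur + (t_final - cur) / 2
        if t_final - cur < 0.005:
            break
        ts.append(cur)
    ts.append(t_final)
    return ThresholdSchedule(tuple(ts))


# ---------------------------------------------------------------------------
# representatives


def central_representative(group: list[SequenceRecord], engine: SimilarityEngine) -> str:
    """Member maximizing the sum of similarities to all other members.

    Ties broken by ascending id; |group|(|group|-1)/2 comparisons on a cold
    cache.
    """
    if not group:
        raise InvalidInputError("cannot pick a representative of an empty group")
    if len(group) == 1:
        return group[0].id
    sums = {r.id: 0.0 for r in group}
    for i, a in enumerate(group):
        for b in group[i + 1 :]:
            s = engine.similarity(a, b)
            sums[a.id] += s
            sums[b.id] += s
    return min(group, key=lambda r: (-sums[r.id], r.id)).id


def almost_central_representative(
    group: list[SequenceRecord],
    gc_rep: str,
    k: int,
    engine: SimilarityEngine,
) -> str:
    """Centre of a k-member subset sampled across the similarity range.

    Members are ordered by descending similarity to the group's greedy
    representative (ties by id); k members at evenly spaced ranks are kept
    (the most similar one always included, so k=1 returns the member
    closest to ``gc_rep``) and the central sequence of that subset is
    returned.  Groups of at most k members fall back to the exact centre.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    ids = {r.id for r in group}
    if gc_rep not in ids:
        raise InvalidInputError(f"anchor {gc_rep!r} is not a member of the group")
    if len(group) <= k:
        return central_representative(group, engine)
    rep_rec = next(r for r in group if r.id == gc_rep)

    def sim_to_rep(r: SequenceRecord) -> float:
        return 1.0 if r.id == gc_rep else engine.similarity(r, rep_rec)

    ordered = sorted(group, key=lambda r: (-sim_to_rep(r), r.id))
    n = len(ordered)
    ranks = sorted({math.ceil(i * n / k) for i in range(k)})
    subset = [ordered[i] for i in ranks]
    return central_representative(subset, engine)


def select_representative(
    group: list[SequenceRecord],
    gc_rep: str,
    *,
    mode: str,
    k: int,
    engine: SimilarityEngine,
) -> str:
    """Dispatch on the representative mode (first / central / almost-central)."""
    if mode == "first":
        return gc_rep
    if mode == "central":
        return central_representative(group, engine)
    if mode == "almost-central":
        return almost_central_representative(group, gc_rep, k, engine)
    raise InvalidInputError(f"unknown rep_mode {mode!r}")


# ---------------------------------------------------------------------------
# orderings and blocks


def resolve_ordering(
    seqs: list[SequenceRecord],
    ordering,
    engine: SimilarityEngine,
) -> list[SequenceRecord]:
    """Materialize an input ordering.

    ``"given"`` keeps the caller's order, ``"length"`` sorts by decreasing
    length (the default of every published run), ``"name"`` sorts
    lexicographically by description then id (taxon-name preordering), and
    ``("gc", low_t)`` / ``"gc:<low_t>"`` pre-clusters greedily at a low
    threshold so that crudely similar sequences become contiguous.
    """
    if ordering in (None, "given"):
        return list(seqs)
    if ordering == "length":
        return order_by_decreasing_length(seqs)
    if ordering == "name":
        return sorted(seqs, key=lambda r: (r.description, r.id))
    if isinstance(ordering, str) and ordering.startswith("gc:"):
        ordering = ("gc", float(ordering[3:]))
    if isinstance(ordering, tuple) and len(ordering) == 2 and ordering[0] == "gc":
        return preorder_by_gc(seqs, float(ordering[1]), engine)
    raise InvalidInputError(f"unknown ordering {ordering!r}")


def partition_into_blocks(
    seqs: list[SequenceRecord], block_size: int
) -> list[list[SequenceRecord]]:
    """Contiguous chunks of the given ordering (last block may be smaller)."""
    if block_size < 0:
        raise InvalidInputError("block_size must be >= 0")
    if not seqs:
        return []
    if block_size == 0 or block_size >= len(seqs):
        return [list(seqs)]
    return [list(seqs[i : i + block_size]) for i in range(0, len(seqs), block_size)]


# ---------------------------------------------------------------------------
# MLC1


def _renumber(clusters: list[Cluster], order_index: dict[str, int]) -> Partition:
    clusters = sorted(clusters, key=lambda c: min(order_index[m] for m in c.member_ids))
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return Partition(clusters)


def mlc1(
    seqs: list[SequenceRecord],
    t: float,
    config: MLCConfig | None = None,
    engine: SimilarityEngine | None = None,
    *,
    ordering="length",
    _block_cluster=None,
    _rep_cluster=None,
) -> Partition:
    """One-level multi-level clustering.

    Blocks are greedy-clustered at ``t``; one representative per block-group
    is chosen per ``config.rep_mode``; CCBC at ``t`` over the representatives
    decides which groups merge; every final cluster is the union of its
    groups' members with a fresh almost-central representative.  With
    ``config.block_size == 0`` blocking is disabled and the result is plain
    CCBC over all sequences (full-matrix cost, f-value 1).
    """
    _check_threshold(t)
    config = config or MLCConfig()
    engine = engine or SimilarityEngine()
    recs = resolve_ordering(seqs, ordering, engine)
    if not recs:
        return Partition([])
    if config.block_size == 0:
        return ccbc_cluster(recs, t, engine, rep_mode=config.rep_mode, rep_k=config.k)
    recmap = {r.id: r for r in recs}
    if len(recmap) != len(recs):
        raise InvalidInputError("duplicate sequence ids in input")
    order_index = {r.id: i for i, r in enumerate(recs)}
    if _block_cluster is None:
        _block_cluster = lambda block, tt: greedy_cluster(
            block, tt, engine, best_match=config.gc_best_match
        )
    if _rep_cluster is None:
        _rep_cluster = lambda reps, tt: ccbc_cluster(
            reps, tt, engine, rep_mode=config.rep_mode, rep_k=config.k
        )

    blocks = partition_into_blocks(recs, config.resolve_block_size(len(recs)))
    groups: dict[str, list[SequenceRecord]] = {}  # rep id -> members
    rep_records: list[SequenceRecord] = []
    for block in blocks:
        part = _block_cluster(block, t)
        for cl in part.clusters:
            members = [recmap[m] for m in cl.member_ids]
            rep_id = select_representative(
                members,
                cl.representative_id,
                mode=config.rep_mode,
                k=config.k,
                engine=engine,
            )
            groups[rep_id] = members
            rep_records.append(recmap[rep_id])
    logger.debug(
        "mlc1 t=%.4f: %d blocks -> %d groups", t, len(blocks), len(rep_records)
    )

    rep_part = _rep_cluster(rep_records, t)
    clusters: list[Cluster] = []
    for cl in rep_part.clusters:
        members: list[SequenceRecord] = []
        for rid in cl.member_ids:
            members.extend(groups[rid])
        if len(cl.member_ids) == 1:
            rep_id = cl.member_ids[0]
        elif config.rep_mode == "first":
            rep_id = cl.representative_id
        else:
            # Recompute the centre of the merged cluster: over all members
            # while the union is small, over the constituent groups'
            # representatives otherwise (bounds the cost at O(k^2)).
            if len(members) <= config.k * 10:
                pool = members
            else:
                pool = [recmap[rid] for rid in cl.member_ids]
            rep_id = almost_central_representative(
                pool, cl.representative_id, config.k, engine
            )
        clusters.append(Cluster(0, [m.id for m in members], rep_id))
    return _renumber(clusters, order_index)


# ---------------------------------------------------------------------------
# MLC and rMLC


def _group_handoff(part: Partition, recmap: dict) -> list[list[SequenceRecord]]:
    """Present each cluster as a record list, representative first."""
    out = []
    for cl in part.clusters:
        rest = [recmap[m] for m in cl.member_ids if m != cl.representative_id]
        out.append([recmap[cl.representative_id]] + rest)
    return out


def mlc(
    seqs: list[SequenceRecord],
    schedule,
    config: MLCConfig | None = None,
    engine: SimilarityEngine | None = None,
    *,
    ordering="length",
) -> Partition:
    """Multi-level clustering over an increasing threshold schedule.

    One group (the whole input) enters level 1; at each level, groups
    smaller than ``config.s`` are finalized by MLC1 at the target threshold
    t, larger ones are clustered by MLC1 at the level's threshold and their
    subgroups passed on; after the last level every surviving group is
    finalized at t.
    """
    config = config or MLCConfig()
    engine = engine or SimilarityEngine()
    sched = as_schedule(schedule)
    t = sched.final
    recs = resolve_ordering(seqs, ordering, engine)
    if not recs:
        return Partition([])
    recmap = {r.id: r for r in recs}
    order_index = {r.id: i for i, r in enumerate(recs)}
    groups: list[list[SequenceRecord]] = [list(recs)]
    final: list[Cluster] = []
    for level, ti in enumerate(sched, start=1):
        nxt: list[list[SequenceRecord]] = []
        for g in groups:
            if len(g) < config.s:
                final.extend(
                    mlc1(g, t, config, engine, ordering="given").clusters
                )
            else:
                part = mlc1(g, ti, config, engine, ordering="given")
                nxt.extend(_group_handoff(part, recmap))
        logger.info(
            "mlc level %d (t=%.4f): %d groups in, %d pending, %d finalized, "
            "%d comparisons so far",
            level, ti, len(groups), len(nxt), len(final), engine.ledger.comparisons,
        )
        groups = nxt
    for g in groups:
        final.extend(mlc1(g, t, config, engine, ordering="given").clusters)
    return _renumber(final, order_index)


def _recursion_start(tau: float, prev_tau: float | None) -> float:
    # Never recurse below the surrounding schedule: descending further would
    # cluster through similarity bands the outer run has already resolved,
    # and a mixed coarse group is then misrepresented by its single centre.
    if prev_tau is not None and prev_tau < tau:
        return prev_tau
    return tau


def rmlc(
    seqs: list[SequenceRecord],
    schedule,
    config: MLCConfig | None = None,
    engine: SimilarityEngine | None = None,
    *,
    ordering="length",
) -> Partition:
    """Recursive MLC for inputs too large to feed MLC1 directly.

    Inputs of at most ``config.M`` sequences are handled by plain MLC.
    Above that, the MLC iteration runs as usual, but wherever MLC1 would
    cluster a set larger than M (a block in its step 1, or the
    representative set in its step 2) the algorithm recurses on that set
    with a fresh gap-halving schedule from the surrounding level's previous
    threshold up to the set's target threshold.  Every recursive call
    receives a strictly smaller set, so the recursion terminates; batch
    limits on the ledger bound each similarity-matrix computation.
    """
    config = config or MLCConfig()
    engine = engine or SimilarityEngine()
    sched = as_schedule(schedule)
    recs = resolve_ordering(seqs, ordering, engine)
    if len(recs) <= config.M:
        return mlc(recs, sched, config, engine, ordering="given")
    t = sched.final
    recmap = {r.id: r for r in recs}
    order_index = {r.id: i for i, r in enumerate(recs)}

    def recursive_mlc1(
        group: list[SequenceRecord], tau: float, prev_tau: float | None
    ) -> Partition:
        n_group = len(group)

        def block_cluster(block, tt):
            if config.M < len(block) < n_group:
                sub_sched = threshold_schedule(_recursion_start(tt, prev_tau), tt)
                return rmlc(block, sub_sched, config, engine, ordering="given")
            return greedy_cluster(block, tt, engine, best_match=config.gc_best_match)

        def rep_cluster(reps, tt):
            if config.M < len(reps) < n_group:
                sub_sched = threshold_schedule(_recursion_start(tt, prev_tau), tt)
                return rmlc(reps, sub_sched, config, engine, ordering="given")
            return ccbc_cluster(reps, tt, engine, rep_mode=config.rep_mode, rep_k=config.k)

        return mlc1(
            group, tau, config, engine,
            ordering="given", _block_cluster=block_cluster, _rep_cluster=rep_cluster,
        )

    groups: list[list[SequenceRecord]] = [list(recs)]
    final: list[Cluster] = []
    prev_tau: float | None = None
    for level, ti in enumerate(sched, start=1):
        nxt: list[list[SequenceRecord]] = []
        for g in groups:
            if len(g) < config.s:
                final.extend(recursive_mlc1(g, t, prev_tau).clusters)
            else:
                part = recursive_mlc1(g, ti, prev_tau)
                nxt.extend(_group_handoff(part, recmap))
        logger.info(
            "rmlc level %d (t=%.4f): %d groups in, %d pending, %d finalized, "
            "%d comparisons so far",
            level, ti, len(groups), len(nxt), len(final), engine.ledger.comparisons,
        )
        groups = nxt
        prev_tau = ti
    for g in groups:
        final.extend(recursive_mlc1(g, t, prev_tau).clusters)
    return _renumber(final, order_index)


# ---------------------------------------------------------------------------
# dispatch

ALGORITHMS = ("gc", "ccbc", "mlc1", "mlc", "rmlc")


def run_algorithm(
    name: str,
    seqs: list[SequenceRecord],
    threshold: float,
    *,
    engine: SimilarityEngine | None = None,
    config: MLCConfig | None = None,
    schedule=None,
    start_threshold: float | None = None,
    ordering="length",
) -> Partition:
    """Run one of the five clustering algorithms by name.

    ``schedule`` (explicit list) or ``start_threshold`` (gap-halving rule up
    to ``threshold``) configure mlc/rmlc; the other algorithms reject them.
    """
    name = name.lower()
    if name not in ALGORITHMS:
        raise InvalidInputError(
            f"unknown algorithm {name!r}; expected one of {ALGORITHMS}"
        )
    engine = engine or SimilarityEngine()
    config = config or MLCConfig()
    if name in ("gc", "ccbc", "mlc1") and (schedule is not None or start_threshold is not None):
        raise InvalidInputError(f"threshold schedules only apply to mlc/rmlc, not {name!r}")
    if name == "gc":
        ordered = resolve_ordering(seqs, ordering, engine)
        return greedy_cluster(ordered, threshold, engine, best_match=config.gc_best_match)
    if name == "ccbc":
        ordered = resolve_ordering(seqs, ordering, engine)
        return ccbc_cluster(ordered, threshold, engine, rep_mode=config.rep_mode, rep_k=config.k)
    if name == "mlc1":
        return mlc1(seqs, threshold, config, engine, ordering=ordering)
    if schedule is not None:
        sched = as_schedule(schedule)
        if sched.final != threshold:
            raise InvalidInputError(
                f"explicit schedule must end at the target threshold {threshold}"
            )
    else:
        start = threshold if start_threshold is None else start_threshold
        sched = threshold_schedule(start, threshold)
    fn = mlc if name == "mlc" else rmlc
    return fn(seqs, sched, config, engine, ordering=ordering)
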