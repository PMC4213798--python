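"""Pairwise percent-identity similarity with exact comparison accounting.

Every clustering algorithm in this package is driven by a single scalar:
the percent identity of the optimal pairwise alignment of two sequences
(identical columns divided by all alignment columns, gap columns included).
Alignments are computed by Biopython's :class:`Bio.Align.PairwiseAligner`
with BLAST-like defaults — local alignment, match +1 / mismatch -2,
gap open -5 / extend -2 for DNA, and BLOSUM62 with gap open -11 / extend -1
for proteins.  All scoring knobs are configurable because percent identity,
and hence every similarity threshold, depends on them.

The cost model of the clustering algorithms is the *number of pairwise
alignments performed*.  A :class:`ComparisonLedger` counts exactly that:
each unordered pair of sequence ids is counted once while its cache entry
is live, and the count is the numerator of the f-value cost statistic
(comparisons divided by N(N-1)/2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidInputError

__all__ = [
    "SequenceRecord",
    "SimilarityParams",
    "ComparisonLedger",
    "SimilarityEngine",
    "SimilarityMatrix",
    "percent_identity",
    "half_matrix",
]

logger = logging.getLogger(__name__)

# Residues accepted per mode; only the strict symbols count as identities
# (IUPAC ambiguity codes and N/X are treated as mismatches).
DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
DNA_STRICT = "ACGT"
PROTEIN_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVBZX*")
PROTEIN_STRICT = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence: the atom being clustered.

    The id must be a non-empty token, unique within a dataset; residues are
    stored uppercase and must be non-empty.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise InvalidInputError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise InvalidInputError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SimilarityParams:
    """Scoring contract behind percent identity.

    ``gap_open`` is the score of the first column of a gap, ``gap_extend``
    of each subsequent column.  In protein mode the BLOSUM62 matrix replaces
    ``match_score``/``mismatch_score``.  Identity is identical columns /
    alignment columns of the optimal alignment under these scores.

    ``scope`` chooses the alignment form.  The default ``semiglobal``
    (overlap) alignment leaves end gaps free and divides matches by the
    larger of the overlap column count and the shorter sequence's length —
    the identity definition of threshold-clustering practice, robust
    against the short spuriously clean segments that score-optimal local or
    dovetail alignments promote on weakly related pairs.  ``local`` reports
    the classic HSP identity, matches over the columns of the best local
    segment (0 when no positive-scoring one exists); ``global`` penalizes
    and counts end gaps.
    """

    mode: str = "dna"
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    scope: str = "semiglobal"

    def __post_init__(self) -> None:
        if self.mode not in ("dna", "protein"):
            raise InvalidInputError(f"mode must be 'dna' or 'protein', got {self.mode!r}")
        if self.scope not in ("local", "global", "semiglobal"):
            raise InvalidInputError(
                f"scope must be 'local', 'global' or 'semiglobal', got {self.scope!r}"
            )
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InvalidInputError("gap penalties must be <= 0")

    @classmethod
    def protein(cls, gap_open: int = -11, gap_extend: int = -1, scope: str = "semiglobal") -> "SimilarityParams":
        """BLOSUM62 protein scoring with BLAST-like gap penalties."""
        return cls(mode="protein", gap_open=gap_open, gap_extend=gap_extend, scope=scope)

    @property
    def alphabet(self) -> frozenset:
        return DNA_ALPHABET if self.mode == "dna" else PROTEIN_ALPHABET

    @property
    def strict_symbols(self) -> str:
        return DNA_STRICT if self.mode == "dna" else PROTEIN_STRICT


class ComparisonLedger:
    """Counts distinct pairwise alignments; basis of the f-value.

    ``comparisons`` increases monotonically and counts cache misses only: a
    given unordered id pair is counted at most once while its cache entry is
    live.  ``batch_limit`` caps how many pairs :func:`half_matrix` evaluates
    per batch (default 1,000,000, a cap that keeps peak memory modest on a
    desktop machine); batching never changes results.
    """

    def __init__(self, batch_limit: int = 1_000_000, cache: bool = True):
        if batch_limit < 1:
            raise InvalidInputError("batch_limit must be >= 1")
        self.comparisons = 0
        self.batch_limit = batch_limit
        self.cache: dict | None = {} if cache else None

    def record(self, n: int = 1) -> None:
        self.comparisons += n

    def lookup(self, key) -> float | None:
        if self.cache is None:
            return None
        return self.cache.get(key)

    def store(self, key, value: float) -> None:
        if self.cache is not None:
            self.cache[key] = value

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        size = "off" if self.cache is None else len(self.cache)
        return f"ComparisonLedger(comparisons={self.comparisons}, cache={size})"


def _build_aligner(params: SimilarityParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if params.scope == "local" else "global"
    if params.mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        # Custom matrix over the IUPAC DNA alphabet: only A/C/G/T self-matches
        # score as matches, every ambiguity code scores as a mismatch.
        alphabet = "".join(sorted(DNA_ALPHABET))
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
        mat[:, :] = params.mismatch_score
        for c in DNA_STRICT:
            mat[c, c] = params.match_score
        aligner.substitution_matrix = mat
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.scope == "semiglobal":
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _pair_key(id_a: str, id_b: str) -> tuple:
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


class SimilarityEngine:
    """Bundles similarity parameters, the ledger, and the pair cache.

    The default backend aligns sequences; tests and non-sequence use cases
    may inject any callable ``func(a, b) -> float`` instead (the multi-level
    algorithms only ever see this interface, which is what makes them
    applicable to arbitrary similarity functions).
    """

    def __init__(
        self,
        params: SimilarityParams | None = None,
        ledger: ComparisonLedger | None = None,
        func=None,
    ):
        self.params = params if params is not None else SimilarityParams()
        self.ledger = ledger if ledger is not None else ComparisonLedger()
        self._func = func
        self._aligner = None if func is not None else _build_aligner(self.params)
        self._strict = (
            None
            if func is not None
            else np.frombuffer(self.params.strict_symbols.encode("ascii"), dtype="S1")
        )
        self._validated: set = set()

    @classmethod
    def from_table(
        cls,
        table: dict,
        ledger: ComparisonLedger | None = None,
        default: float = 0.0,
    ) -> "SimilarityEngine":
        """Engine over stipulated similarities keyed by unordered id pairs."""
        norm = {_pair_key(*k): float(v) for k, v in table.items()}

        def func(a: SequenceRecord, b: SequenceRecord) -> float:
            if a.id == b.id:
                return 1.0
            return norm.get(_pair_key(a.id, b.id), default)

        return cls(ledger=ledger, func=func)

    # -- computation -------------------------------------------------------

    def _validate(self, rec: SequenceRecord) -> None:
        if rec.id in self._validated:
            return
        bad = set(rec.residues) - self.params.alphabet
        if bad:
            raise InvalidInputError(
                f"sequence {rec.id!r} contains symbols {sorted(bad)} not valid "
                f"for mode {self.params.mode!r}"
            )
        self._validated.add(rec.id)

    def _compute(self, a: SequenceRecord, b: SequenceRecord) -> float:
        if self._func is not None:
            return float(self._func(a, b))
        self._validate(a)
        self._validate(b)
        # canonical argument order: traceback tie-breaks among co-optimal
        # alignments depend on it, and identity must be symmetric
        if (a.residues, a.id) > (b.residues, b.id):
            a, b = b, a
        alignments = self._aligner.align(a.residues, b.residues)
        if self.params.scope == "local" and alignments.score <= 0:
            # no positive-scoring local alignment exists
            return 0.0
        aln = alignments[0]
        columns = aln.shape[1]
        blocks_a, blocks_b = aln.aligned
        if columns == 0 or len(blocks_a) == 0:
            return 0.0
        if self.params.scope == "semiglobal":
            # end gaps are free and excluded; normalizing by the shorter
            # sequence keeps a short spurious end-overlap from scoring high
            left = int(blocks_a[0][0]) + int(blocks_b[0][0])
            right = (a.length - int(blocks_a[-1][1])) + (b.length - int(blocks_b[-1][1]))
            columns = max(columns - left - right, min(a.length, b.length))
            if columns <= 0:
                return 0.0
        identities = 0
        for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
            xa = np.frombuffer(a.residues[a0:a1].encode("ascii"), dtype="S1")
            xb = np.frombuffer(b.residues[b0:b1].encode("ascii"), dtype="S1")
            eq = (xa == xb) & np.isin(xa, self._strict)
            identities += int(eq.sum())
        return identities / columns

    # -- public API --------------------------------------------------------

    def similarity(self, a: SequenceRecord, b: SequenceRecord) -> float:
        """Cached, ledger-counted similarity of an unordered pair."""
        key = _pair_key(a.id, b.id)
        hit = self.ledger.lookup(key)
        if hit is not None:
            return hit
        value = self._compute(a, b)
        self.ledger.record()
        self.ledger.store(key, value)
        return value

    def peek(self, a_id: str, b_id: str) -> float | None:
        """Cache lookup only; never computes, never counts."""
        if a_id == b_id:
            return 1.0
        return self.ledger.lookup(_pair_key(a_id, b_id))

    def similarity_uncounted(self, a: SequenceRecord, b: SequenceRecord) -> float:
        """Similarity for reporting purposes; never touches the count."""
        hit = self.peek(a.id, b.id)
        if hit is not None:
            return hit
        return self._compute(a, b)

    def with_matrix(self, matrix: "SimilarityMatrix") -> "_MatrixView":
        """View that reads already-computed similarities from ``matrix``."""
        return _MatrixView(self, matrix)


class _MatrixView:
    """Engine facade backed by a precomputed half matrix (no new counts)."""

    def __init__(self, parent: SimilarityEngine, matrix: "SimilarityMatrix"):
        self._parent = parent
        self._matrix = matrix
        self.params = parent.params
        self.ledger = parent.ledger

    def similarity(self, a: SequenceRecord, b: SequenceRecord) -> float:
        value = self._matrix.peek(a.id, b.id)
        if value is not None:
            return value
        return self._parent.similarity(a, b)


class SimilarityMatrix:
    """Triangular similarity table over a fixed id list (condensed storage)."""

    def __init__(self, ids: list[str], values: np.ndarray):
        n = len(ids)
        if values.shape != (n * (n - 1) // 2,):
            raise InvalidInputError("condensed value array has wrong length")
        self.ids = list(ids)
        self.values = values
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def _flat(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        n = len(self.ids)
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    def peek(self, id_a: str, id_b: str) -> float | None:
        if id_a == id_b:
            return 1.0
        ia = self._index.get(id_a)
        ib = self._index.get(id_b)
        if ia is None or ib is None:
            return None
        return float(self.values[self._flat(ia, ib)])

    def get(self, id_a: str, id_b: str) -> float:
        value = self.peek(id_a, id_b)
        if value is None:
            raise KeyError((id_a, id_b))
        return value


def percent_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: SimilarityParams | None = None,
    ledger: ComparisonLedger | None = None,
    *,
    engine: SimilarityEngine | None = None,
) -> float:
    """Percent identity of the optimal pairwise alignment, in [0, 1].

    Symmetric in its arguments; increments the ledger by one on a cache
    miss and zero on a hit.
    """
    if engine is None:
        engine = SimilarityEngine(params, ledger)
    return engine.similarity(a, b)


def half_matrix(
    seqs: list[SequenceRecord],
    params: SimilarityParams | None = None,
    ledger: ComparisonLedger | None = None,
    *,
    engine: SimilarityEngine | None = None,
) -> SimilarityMatrix:
    """All unordered pairwise similarities, computed in bounded batches.

    Exactly N(N-1)/2 new ledger comparisons when the cache starts empty;
    rerunning with a warm cache adds none.  Batches hold at most
    ``ledger.batch_limit`` pairs; results are independent of the limit.
    """
    if engine is None:
        engine = SimilarityEngine(params, ledger)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for sid in ids:
            (dupes if sid in seen else seen).add(sid)
        raise InvalidInputError(f"duplicate sequence ids: {sorted(dupes)}")
    n = len(seqs)
    values = np.empty(n * (n - 1) // 2, dtype=np.float64)
    limit = engine.ledger.batch_limit
    pairs = itertools.combinations(range(n), 2)
    pos = 0
    while True:
        batch = list(itertools.islice(pairs, limit))
        if not batch:
            break
        for i, j in batch:
            values[pos] = engine.similarity(seqs[i], seqs[j])
            pos += 1
        logger.debug("half_matrix batch done: %d pairs (total %d)", len(batch), pos)
    return SimilarityMatrix(ids, values)
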