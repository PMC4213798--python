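"""Synthetic sequence families with planted ground truth, plus file IO.

The generator emulates the structure of curated reference datasets (protein
superfamilies, species-level ITS barcodes): a number of families, each
descending from its own ancestor, with member-to-ancestor identity
calibrated to a target *within-family* identity and ancestor-to-ancestor
divergence calibrated so that *between-family* pairwise identity lands near
its target.  Clustering at a threshold strictly between the two identity
levels should recover the planted partition exactly, which is what makes
the generator a desk-scale gold standard.

Calibration detail: each family ancestor is derived from one common root by
substituting a fraction 1-p of positions, where p solves

    p^2 + (1-p)^2 / (|A|-1) = between_identity

(|A| = 4 for DNA, 20 for protein): two ancestors agree at a position when
both kept it, or both mutated it to the same residue.  Members substitute
exactly ceil((1-within)*L) positions of their ancestor, so the *ungapped*
member-to-ancestor identity equals the target; aligned identities drift
slightly once indels are enabled, which is why identity-critical tests
keep indels off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .baseline import Cluster, Partition
from .errors import FastaParseError, InvalidInputError
from .evaluation import ReferencePartition
from .seqsim import DNA_STRICT, PROTEIN_STRICT, SequenceRecord

__all__ = [
    "FamilySpec",
    "generate_families",
    "mutate_sequence",
    "read_fasta",
    "write_fasta",
    "read_reference",
    "write_reference",
    "read_clusters",
    "write_clusters",
]


def _strict_alphabet(alphabet: str) -> str:
    if alphabet == "dna":
        return DNA_STRICT
    if alphabet == "protein":
        return PROTEIN_STRICT
    raise InvalidInputError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a planted family structure.

    ``seqs_per_family`` and ``seq_length`` may be ints or inclusive
    (low, high) ranges.  ``within_identity`` is the target member-to-
    ancestor identity, ``between_identity`` the target pairwise identity
    across families; the former must exceed the latter for a planted
    partition to exist.  ``indel_rate`` (at most 0.02) adds single-residue
    indels on top of substitutions.
    """

    num_families: int = 10
    seqs_per_family: int | tuple = 10
    seq_length: int | tuple = 300
    within_identity: float = 0.99
    between_identity: float = 0.70
    alphabet: str = "dna"
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_families < 1:
            raise InvalidInputError("num_families must be >= 1")
        if not self.within_identity > self.between_identity:
            raise InvalidInputError(
                "within_identity must exceed between_identity "
                f"({self.within_identity} <= {self.between_identity})"
            )
        if not 0.0 < self.within_identity <= 1.0:
            raise InvalidInputError("within_identity must be in (0, 1]")
        lo = self.seq_length if isinstance(self.seq_length, int) else min(self.seq_length)
        if lo < 20:
            raise InvalidInputError("sequence lengths must be >= 20")
        if not 0.0 <= self.indel_rate <= 0.02:
            raise InvalidInputError("indel_rate must be in [0, 0.02]")
        _strict_alphabet(self.alphabet)
        a = len(_strict_alphabet(self.alphabet))
        if self.between_identity < 1.0 / a:
            raise InvalidInputError(
                f"between_identity below the random-identity floor 1/{a}"
            )


def _draw(value, rng: np.random.Generator) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def _ancestor_identity(between: float, alphabet_size: int) -> float:
    """Solve p^2 + (1-p)^2/(a-1) = between for the root-to-ancestor identity."""
    a1 = alphabet_size - 1
    # (1 + 1/a1) p^2 - (2/a1) p + 1/a1 - between = 0
    A = 1 + 1 / a1
    B = -2 / a1
    C = 1 / a1 - between
    disc = B * B - 4 * A * C
    p = (-B + math.sqrt(disc)) / (2 * A)
    return min(1.0, p)


def _substitute(residues: str, n_sub: int, alphabet: str, rng: np.random.Generator) -> str:
    if n_sub == 0:
        return residues
    chars = list(residues)
    positions = rng.choice(len(chars), size=n_sub, replace=False)
    for pos in positions:
        choices = [c for c in alphabet if c != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def mutate_sequence(
    seq: SequenceRecord,
    target_identity: float,
    rng: np.random.Generator,
    *,
    alphabet: str = "dna",
    indel_rate: float = 0.0,
    new_id: str | None = None,
) -> SequenceRecord:
    """Derive a mutant at a controlled ungapped identity to its parent.

    Applies exactly ceil((1 - target_identity) * length) substitutions at
    distinct positions (each new residue differs from the old one), then
    optionally ``round(indel_rate * length)`` single-residue insertions or
    deletions.  With indels off, the ungapped identity to the parent equals
    the target exactly.
    """
    if not 0.0 < target_identity <= 1.0:
        raise InvalidInputError("target_identity must be in (0, 1]")
    strict = _strict_alphabet(alphabet)
    length = seq.length
    # round before ceil so float noise in (1 - target) cannot shift the count
    n_sub = math.ceil(round((1.0 - target_identity) * length, 9))
    residues = _substitute(seq.residues, n_sub, strict, rng)
    n_indel = int(round(min(indel_rate, 0.02) * length))
    for _ in range(n_indel):
        pos = int(rng.integers(len(residues) + 1))
        if rng.random() < 0.5 and len(residues) > 20:
            residues = residues[:pos] + residues[pos + 1 :]
        else:
            ins = strict[int(rng.integers(len(strict)))]
            residues = residues[:pos] + ins + residues[pos:]
    return SequenceRecord(new_id or seq.id, residues, seq.description)


def generate_families(spec: FamilySpec) -> tuple[list[SequenceRecord], ReferencePartition]:
    """Draw planted families; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    strict = _strict_alphabet(spec.alphabet)
    max_len = (
        spec.seq_length if isinstance(spec.seq_length, int) else max(spec.seq_length)
    )
    root = "".join(
        strict[i] for i in rng.integers(len(strict), size=max_len)
    )
    p_anc = _ancestor_identity(spec.between_identity, len(strict))
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for fam in range(spec.num_families):
        label = f"family{fam:03d}"
        anc_res = _substitute(
            root, math.ceil((1.0 - p_anc) * max_len), strict, rng
        )
        ancestor = SequenceRecord(f"F{fam:03d}anc", anc_res)
        n_members = _draw(spec.seqs_per_family, rng)
        for m in range(n_members):
            sid = f"F{fam:03d}S{m:03d}"
            rec = mutate_sequence(
                ancestor,
                spec.within_identity,
                rng,
                alphabet=spec.alphabet,
                indel_rate=spec.indel_rate,
                new_id=sid,
            )
            target_len = _draw(spec.seq_length, rng)
            residues = rec.residues[:target_len] if target_len < len(rec.residues) else rec.residues
            records.append(SequenceRecord(sid, residues, f"planted={label}"))
            labels[sid] = label
    return records, ReferencePartition(labels)


# ---------------------------------------------------------------------------
# file formats


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into records (uppercased); reject duplicates and empties."""
    path = Path(path)
    # cheap structural pre-check so errors carry a line number
    first_content = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content = (lineno, line)
                break
    if first_content is not None and not first_content[1].startswith(">"):
        raise FastaParseError(
            f"{path}:{first_content[0]}: sequence data before any '>' header"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = str(bio.seq).upper()
        if not residues:
            raise FastaParseError(
                f"{path}:{_header_line(path, bio.id)}: record {bio.id!r} has no sequence"
            )
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {bio.id!r}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id) :].strip() if bio.description else ""
        records.append(SequenceRecord(bio.id, residues, desc))
    return records


def _header_line(path: Path, seq_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [seq_id]:
                return lineno
    return 0


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_reference(path) -> ReferencePartition:
    return ReferencePartition.from_tsv(path)


def write_reference(reference: ReferencePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tlabel\n")
        for sid, label in sorted(reference.labels.items()):
            fh.write(f"{sid}\t{label}\n")


def write_clusters(
    partition: Partition,
    path,
    *,
    algorithm: str = "",
    threshold: float | None = None,
    engine=None,
) -> None:
    """Write the cluster table (TSV: id, cluster, representative, similarity,
    algorithm, threshold).  Similarity to the representative is reported from
    the engine's cache where available (or recomputed uncounted); without an
    engine the column is NA."""
    with open(path, "w") as fh:
        fh.write(
            "sequence_id\tcluster_id\trepresentative_id\t"
            "similarity_to_representative\talgorithm\tthreshold\n"
        )
        t_str = "" if threshold is None else f"{threshold:.4f}"
        for cluster in partition.clusters:
            for sid in cluster.member_ids:
                sim = ""
                if sid == cluster.representative_id:
                    sim = "1.0000"
                elif engine is not None:
                    val = engine.peek(sid, cluster.representative_id)
                    sim = "" if val is None else f"{val:.4f}"
                fh.write(
                    f"{sid}\t{cluster.cluster_id}\t{cluster.representative_id}\t"
                    f"{sim or 'NA'}\t{algorithm}\t{t_str}\n"
                )


def read_clusters(path) -> Partition:
    """Read a cluster table back into a Partition."""
    groups: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence_id"):
            raise InvalidInputError(f"{path}: not a cluster table")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"{path}:{lineno}: too few columns")
            sid, cid, rep = fields[0], fields[1], fields[2]
            groups.setdefault(cid, []).append(sid)
            reps[cid] = rep
    clusters = [
        Cluster(i, members, reps[cid])
        for i, (cid, members) in enumerate(groups.items())
    ]
    return Partition(clusters)
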