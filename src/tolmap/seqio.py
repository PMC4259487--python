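"""Sequence and alignment I/O plus a minimal exact-seed aligner.

This module provides the plumbing shared by the integration-mapping arm:
FASTA/FASTQ reading and writing (via Biopython), SAM ingestion/emission
(via pysam), construction of an *amended reference* (genome scaffolds plus
the transgene construct as an extra scaffold), a toy seed-and-verify
aligner adequate for synthetic fixtures, and the uniqueness
classification used by chimeric-pair filtering.

Coordinates are 0-based half-open everywhere internally; 1-based
coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence.

    ``id`` must be non-empty; ``sequence`` is uppercase A/C/G/T/N.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AmendedReference:
    """Genome scaffolds amended with the construct as a separate scaffold."""

    scaffolds: list[SequenceRecord]
    construct_scaffold_id: str

    @property
    def genome_scaffolds(self) -> list[SequenceRecord]:
        return [s for s in self.scaffolds if s.id != self.construct_scaffold_id]

    @property
    def construct(self) -> SequenceRecord:
        for s in self.scaffolds:
            if s.id == self.construct_scaffold_id:
                return s
        raise KeyError(self.construct_scaffold_id)

    def get(self, scaffold_id: str) -> SequenceRecord:
        for s in self.scaffolds:
            if s.id == scaffold_id:
                return s
        raise KeyError(scaffold_id)

    def genome_length(self) -> int:
        return sum(len(s) for s in self.genome_scaffolds)


def build_amended_reference(
    genome: Sequence[SequenceRecord], construct: SequenceRecord
) -> AmendedReference:
    """Append the construct to the genome scaffolds as its own scaffold.

    Scaffold order is preserved; an id collision between the construct and
    any genome scaffold is rejected.
    """
    ids = [s.id for s in genome]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scaffold ids in genome")
    if construct.id in ids:
        raise ValueError(
            f"construct id {construct.id!r} collides with a genome scaffold"
        )
    return AmendedReference(
        scaffolds=list(genome) + [construct], construct_scaffold_id=construct.id
    )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq), r.description.removeprefix(r.id).strip())
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class ReadPair:
    """One paired-end read: mate 1 from the fragment 5' end, mate 2 the
    reverse complement of the fragment 3' end."""

    pair_id: str
    seq1: str
    seq2: str
    qual: int = 35  # constant Phred score used for synthetic reads


def write_fastq_pair(
    pairs: Iterable[ReadPair], r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> None:
    """Write mates to `_R1`/`_R2` FASTQ files (Phred+33, constant quality)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            q1 = chr(p.qual + 33) * len(p.seq1)
            q2 = chr(p.qual + 33) * len(p.seq2)
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")


def read_fastq_pair(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 files have different numbers of reads")
    pairs = []
    for a, b in zip(r1, r2):
        ida = a.id.removesuffix("/1")
        idb = b.id.removesuffix("/2")
        if ida != idb:
            raise ValueError(f"mate ids do not pair: {a.id} vs {b.id}")
        pairs.append(ReadPair(ida, str(a.seq), str(b.seq)))
    return pairs


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

UNMAPPED = "*"


@dataclass
class MateAlignment:
    """Placement of one mate: scaffold/pos/strand plus hit multiplicity."""

    scaffold_id: str  # UNMAPPED ("*") when the mate did not align
    pos: int = 0  # 0-based leftmost
    strand: str = "+"
    n_best_hits: int = 0
    aligned_len: int = 0

    @property
    def mapped(self) -> bool:
        return self.scaffold_id != UNMAPPED


@dataclass
class PairAlignment:
    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def mates(self) -> tuple[MateAlignment, MateAlignment]:
        return (self.mate1, self.mate2)


def classify_uniqueness(
    mate: MateAlignment, *, mapq: int | None = None, mapq_threshold: int = 30
) -> str:
    """Classify a mate as ``unique``, ``repetitive`` or ``unmapped``.

    With the internal aligner, unique means exactly one best hit.  On the
    SAM ingestion path a MAPQ is available instead and MAPQ >=
    ``mapq_threshold`` is taken as the conventional uniqueness proxy.
    """
    if not mate.mapped:
        return "unmapped"
    if mapq is not None:
        return "unique" if mapq >= mapq_threshold else "repetitive"
    return "unique" if mate.n_best_hits == 1 else "repetitive"


# ---------------------------------------------------------------------------
# Toy exact-seed aligner
# ---------------------------------------------------------------------------


class ExactSeedAligner:
    """Seed-and-verify aligner for synthetic fixtures.

    A mate is reported mapped at every position where its sequence (or
    reverse complement) matches the reference with >= ``min_identity``
    identity (substitutions only) anchored by an exact seed of
    ``min_exact_seed`` bases.  ``n_best_hits`` counts equal-best
    positions; the primary hit is the deterministic minimum of
    (scaffold id, pos, strand) among the best hits.
    """

    def __init__(
        self,
        reference: AmendedReference,
        min_exact_seed: int = 20,
        min_identity: float = 0.95,
    ):
        if not reference.scaffolds:
            raise ValueError("reference is empty")
        self.reference = reference
        self.k = int(min_exact_seed)
        self.min_identity = float(min_identity)
        # k-mer -> list of (scaffold index, offset)
        self._index: dict[str, list[tuple[int, int]]] = {}
        self._seqs = [s.sequence for s in reference.scaffolds]
        self._ids = [s.id for s in reference.scaffolds]
        k = self.k
        for si, seq in enumerate(self._seqs):
            for off in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[off : off + k], []).append((si, off))

    def _candidate_positions(self, seq: str) -> set[tuple[int, int]]:
        """Candidate (scaffold, start) placements from exact seed hits."""
        k = self.k
        n = len(seq)
        cands: set[tuple[int, int]] = set()
        offsets = list(range(0, n - k + 1, k))
        if offsets[-1] != n - k:
            offsets.append(n - k)
        for off in offsets:
            for si, ref_off in self._index.get(seq[off : off + k], ()):
                start = ref_off - off
                if start >= 0 and start + n <= len(self._seqs[si]):
                    cands.add((si, start))
        return cands

    def _identity(self, seq: str, si: int, start: int) -> float:
        ref = self._seqs[si][start : start + len(seq)]
        matches = sum(a == b for a, b in zip(seq, ref))
        return matches / len(seq)

    def align_mate(self, seq: str) -> MateAlignment:
        seq = seq.upper()
        if len(seq) < self.k:
            raise ValueError(
                f"read shorter than the exact-seed length {self.k}"
            )
        if set(seq) - VALID_BASES:
            raise ValueError("malformed read characters")
        hits: list[tuple[float, int, int, str]] = []  # (identity, si, pos, strand)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for si, start in self._candidate_positions(s):
                if s == self._seqs[si][start : start + len(s)]:
                    ident = 1.0
                else:
                    ident = self._identity(s, si, start)
                if ident >= self.min_identity:
                    hits.append((ident, si, start, strand))
        if not hits:
            return MateAlignment(UNMAPPED)
        best = max(h[0] for h in hits)
        best_hits = [h for h in hits if h[0] == best]
        # total deterministic tie-break: lowest scaffold id, then pos, then '+'
        _, si, pos, strand = min(
            best_hits, key=lambda h: (self._ids[h[1]], h[2], h[3])
        )
        return MateAlignment(
            scaffold_id=self._ids[si],
            pos=pos,
            strand=strand,
            n_best_hits=len(best_hits),
            aligned_len=len(seq),
        )

    def align_pairs(self, pairs: Iterable[ReadPair]) -> list[PairAlignment]:
        return [
            PairAlignment(p.pair_id, self.align_mate(p.seq1), self.align_mate(p.seq2))
            for p in pairs
        ]


def align_pairs(
    pairs: Iterable[ReadPair],
    reference: AmendedReference,
    min_exact_seed: int = 20,
) -> list[PairAlignment]:
    """Convenience wrapper building an :class:`ExactSeedAligner` once."""
    return ExactSeedAligner(reference, min_exact_seed=min_exact_seed).align_pairs(pairs)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Iterable[PairAlignment],
    reference: AmendedReference,
    path: str | os.PathLike,
    *,
    unique_mapq: int = 60,
    repetitive_mapq: int = 0,
) -> None:
    """Write pair alignments as minimal valid SAM.

    MAPQ encodes the uniqueness classification (NH carries the hit count),
    so a round-trip through :func:`read_sam` preserves the records.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": s.id, "LN": len(s)} for s in reference.scaffolds],
    }
    tid = {s.id: i for i, s in enumerate(reference.scaffolds)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pa in alignments:
            for mate_idx, mate in enumerate(pa.mates):
                a = pysam.AlignedSegment(out.header)
                a.query_name = pa.pair_id
                a.flag = 0x1 | (0x40 if mate_idx == 0 else 0x80)
                if mate.mapped:
                    a.reference_id = tid[mate.scaffold_id]
                    a.reference_start = mate.pos
                    if mate.strand == "-":
                        a.flag |= 0x10
                    a.mapping_quality = (
                        unique_mapq if mate.n_best_hits == 1 else repetitive_mapq
                    )
                    a.cigarstring = f"{mate.aligned_len}M"
                    a.set_tag("NH", mate.n_best_hits)
                    a.query_sequence = "N" * mate.aligned_len
                    a.query_qualities = pysam.qualitystring_to_array(
                        "I" * mate.aligned_len
                    )
                else:
                    a.flag |= 0x4
                    a.query_sequence = "N"
                    a.query_qualities = pysam.qualitystring_to_array("I")
                out.write(a)


def read_sam(path: str | os.PathLike, *, mapq_threshold: int = 30) -> list[PairAlignment]:
    """Read a SAM file into :class:`PairAlignment` records.

    Uses QNAME/FLAG/RNAME/POS/MAPQ/CIGAR; POS is converted from SAM's
    1-based convention by pysam.  ``n_best_hits`` is taken from the NH tag
    when present, otherwise inferred from MAPQ (>= threshold -> 1, else 2).
    Secondary and supplementary records are ignored.
    """
    by_name: dict[str, dict[int, MateAlignment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                mate = MateAlignment(UNMAPPED)
            else:
                if rec.has_tag("NH"):
                    nh = int(rec.get_tag("NH"))
                else:
                    nh = 1 if rec.mapping_quality >= mapq_threshold else 2
                alen = rec.query_alignment_length or (rec.query_length or 0)
                mate = MateAlignment(
                    scaffold_id=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    n_best_hits=nh,
                    aligned_len=alen,
                )
            which = 2 if rec.is_read2 else 1
            if rec.query_name not in by_name:
                by_name[rec.query_name] = {}
                order.append(rec.query_name)
            by_name[rec.query_name][which] = mate
    out = []
    for name in order:
        mates = by_name[name]
        out.append(
            PairAlignment(
                name,
                mates.get(1, MateAlignment(UNMAPPED)),
                mates.get(2, MateAlignment(UNMAPPED)),
            )
        )
    return out
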