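"""Transgene concatemer integration-site discovery.

The computation follows the targeted-capture mapping strategy for a
high-copy Tol2 transgene array: read pairs aligned to an amended
reference (genome + construct scaffold) are filtered down to *chimeric*
pairs — one mate on the construct, the other mate at a unique genomic
location — genome-mate positions are binned into 1000 bp intervals, a
bootstrap null (reads thrown uniformly over genome bins) assigns an
empirical enrichment p-value to each occupied interval, candidate sites
are called by read support across samples, repetitive-DNA candidates are
rejected by k-mer copy number, and the surviving site's junctions and
target-site duplication (TSD) are resolved from split reads.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .seqio import (
    AmendedReference,
    PairAlignment,
    ReadPair,
    SequenceRecord,
    classify_uniqueness,
    revcomp,
)

DEFAULT_BIN_SIZE = 1000
DEFAULT_MIN_READS = 9
DEFAULT_MIN_SAMPLES = 2
DEFAULT_ALPHA = 0.05


@dataclass
class ChimericEvidence:
    """One read pair supporting an integration junction: the construct
    mate anchors the transgene, the genome mate pins a unique locus."""

    pair_id: str
    sample_id: str
    genome_scaffold: str
    genome_pos: int  # 0-based leftmost of the genome mate
    genome_strand: str
    side: str  # left | right | unknown flank of the insertion
    construct_offset: int


@dataclass
class FilterTally:
    """Audit counts for discarded pairs; retained + discards = input."""

    retained: int = 0
    both_genome: int = 0
    both_construct: int = 0
    nonunique_genome: int = 0
    unmapped: int = 0

    def total(self) -> int:
        return (
            self.retained
            + self.both_genome
            + self.both_construct
            + self.nonunique_genome
            + self.unmapped
        )


@dataclass
class IntervalStat:
    scaffold: str
    start: int  # 0-based, multiple of bin_size
    bin_size: int = DEFAULT_BIN_SIZE
    read_count: int = 0
    samples_supporting: int = 0
    p_boot: float = float("nan")


@dataclass
class CandidateSite:
    scaffold: str
    interval: IntervalStat
    support_by_sample: dict[str, int]
    total_support: int
    repetitive: bool = False
    status: str = "candidate"  # candidate | rejected_repetitive | validated


@dataclass
class Breakpoint:
    """Resolved junction coordinates on the genome scaffold.

    ``left_junction`` is the 0-based position of the last genomic base
    joined to the construct 5' end; ``right_junction`` the first genomic
    base joined to the construct 3' end.  When the junctions overlap
    (left >= right) the overlap is the target-site duplication.
    Unresolved sides are ``None`` and the TSD is left unset.
    """

    scaffold: str
    left_junction: int | None
    right_junction: int | None
    tsd_len: int | None = None
    tsd_seq: str | None = None
    n_left_reads: int = 0
    n_right_reads: int = 0


# ---------------------------------------------------------------------------
# Chimeric-pair filtering
# ---------------------------------------------------------------------------


def filter_chimeric_pairs(
    alignments: list[PairAlignment],
    sample_id: str,
    construct_scaffold_id: str,
    *,
    known_scaffolds: set[str] | None = None,
) -> tuple[list[ChimericEvidence], FilterTally]:
    """Retain pairs with one mate on the construct and the other mate
    uniquely on a genome scaffold.

    Side convention: a genome mate on the + strand reads toward the
    construct at increasing coordinates, so it supports the *left* flank
    of the insertion; a - strand genome mate supports the *right* flank.
    Discards are tallied by reason.
    """
    if known_scaffolds is not None and construct_scaffold_id not in known_scaffolds:
        raise ValueError(f"unknown construct scaffold {construct_scaffold_id!r}")
    evidence: list[ChimericEvidence] = []
    tally = FilterTally()
    for pa in alignments:
        m1, m2 = pa.mates
        on_construct = [m.mapped and m.scaffold_id == construct_scaffold_id for m in (m1, m2)]
        if not (m1.mapped and m2.mapped):
            tally.unmapped += 1
            continue
        if all(on_construct):
            tally.both_construct += 1
            continue
        if not any(on_construct):
            tally.both_genome += 1
            continue
        construct_mate, genome_mate = (m1, m2) if on_construct[0] else (m2, m1)
        if classify_uniqueness(genome_mate) != "unique":
            tally.nonunique_genome += 1
            continue
        side = "left" if genome_mate.strand == "+" else "right"
        evidence.append(
            ChimericEvidence(
                pair_id=pa.pair_id,
                sample_id=sample_id,
                genome_scaffold=genome_mate.scaffold_id,
                genome_pos=genome_mate.pos,
                genome_strand=genome_mate.strand,
                side=side,
                construct_offset=construct_mate.pos,
            )
        )
        tally.retained += 1
    return evidence, tally


# ---------------------------------------------------------------------------
# Interval binning + bootstrap enrichment
# ---------------------------------------------------------------------------


def bin_interval_counts(
    evidence: list[ChimericEvidence], bin_size: int = DEFAULT_BIN_SIZE
) -> list[IntervalStat]:
    """Count genome-mate positions in fixed half-open bins.

    Every interval with at least one read appears exactly once; counts sum
    to the number of evidence records.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if not evidence:
        return []
    df = pd.DataFrame(
        {
            "scaffold": [e.genome_scaffold for e in evidence],
            "start": [(e.genome_pos // bin_size) * bin_size for e in evidence],
            "sample": [e.sample_id for e in evidence],
        }
    )
    grouped = df.groupby(["scaffold", "start"]).agg(
        read_count=("sample", "size"), samples_supporting=("sample", "nunique")
    )
    return [
        IntervalStat(
            scaffold=sc,
            start=int(st),
            bin_size=bin_size,
            read_count=int(row.read_count),
            samples_supporting=int(row.samples_supporting),
        )
        for (sc, st), row in grouped.sort_index().iterrows()
    ]


def _multinomial_null(
    rng: np.random.Generator,
    n_reads: int,
    genome_bins: int,
    n_boot: int,
    occupied_cols: np.ndarray,
    need_max: bool,
    chunk: int = 16384,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Throw ``n_reads`` uniformly over ``genome_bins`` in each of
    ``n_boot`` replicates, without materialising the full B x M matrix.

    Columns are generated chunk-wise with the exact sequential
    conditional-binomial decomposition of the multinomial.  Returns the
    null counts at ``occupied_cols`` (shape B x k) and, when requested,
    the per-replicate maximum over all bins.
    """
    occupied_counts = np.zeros((n_boot, len(occupied_cols)), dtype=np.int64)
    max_counts = np.zeros(n_boot, dtype=np.int64) if need_max else None
    remaining = np.full(n_boot, n_reads, dtype=np.int64)
    bins_left = genome_bins
    col0 = 0
    order = np.argsort(occupied_cols)
    sorted_cols = occupied_cols[order]
    next_oc = 0
    while bins_left > 0:
        mc = min(chunk, bins_left)
        # reads landing in this chunk of bins
        n_chunk = rng.binomial(remaining, mc / bins_left)
        if mc == 1:
            counts = n_chunk[:, None]
        else:
            counts = rng.multinomial(n_chunk, np.full(mc, 1.0 / mc))
        if need_max:
            np.maximum(max_counts, counts.max(axis=1), out=max_counts)
        hi = next_oc
        while hi < len(sorted_cols) and sorted_cols[hi] < col0 + mc:
            occupied_counts[:, order[hi]] = counts[:, sorted_cols[hi] - col0]
            hi += 1
        next_oc = hi
        remaining -= n_chunk
        bins_left -= mc
        col0 += mc
    return occupied_counts, max_counts


def bootstrap_interval_pvalues(
    intervals: list[IntervalStat],
    genome_bins: int,
    n_boot: int,
    seed: int,
    mode: str = "max_count",
) -> list[IntervalStat]:
    """Empirical enrichment p-values under a uniform-throw null.

    The null model throws the observed total read count uniformly over
    ``genome_bins`` bins, ``n_boot`` times.  ``per_interval`` mode compares
    each interval's count with its own bin's null counts, giving a
    per-interval empirical p; ``max_count`` mode (default) compares with
    the maximum bin count of each replicate, a family-wise calibrated p
    appropriate when the whole genome is scanned.  Both use +1 smoothing
    so p is never 0.  Deterministic given ``seed``.
    """
    if mode not in ("per_interval", "max_count"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if genome_bins < len(intervals):
        raise ValueError("genome_bins smaller than the number of occupied intervals")
    n_reads = sum(iv.read_count for iv in intervals)
    if n_reads == 0:
        warnings.warn("no reads: all bootstrap p-values set to 1", stacklevel=2)
        return [replace(iv, p_boot=1.0) for iv in intervals]
    rng = np.random.default_rng(seed)
    # each occupied interval occupies one distinct column of the null throw
    occupied_cols = np.arange(len(intervals))
    need_max = mode == "max_count"
    null_counts, null_max = _multinomial_null(
        rng, n_reads, genome_bins, n_boot, occupied_cols, need_max
    )
    out = []
    for j, iv in enumerate(intervals):
        if need_max:
            exceed = int((null_max >= iv.read_count).sum())
        else:
            exceed = int((null_counts[:, j] >= iv.read_count).sum())
        out.append(replace(iv, p_boot=(1 + exceed) / (n_boot + 1)))
    return out


# ---------------------------------------------------------------------------
# Candidate calling + repeat flagging
# ---------------------------------------------------------------------------


def call_candidate_sites(
    intervals_by_sample: dict[str, list[IntervalStat]],
    *,
    genome_bins: int,
    n_boot: int = 999,
    seed: int = 0,
    min_reads: int = DEFAULT_MIN_READS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "max_count",
) -> list[CandidateSite]:
    """Pool per-sample interval counts and call candidate sites.

    A site is a candidate iff pooled support >= ``min_reads``, distinct
    supporting samples >= ``min_samples``, and the pooled bootstrap
    p-value <= ``alpha``.  Output is sorted by descending support, ties by
    (scaffold, start); per-sample support is recorded for reporting.
    """
    bin_sizes = {
        iv.bin_size for ivs in intervals_by_sample.values() for iv in ivs
    }
    if len(bin_sizes) > 1:
        raise ValueError(f"inconsistent bin sizes across samples: {sorted(bin_sizes)}")
    bin_size = bin_sizes.pop() if bin_sizes else DEFAULT_BIN_SIZE

    pooled: dict[tuple[str, int], Counter] = {}
    for sample, ivs in intervals_by_sample.items():
        for iv in ivs:
            pooled.setdefault((iv.scaffold, iv.start), Counter())[sample] += iv.read_count
    keys = sorted(pooled)
    pooled_intervals = [
        IntervalStat(
            scaffold=sc,
            start=st,
            bin_size=bin_size,
            read_count=sum(pooled[(sc, st)].values()),
            samples_supporting=len(pooled[(sc, st)]),
        )
        for sc, st in keys
    ]
    pooled_intervals = bootstrap_interval_pvalues(
        pooled_intervals, genome_bins=genome_bins, n_boot=n_boot, seed=seed, mode=mode
    )
    sites = []
    for iv, key in zip(pooled_intervals, keys):
        if (
            iv.read_count >= min_reads
            and iv.samples_supporting >= min_samples
            and iv.p_boot <= alpha
        ):
            sites.append(
                CandidateSite(
                    scaffold=iv.scaffold,
                    interval=iv,
                    support_by_sample=dict(pooled[key]),
                    total_support=iv.read_count,
                )
            )
    sites.sort(key=lambda s: (-s.total_support, s.scaffold, s.interval.start))
    return sites


def flag_repetitive(
    site: CandidateSite,
    reference: AmendedReference,
    k: int = 25,
    max_copy: float = 2.0,
) -> CandidateSite:
    """Flag a candidate whose interval lies in repetitive DNA.

    The interval's k-mers are counted genome-wide (both strands collapsed
    to the forward orientation); a mean occurrence above ``max_copy``
    marks the site repetitive and rejects it — non-specific capture of
    repeats mimics integration evidence.
    """
    scaffold = reference.get(site.scaffold)
    start = site.interval.start
    end = min(start + site.interval.bin_size, len(scaffold))
    window = scaffold.sequence[start:end]
    if len(window) < k:
        raise ValueError("interval shorter than k")
    query = set()
    for i in range(len(window) - k + 1):
        km = window[i : i + k]
        query.add(min(km, revcomp(km)))
    counts = dict.fromkeys(query, 0)
    for s in reference.genome_scaffolds:
        seq = s.sequence
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            canon = min(km, revcomp(km))
            if canon in counts:
                counts[canon] += 1
    mean_copy = float(np.mean(list(counts.values()))) if counts else 0.0
    repetitive = mean_copy > max_copy
    status = "rejected_repetitive" if repetitive else site.status
    return replace(site, repetitive=repetitive, status=status)


# ---------------------------------------------------------------------------
# Breakpoint refinement
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def refine_breakpoint(
    site: CandidateSite,
    reads: list[ReadPair],
    reference: AmendedReference,
    construct: SequenceRecord,
    *,
    min_part: int = 15,
    margin: int = 2000,
) -> Breakpoint:
    """Resolve junction coordinates and the TSD from split reads.

    Scans every read (and its reverse complement) for a split
    composition: a genomic part of >= ``min_part`` exactly matching the
    reference near the candidate interval, joined to >= ``min_part``
    bases of a construct *end* (5' prefix or 3' suffix).  The left
    junction is the maximum genomic coordinate adjacent to a construct
    5'-end match; the right junction the minimum genomic coordinate
    adjacent to a construct 3'-end match.  A positive overlap
    left - right + 1 is the TSD, extracted from the reference; a side
    with no split reads stays unresolved and the TSD unset.
    """
    if site.repetitive:
        raise ValueError("breakpoint refinement requires a non-repetitive candidate")
    scaffold = reference.get(site.scaffold)
    start = max(0, site.interval.start - margin)
    end = min(len(scaffold), site.interval.start + site.interval.bin_size + margin)
    region = scaffold.sequence[start:end]
    cseq = construct.sequence
    c_head = cseq[:min_part]
    c_tail = cseq[-min_part:]

    left_positions: list[int] = []
    right_positions: list[int] = []

    def scan(q: str) -> None:
        n = len(q)
        # left junction: genome prefix + construct 5' end
        idx = q.find(c_head)
        if idx >= min_part and q[idx:] == cseq[: n - idx]:
            gpart = q[:idx]
            for hit in _find_all(region, gpart):
                left_positions.append(start + hit + idx - 1)
        # right junction: construct 3' end + genome suffix
        ridx = q.rfind(c_tail)
        if ridx != -1:
            k = ridx + min_part  # construct part length
            if n - k >= min_part and q[:k] == cseq[-k:]:
                gpart = q[k:]
                for hit in _find_all(region, gpart):
                    right_positions.append(start + hit)

    for pair in reads:
        for seq in (pair.seq1, pair.seq2):
            scan(seq)
            scan(revcomp(seq))

    left = max(left_positions) if left_positions else None
    right = min(right_positions) if right_positions else None
    tsd_len: int | None = None
    tsd_seq: str | None = None
    if left is not None and right is not None:
        overlap = left - right + 1
        tsd_len = overlap if overlap > 0 else 0
        tsd_seq = scaffold.sequence[right : left + 1] if tsd_len > 0 else ""
    return Breakpoint(
        scaffold=site.scaffold,
        left_junction=left,
        right_junction=right,
        tsd_len=tsd_len,
        tsd_seq=tsd_seq,
        n_left_reads=len(left_positions),
        n_right_reads=len(right_positions),
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def candidates_to_bed(sites: list[CandidateSite]) -> str:
    """Candidate intervals as BED (0-based half-open, score = support)."""
    lines = [
        f"{s.scaffold}\t{s.interval.start}\t{s.interval.start + s.interval.bin_size}"
        f"\t{s.status}\t{s.total_support}"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def evidence_to_frame(evidence: list[ChimericEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [e.pair_id for e in evidence],
            "sample_id": [e.sample_id for e in evidence],
            "scaffold": [e.genome_scaffold for e in evidence],
            "genome_pos": [e.genome_pos for e in evidence],
            "strand": [e.genome_strand for e in evidence],
            "side": [e.side for e in evidence],
            "construct_offset": [e.construct_offset for e in evidence],
        }
    )


def breakpoint_report(bp: Breakpoint) -> str:
    """Human-readable junction report (1-based inclusive coordinates)."""
    left = "unresolved" if bp.left_junction is None else str(bp.left_junction + 1)
    right = "unresolved" if bp.right_junction is None else str(bp.right_junction + 1)
    tsd = "unset" if bp.tsd_len is None else f"{bp.tsd_len} bp ({bp.tsd_seq or '-'})"
    return (
        f"scaffold\t{bp.scaffold}\n"
        f"left_junction_1based\t{left}\n"
        f"right_junction_1based\t{right}\n"
        f"target_site_duplication\t{tsd}\n"
        f"split_reads_left\t{bp.n_left_reads}\n"
        f"split_reads_right\t{bp.n_right_reads}\n"
    )
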