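"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be generated here: a random
reference genome carrying a multi-copy transgene concatemer with a
target-site duplication (TSD), capture-enriched paired-end reads,
pedigree genotype tables for STR linkage, and three-sample count
matrices with spiked fold changes for the differential-expression arm.

All randomness flows through a numpy ``Generator`` seeded by an explicit
argument; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import ReadPair, SequenceRecord, revcomp

BASES = np.array(["A", "C", "G", "T"])

DEFAULT_TSD_LEN = 8  # the Tol2 transposon signature duplication
DEFAULT_COPY_NUMBER = 100  # the study line carries ~100 tandem copies
DEFAULT_FRAGMENT_MEAN = 250  # shearing target in the capture protocol
DEFAULT_FRAGMENT_SD = 30
DEFAULT_READ_LEN = 75
DEFAULT_ENRICHMENT = 50.0  # placeholder bait-capture weight (unmeasured)


# ---------------------------------------------------------------------------
# Reference + concatemer insertion
# ---------------------------------------------------------------------------


@dataclass
class SimulatedLocus:
    """Ground-truth description of one concatemer insertion.

    ``insertion_pos`` is the 0-based offset of the base *before which* the
    construct block is inserted; ``tsd_len`` bases immediately upstream are
    duplicated on the 3' side of the block.
    """

    scaffold_id: str
    insertion_pos: int
    copy_number: int = DEFAULT_COPY_NUMBER
    tsd_len: int = DEFAULT_TSD_LEN
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.insertion_pos < 0:
            raise ValueError("insertion_pos must be >= 0")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.tsd_len > self.insertion_pos:
            raise ValueError(
                "tsd_len exceeds insertion_pos: the duplicated segment "
                "must exist upstream of the insertion"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")


@dataclass
class ReadPairTruth:
    """Truth record for one simulated pair (for recovery tests)."""

    pair_id: str
    origin: str  # genome | construct | junction_left | junction_right
    fragment_start: int  # 0-based on the modified genome
    fragment_len: int


@dataclass
class CountTruth:
    gene_id: str
    true_log2fc_pretumor: float
    true_log2fc_tumor: float
    is_de: bool

    def __post_init__(self) -> None:
        if not self.is_de and (self.true_log2fc_pretumor or self.true_log2fc_tumor):
            raise ValueError("non-DE gene must have zero log2 fold changes")


def simulate_reference(
    n_scaffolds: int,
    lengths: list[int],
    gc: float,
    seed: int,
    *,
    prefix: str = "scaffold",
) -> list[SequenceRecord]:
    """Random scaffolds with the requested GC content.

    Deterministic given ``seed``; base composition approximates ``gc``
    within binomial error.
    """
    if len(lengths) != n_scaffolds:
        raise ValueError("lengths must have one entry per scaffold")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i, length in enumerate(lengths):
        name = f"{prefix}_{i + 1}"
        if length <= 0:
            raise ValueError(f"non-positive length for scaffold {name}")
        seq = "".join(BASES[rng.choice(4, size=length, p=p)])
        records.append(SequenceRecord(name, seq))
    return records


def insert_concatemer(
    reference: list[SequenceRecord],
    construct_seq: str,
    locus: SimulatedLocus,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimulatedLocus]:
    """Insert a tandem concatemer with a target-site duplication.

    The modified scaffold is ``orig[:pos] + construct*copies +
    orig[pos-tsd:pos] + orig[pos:]`` — the ``tsd_len`` bases immediately 5'
    of the insertion reappear immediately 3' of the inserted block, the
    hallmark of transposase-mediated integration.  The returned truth
    record echoes the locus.  ``seed`` is accepted for interface symmetry;
    the operation itself is deterministic.
    """
    del seed
    by_id = {s.id: s for s in reference}
    if locus.scaffold_id not in by_id:
        raise ValueError(f"unknown scaffold {locus.scaffold_id!r}")
    target = by_id[locus.scaffold_id]
    if locus.insertion_pos >= len(target):
        raise ValueError("insertion_pos out of range")
    construct_seq = construct_seq.upper()
    block_unit = construct_seq if locus.orientation == "forward" else revcomp(construct_seq)
    pos, tsd = locus.insertion_pos, locus.tsd_len
    modified_seq = (
        target.sequence[:pos]
        + block_unit * locus.copy_number
        + target.sequence[pos - tsd : pos]
        + target.sequence[pos:]
    )
    out = []
    for s in reference:
        if s.id == locus.scaffold_id:
            out.append(SequenceRecord(s.id, modified_seq, s.description))
        else:
            out.append(s)
    return out, locus


def concatemer_span(locus: SimulatedLocus, construct_len: int) -> tuple[int, int]:
    """Half-open span of the inserted block plus its duplicated flank on
    the *modified* scaffold."""
    start = locus.insertion_pos
    end = start + locus.copy_number * construct_len + locus.tsd_len
    return start, end


# ---------------------------------------------------------------------------
# Capture-enriched paired-end reads
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        orig = arr[idx]
        subs = BASES[rng.integers(0, 4, size=len(idx))].astype("S1")
        # redraw collisions with the original base so every hit substitutes
        same = subs == orig
        while same.any():
            subs[same] = BASES[rng.integers(0, 4, size=int(same.sum()))].astype("S1")
            same = subs == orig
        arr[idx] = subs
    return arr.tobytes().decode()


def simulate_capture_pairs(
    modified_genome: list[SequenceRecord],
    construct_span: tuple[str, int, int],
    n_pairs: int,
    *,
    fragment_mean: int = DEFAULT_FRAGMENT_MEAN,
    fragment_sd: int = DEFAULT_FRAGMENT_SD,
    read_len: int = DEFAULT_READ_LEN,
    enrichment: float = DEFAULT_ENRICHMENT,
    error_rate: float = 0.0,
    seed: int = 0,
    pair_prefix: str = "pair",
) -> tuple[list[ReadPair], list[ReadPairTruth]]:
    """Simulate bait-capture paired-end sequencing of sheared fragments.

    Fragment lengths are Normal(``fragment_mean``, ``fragment_sd``)
    truncated below at ``read_len``.  Fragments overlapping the construct
    block (``construct_span`` = (scaffold, start, end) on the modified
    genome) are sampled with weight ``enrichment`` relative to background,
    emulating hybridization capture.  Mate 1 is the fragment 5' end read,
    mate 2 the reverse complement of the 3' end.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if read_len > fragment_mean:
        raise ValueError("read_len must not exceed fragment_mean")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")

    span_scaffold, span_start, span_end = construct_span
    by_id = {s.id: s for s in modified_genome}
    if span_scaffold not in by_id:
        raise ValueError(f"construct_span scaffold {span_scaffold!r} not in genome")
    if not (0 <= span_start <= span_end <= len(by_id[span_scaffold])):
        raise ValueError("construct_span outside genome")

    rng = np.random.default_rng(seed)
    names = [s.id for s in modified_genome]
    seqs = {s.id: s.sequence for s in modified_genome}
    lens = np.array([len(s) for s in modified_genome], dtype=np.int64)
    scaffold_p = lens / lens.sum()

    pairs: list[ReadPair] = []
    truths: list[ReadPairTruth] = []
    # rejection sampling against the enrichment weight, drawn in batches
    while len(pairs) < n_pairs:
        batch = max(1024, 2 * (n_pairs - len(pairs)))
        sc_idx = rng.choice(len(names), size=batch, p=scaffold_p)
        flen = np.rint(rng.normal(fragment_mean, fragment_sd, size=batch)).astype(int)
        flen = np.maximum(flen, read_len)
        starts = (rng.random(batch) * np.maximum(lens[sc_idx] - flen + 1, 1)).astype(int)
        u = rng.random(batch)
        for i in range(batch):
            if len(pairs) >= n_pairs:
                break
            name = names[sc_idx[i]]
            fl = int(flen[i])
            if fl > lens[sc_idx[i]]:
                continue
            start = int(starts[i])
            end = start + fl
            overlaps = (
                name == span_scaffold and start < span_end and end > span_start
            )
            weight = enrichment if overlaps else 1.0
            if u[i] >= weight / enrichment:
                continue
            frag = seqs[name][start:end]
            seq1 = _apply_errors(frag[:read_len], error_rate, rng)
            seq2 = _apply_errors(revcomp(frag[-read_len:]), error_rate, rng)
            pid = f"{pair_prefix}_{len(pairs):07d}"
            if not overlaps:
                origin = "genome"
            elif start >= span_start and end <= span_end:
                origin = "construct"
            elif start < span_start:
                origin = "junction_left"
            else:
                origin = "junction_right"
            pairs.append(ReadPair(pid, seq1, seq2))
            truths.append(ReadPairTruth(pid, origin, start, fl))
    return pairs, truths


def write_truth_bed(
    truths: list[ReadPairTruth], scaffold_id: str, path: str | os.PathLike
) -> None:
    """Tab-delimited BED-like truth file: scaffold, start, end, label."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{scaffold_id}\t{t.fragment_start}\t"
                f"{t.fragment_start + t.fragment_len}\t{t.origin}|{t.pair_id}\n"
            )


def read_truth_bed(path: str | os.PathLike) -> list[ReadPairTruth]:
    truths = []
    with open(path) as fh:
        for line in fh:
            _, start, end, label = line.rstrip("\n").split("\t")
            origin, pid = label.split("|")
            truths.append(ReadPairTruth(pid, origin, int(start), int(end) - int(start)))
    return truths


# ---------------------------------------------------------------------------
# Pedigree genotype tables
# ---------------------------------------------------------------------------


@dataclass
class MarkerSpec:
    """One STR/STS marker in a simulated cross.

    The transgenic parent is heterozygous ``linked_allele``/``unlinked_allele``
    with the linked allele in cis to the transgene; ``r`` is the
    recombination fraction between marker and transgene.
    """

    marker_id: str
    linked_allele: str
    unlinked_allele: str
    other_parent_alleles: tuple[str, str]
    r: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")


def simulate_genotype_table(
    markers: list[MarkerSpec],
    n_transgenic: int,
    n_nontransgenic: int,
    seed: int,
):
    """Simulate a sibling panel from transgenic x wild-type.

    Transgenic offspring carry the transgene-linked allele except at
    recombinant meioses drawn Bernoulli(r); non-transgenic offspring carry
    the unlinked allele except at recombinants.  The other parent
    transmits one of its alleles uniformly.  Returns (GenotypeTable,
    truth haplotype dict marker -> linked allele).
    """
    from .linkage import GenotypeTable, Individual, Marker

    ids = [m.marker_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids")
    if n_transgenic <= 0 or n_nontransgenic <= 0:
        raise ValueError("panel sizes must be > 0")
    rng = np.random.default_rng(seed)
    individuals = []
    genotypes: dict[tuple[str, str], tuple[str, str]] = {}
    n_total = n_transgenic + n_nontransgenic
    for i in range(n_total):
        transgenic = i < n_transgenic
        ind_id = f"{'tg' if transgenic else 'wt'}_{i + 1:03d}"
        individuals.append(Individual(ind_id, transgenic))
        for m in markers:
            recomb = rng.random() < m.r
            if transgenic:
                from_tg = m.unlinked_allele if recomb else m.linked_allele
            else:
                from_tg = m.linked_allele if recomb else m.unlinked_allele
            from_other = m.other_parent_alleles[rng.integers(0, 2)]
            genotypes[(ind_id, m.marker_id)] = tuple(sorted((from_tg, from_other)))
    table = GenotypeTable(
        individuals=individuals,
        markers=[Marker(m.marker_id, "sim", 0) for m in markers],
        genotypes=genotypes,
    )
    truth = {m.marker_id: m.linked_allele for m in markers}
    return table, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def simulate_counts(
    n_genes: int,
    samples: list[str],
    library_sizes: list[int],
    de_fraction: float,
    fold_change: float,
    dispersion: float,
    gene_lengths: list[int],
    seed: int,
    abundance_sigma: float = 0.0,
):
    """Negative-binomial count matrix with spiked fold changes.

    The first sample is the reference condition; DE genes are
    up-regulated by ``fold_change`` in every other sample.  Per-gene mean
    is library size x baseline abundance x fold, with baseline abundances
    lognormal(0, ``abundance_sigma``) normalized to sum to 1 — the default
    sigma of 0 gives a homogeneous baseline, under which the upper
    quartile is an uncontaminated null statistic and the downstream
    test's calibration is what the simulation measures (real
    transcriptomes are far more dispersed; see the methods note).
    ``dispersion`` is the NB overdispersion phi (var = mu + phi mu^2);
    phi = 0 degenerates to Poisson.  Returns (CountMatrix, CountTruth list).
    """
    from .dge import CountMatrix

    if len(samples) != len(library_sizes):
        raise ValueError("samples and library_sizes lengths differ")
    if len(gene_lengths) != n_genes:
        raise ValueError("gene_lengths must have one entry per gene")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if any(s <= 0 for s in library_sizes):
        raise ValueError("library sizes must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    abundance = rng.lognormal(0.0, abundance_sigma, size=n_genes)
    abundance /= abundance.sum()
    n_de = round(de_fraction * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, lib in enumerate(library_sizes):
        mu = lib * abundance
        if j > 0:
            mu = mu * np.where(is_de, fold_change, 1.0)
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
            counts[:, j] = rng.poisson(lam)

    lfc = float(np.log2(fold_change))
    truths = []
    for i, gid in enumerate(gene_ids):
        de = bool(is_de[i])
        pre = lfc if (de and len(samples) > 1) else 0.0
        tum = lfc if (de and len(samples) > 2) else 0.0
        truths.append(CountTruth(gid, pre, tum, de))
    matrix = CountMatrix(
        gene_ids=gene_ids,
        gene_lengths_bp=list(gene_lengths),
        sample_ids=list(samples),
        counts=counts,
    )
    return matrix, truths


def write_count_truth(truths: list[CountTruth], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "true_log2fc_pretumor": [t.true_log2fc_pretumor for t in truths],
            "true_log2fc_tumor": [t.true_log2fc_tumor for t in truths],
            "is_de": [int(t.is_de) for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_truth(path: str | os.PathLike) -> list[CountTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        CountTruth(
            r.gene_id,
            float(r.true_log2fc_pretumor),
            float(r.true_log2fc_tumor),
            bool(r.is_de),
        )
        for r in df.itertuples()
    ]
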