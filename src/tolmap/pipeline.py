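"""Stage orchestration for the three analysis arms.

Each ``run_*`` function is a pure-Python driver over the library modules:
it loads inputs, executes the stage chain, writes the declared report
files plus a machine-readable run manifest, and returns the in-memory
results so tests and scripts can assert on them directly.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import Parameters
from .dge import (
    CountMatrix,
    attach_qvalues,
    dge_contrast,
    fpkm_filter,
    group_by_direction,
    read_count_matrix,
    results_to_frame,
    upper_quartile_factors,
    write_count_matrix,
)
from .integration import (
    Breakpoint,
    CandidateSite,
    FilterTally,
    bin_interval_counts,
    breakpoint_report,
    call_candidate_sites,
    candidates_to_bed,
    evidence_to_frame,
    filter_chimeric_pairs,
    flag_repetitive,
    refine_breakpoint,
)
from .linkage import (
    count_recombinants,
    infer_linked_haplotype,
    linkage_report,
    mendelian_ratio_test,
    read_genotype_table,
    read_parent_genotypes,
)
from .seqio import (
    ExactSeedAligner,
    ReadPair,
    build_amended_reference,
    read_fasta,
    read_fastq_pair,
    write_fasta,
    write_fastq_pair,
)
from .synthetic import (
    SimulatedLocus,
    concatemer_span,
    insert_concatemer,
    simulate_capture_pairs,
    simulate_counts,
    simulate_reference,
    write_count_truth,
    write_truth_bed,
)

logger = logging.getLogger("tolmap")

CONSTRUCT_ID = "pTol2_construct"
GENOME_GC = 0.37  # approximate zebrafish GC content


def _write_manifest(out_dir: Path, stage: str, inputs: dict, params: dict, seed: int) -> None:
    manifest = {
        "stage": stage,
        "tolmap_version": __version__,
        "seed": seed,
        "inputs": inputs,
        "parameters": params,
    }
    (out_dir / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    reference_path: Path
    construct_path: Path
    sample_ids: list[str]
    r1_paths: list[Path]
    r2_paths: list[Path]
    truth_paths: list[Path]
    locus: SimulatedLocus
    construct_len: int


def simulate_integration_dataset(
    params: Parameters, out_dir: str | os.PathLike, seed: int | None = None
) -> SimulatedDataset:
    """Generate the full capture-sequencing input set with known truth.

    One scaffold genome, a random construct, a tandem concatemer inserted
    with the default transposon duplication model, and per-sample
    paired-end FASTQ with capture enrichment.  The insertion offset is
    drawn from the interior of its 1000 bp interval so the flanking
    evidence of a single-locus insertion falls in one interval.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed
    seeds = _child_seeds(seed, 3 + params.n_samples)

    genome = simulate_reference(1, [params.genome_length], GENOME_GC, seeds[0])
    construct = simulate_reference(
        1, [params.construct_length], 0.45, seeds[1], prefix=CONSTRUCT_ID
    )[0]
    construct.id = CONSTRUCT_ID

    rng = np.random.default_rng(seeds[2])
    bin_size = params.bin_size
    n_bins = params.genome_length // bin_size
    # interior offset: keeps the +-~350 bp evidence window inside one bin
    bin_idx = int(rng.integers(1, n_bins - 1))
    offset = int(rng.integers(int(0.4 * bin_size), int(0.6 * bin_size)))
    locus = SimulatedLocus(
        scaffold_id=genome[0].id,
        insertion_pos=bin_idx * bin_size + offset,
        copy_number=params.copy_number,
        tsd_len=params.tsd_len,
    )
    modified, truth_locus = insert_concatemer(genome, construct.sequence, locus)
    span = concatemer_span(truth_locus, len(construct))

    reference_path = out / "reference.fasta"
    construct_path = out / "construct.fasta"
    write_fasta(genome, reference_path)
    write_fasta([construct], construct_path)
    (out / "locus_truth.json").write_text(
        json.dumps(
            {
                "scaffold_id": locus.scaffold_id,
                "insertion_pos": locus.insertion_pos,
                "copy_number": locus.copy_number,
                "tsd_len": locus.tsd_len,
                "orientation": locus.orientation,
            },
            indent=2,
        )
        + "\n"
    )

    sample_ids, r1s, r2s, truths = [], [], [], []
    pairs_per_sample = params.n_pairs // params.n_samples
    for i in range(params.n_samples):
        sid = f"sample_{i + 1}"
        pairs, truth = simulate_capture_pairs(
            modified,
            (locus.scaffold_id, span[0], span[1]),
            pairs_per_sample,
            fragment_mean=params.fragment_mean,
            fragment_sd=params.fragment_sd,
            read_len=params.read_len,
            enrichment=params.enrichment,
            error_rate=params.error_rate,
            seed=seeds[3 + i],
            pair_prefix=sid,
        )
        r1, r2 = out / f"{sid}_R1.fastq", out / f"{sid}_R2.fastq"
        tpath = out / f"{sid}_truth.bed"
        write_fastq_pair(pairs, r1, r2)
        write_truth_bed(truth, locus.scaffold_id, tpath)
        sample_ids.append(sid)
        r1s.append(r1)
        r2s.append(r2)
        truths.append(tpath)
        logger.info("simulated %d pairs for %s", len(pairs), sid)

    _write_manifest(
        out, "simulate", {}, {**params.__dict__}, seed
    )
    return SimulatedDataset(
        reference_path, construct_path, sample_ids, r1s, r2s, truths, locus, len(construct)
    )


# ---------------------------------------------------------------------------
# map-integration
# ---------------------------------------------------------------------------


@dataclass
class IntegrationResult:
    candidates: list[CandidateSite]
    breakpoint: Breakpoint | None
    tallies: dict[str, FilterTally]
    n_evidence: int


def run_integration_mapping(
    reference_path: str | os.PathLike,
    construct_path: str | os.PathLike,
    sample_ids: list[str],
    r1_paths: list[str | os.PathLike],
    r2_paths: list[str | os.PathLike],
    params: Parameters,
    out_dir: str | os.PathLike,
    seed: int | None = None,
) -> IntegrationResult:
    """Chimeric filtering -> interval enrichment -> candidates -> breakpoint."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed
    t0 = time.time()

    genome = read_fasta(reference_path)
    construct = read_fasta(construct_path)[0]
    reference = build_amended_reference(genome, construct)
    aligner = ExactSeedAligner(reference, min_exact_seed=params.min_exact_seed)
    logger.info("aligner index built in %.1f s", time.time() - t0)

    all_reads: list[ReadPair] = []
    intervals_by_sample = {}
    tallies: dict[str, FilterTally] = {}
    evidence_frames = []
    n_evidence = 0
    for sid, r1, r2 in zip(sample_ids, r1_paths, r2_paths):
        pairs = read_fastq_pair(r1, r2)
        all_reads.extend(pairs)
        alignments = aligner.align_pairs(pairs)
        evidence, tally = filter_chimeric_pairs(alignments, sid, construct.id)
        tallies[sid] = tally
        n_evidence += len(evidence)
        logger.info(
            "%s: %d pairs -> %d chimeric (both_genome=%d both_construct=%d "
            "nonunique=%d unmapped=%d)",
            sid, tally.total(), tally.retained, tally.both_genome,
            tally.both_construct, tally.nonunique_genome, tally.unmapped,
        )
        intervals_by_sample[sid] = bin_interval_counts(evidence, params.bin_size)
        evidence_frames.append(evidence_to_frame(evidence))

    import pandas as pd

    pd.concat(evidence_frames, ignore_index=True).to_csv(
        out / "chimeric_evidence.tsv", sep="\t", index=False
    )

    genome_bins = max(
        1, sum(len(s) for s in genome) // params.bin_size
    )
    candidates = call_candidate_sites(
        intervals_by_sample,
        genome_bins=genome_bins,
        n_boot=params.n_boot,
        seed=seed,
        min_reads=params.min_reads,
        min_samples=params.min_samples,
        alpha=params.alpha,
        mode=params.bootstrap_mode,
    )
    candidates = [
        flag_repetitive(c, reference, k=params.repeat_k, max_copy=params.repeat_max_copy)
        for c in candidates
    ]
    (out / "candidates.bed").write_text(candidates_to_bed(candidates))

    bp = None
    surviving = [c for c in candidates if not c.repetitive]
    if surviving:
        bp = refine_breakpoint(surviving[0], all_reads, reference, construct)
        (out / "breakpoint_report.txt").write_text(breakpoint_report(bp))
        logger.info(
            "breakpoint: left=%s right=%s tsd=%s",
            bp.left_junction, bp.right_junction, bp.tsd_len,
        )

    _write_manifest(
        out,
        "map_integration",
        {
            "reference": str(reference_path),
            "construct": str(construct_path),
            "samples": {s: [str(a), str(b)] for s, a, b in zip(sample_ids, r1_paths, r2_paths)},
        },
        params.__dict__,
        seed,
    )
    return IntegrationResult(candidates, bp, tallies, n_evidence)


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


@dataclass
class LinkageRun:
    haplotype: list
    results: list
    mendelian: dict[str, float]


def run_linkage(
    genotype_table_path: str | os.PathLike,
    parent_genotypes_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    seed: int = 0,
) -> LinkageRun:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_genotype_table(genotype_table_path)
    tg_parent, other_parent = read_parent_genotypes(parent_genotypes_path)
    haplotype = infer_linked_haplotype(table, tg_parent, other_parent)
    results = count_recombinants(table, haplotype, tg_parent, other_parent)
    n_tg = sum(1 for i in table.individuals if i.transgenic)
    n_wt = len(table.individuals) - n_tg
    mend = mendelian_ratio_test(n_tg, n_wt)
    (out / "linkage_report.tsv").write_text(linkage_report(haplotype, results))
    _write_manifest(
        out,
        "linkage",
        {"genotype_table": str(genotype_table_path), "parents": str(parent_genotypes_path)},
        {},
        seed,
    )
    logger.info("Mendelian 1:1 test: %d:%d p=%.3g", n_tg, n_wt, mend["p"])
    return LinkageRun(haplotype, results, mend)


# ---------------------------------------------------------------------------
# dge
# ---------------------------------------------------------------------------


@dataclass
class DGERun:
    pretumor: list
    tumor: list
    groups: dict[str, list[str]]
    gene_set: list[str]


def run_dge(
    counts_path: str | os.PathLike,
    params: Parameters,
    out_dir: str | os.PathLike,
    seed: int = 0,
    samples: tuple[str, str, str] | None = None,
) -> DGERun:
    """FPKM gate -> UQ normalization -> Fisher tests -> q-values -> groups."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = read_count_matrix(counts_path)
    if samples is None:
        if len(m.sample_ids) < 3:
            raise ValueError(
                "dge stage expects three samples (reference, pretumor, tumor)"
            )
        ref, pre, tum = m.sample_ids[:3]
    else:
        ref, pre, tum = samples
        for s in samples:
            if s not in m.sample_ids:
                raise KeyError(f"sample {s!r} not found in count matrix")
    gene_set = fpkm_filter(m, ref, params.fpkm_threshold)
    logger.info("%d/%d genes pass FPKM >= %g in %s", len(gene_set), len(m.gene_ids), params.fpkm_threshold, ref)
    factors = upper_quartile_factors(m)
    pre_res = attach_qvalues(
        dge_contrast(m, factors, ref, pre, gene_set=gene_set, pseudocount=params.pseudocount),
        method=params.qvalue_method,
    )
    tum_res = attach_qvalues(
        dge_contrast(m, factors, ref, tum, gene_set=gene_set, pseudocount=params.pseudocount),
        method=params.qvalue_method,
    )
    groups, heat = group_by_direction(
        pre_res, tum_res, q_threshold=params.q_threshold, fc_threshold=params.fc_threshold
    )
    results_to_frame(pre_res, tum_res, groups).to_csv(
        out / "dge_results.tsv", sep="\t", index=False
    )
    heat.to_csv(out / "log2fc_heat_matrix.tsv", sep="\t")
    _write_manifest(out, "dge", {"counts": str(counts_path)}, params.__dict__, seed)
    return DGERun(pre_res, tum_res, groups, gene_set)


def simulate_dge_dataset(
    params: Parameters, out_dir: str | os.PathLike, seed: int | None = None
):
    """Three-sample count matrix with spiked fold changes + truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lengths = [int(x) for x in rng.integers(500, 5000, size=params.n_genes)]
    matrix, truths = simulate_counts(
        params.n_genes,
        ["WildType", "Pretumor", "Tumor"],
        [params.library_size] * 3,
        params.de_fraction,
        params.fold_change,
        params.dispersion,
        lengths,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts_path = out / "counts.tsv"
    write_count_matrix(matrix, counts_path)
    write_count_truth(truths, out / "counts_truth.tsv")
    return counts_path, matrix, truths
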