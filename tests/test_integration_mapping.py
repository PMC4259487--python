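"""Chimeric filtering, interval enrichment, candidate calling, repeat
flagging and breakpoint/TSD resolution, including end-to-end parameter
recovery against simulator truth."""

import numpy as np
import pytest

from tolmap.config import Parameters
from tolmap.integration import (
    CandidateSite,
    ChimericEvidence,
    IntervalStat,
    bin_interval_counts,
    bootstrap_interval_pvalues,
    call_candidate_sites,
    filter_chimeric_pairs,
    flag_repetitive,
    refine_breakpoint,
)
from tolmap.pipeline import run_integration_mapping, simulate_integration_dataset
from tolmap.seqio import (
    ExactSeedAligner,
    MateAlignment,
    PairAlignment,
    ReadPair,
    SequenceRecord,
    UNMAPPED,
    build_amended_reference,
)
from tolmap.synthetic import (
    SimulatedLocus,
    concatemer_span,
    insert_concatemer,
    simulate_capture_pairs,
    simulate_reference,
)


def _pa(pair_id, m1, m2):
    return PairAlignment(pair_id, m1, m2)


GENOME_MATE = MateAlignment("chr", 100, "+", 1, 75)
CONSTRUCT_MATE = MateAlignment("pTol2", 5, "-", 3, 75)


class TestFilterChimericPairs:
    def test_single_chimeric_pair_retained(self):
        evidence, tally = filter_chimeric_pairs(
            [_pa("p", CONSTRUCT_MATE, GENOME_MATE)], "s1", "pTol2"
        )
        assert len(evidence) == 1 and tally.retained == 1
        ev = evidence[0]
        assert ev.genome_scaffold == "chr" and ev.genome_pos == 100
        assert ev.side == "left"  # + strand genome mate reads into the insertion
        assert ev.construct_offset == 5

    def test_discard_reasons_tallied(self):
        alignments = [
            _pa("g", GENOME_MATE, MateAlignment("chr", 500, "-", 1, 75)),
            _pa("c", CONSTRUCT_MATE, MateAlignment("pTol2", 9, "+", 2, 75)),
            _pa("n", CONSTRUCT_MATE, MateAlignment("chr", 10, "+", 4, 75)),
            _pa("u", CONSTRUCT_MATE, MateAlignment(UNMAPPED)),
        ]
        evidence, tally = filter_chimeric_pairs(alignments, "s1", "pTol2")
        assert not evidence
        assert (tally.both_genome, tally.both_construct) == (1, 1)
        assert (tally.nonunique_genome, tally.unmapped) == (1, 1)

    def test_evidence_conservation(self, small_insertion):
        """Retained + discard tallies account for every input pair."""
        aligner = ExactSeedAligner(small_insertion["reference"])
        pairs, _ = small_insertion["samples"]["s1"]
        alignments = aligner.align_pairs(pairs)
        evidence, tally = filter_chimeric_pairs(alignments, "s1", "construct")
        assert tally.total() == len(pairs)
        assert tally.retained == len(evidence)

    def test_simulator_truth_identifies_surviving_pairs(self, small_insertion):
        """Every retained pair is junction-derived per the truth records,
        and every junction pair with both mates cleanly placed survives."""
        aligner = ExactSeedAligner(small_insertion["reference"])
        locus = small_insertion["locus"]
        span = small_insertion["span"]
        read_len = 75
        pairs, truths = small_insertion["samples"]["s1"]
        alignments = aligner.align_pairs(pairs)
        evidence, _ = filter_chimeric_pairs(alignments, "s1", "construct")
        retained = {e.pair_id for e in evidence}
        junction = {t.pair_id for t in truths if t.origin.startswith("junction")}
        assert retained <= junction
        # oracle: junction pairs whose mates do not straddle any junction
        block_len = span[1] - span[0]
        copy_len = small_insertion["construct"].sequence
        clean = set()
        boundaries = [span[0] + i * len(copy_len) for i in range(locus.copy_number + 1)]
        boundaries.append(span[1])
        for t in truths:
            if not t.origin.startswith("junction"):
                continue
            m1 = (t.fragment_start, t.fragment_start + read_len)
            end = t.fragment_start + t.fragment_len
            m2 = (end - read_len, end)
            def straddles(iv):
                return any(iv[0] < b < iv[1] for b in boundaries)
            # one mate fully construct-internal (within one copy), the other
            # fully genomic
            def classify(iv):
                if iv[1] <= span[0] or iv[0] >= span[1]:
                    return "genome"
                if not straddles(iv):
                    return "construct"
                return "split"
            kinds = {classify(m1), classify(m2)}
            if kinds == {"genome", "construct"}:
                clean.add(t.pair_id)
        assert clean <= retained


class TestBinIntervalCounts:
    def _ev(self, pos, sample="s1"):
        return ChimericEvidence("p", sample, "chr3", pos, "+", "left", 0)

    def test_same_bin_aggregation(self):
        out = bin_interval_counts([self._ev(24_212_800), self._ev(24_212_900)])
        assert len(out) == 1
        assert (out[0].start, out[0].read_count) == (24_212_000, 2)

    def test_empty_input(self):
        assert bin_interval_counts([]) == []

    def test_half_open_boundary(self):
        out = bin_interval_counts([self._ev(999), self._ev(1000)])
        assert [(iv.start, iv.read_count) for iv in out] == [(0, 1), (1000, 1)]

    def test_samples_supporting_counts_distinct_ids(self):
        out = bin_interval_counts(
            [self._ev(10, "a"), self._ev(20, "a"), self._ev(30, "b")]
        )
        assert out[0].samples_supporting == 2


class TestBootstrapPvalues:
    def test_minimum_attainable_p_for_extreme_bin(self):
        iv = [IntervalStat("c", 0, 1000, read_count=50)]
        out = bootstrap_interval_pvalues(iv, genome_bins=1000, n_boot=999, seed=1)
        assert out[0].p_boot == pytest.approx(1 / 1000)

    def test_singleton_counts_not_significant_under_max_mode(self):
        ivs = [IntervalStat("c", i * 1000, 1000, read_count=1) for i in range(500)]
        out = bootstrap_interval_pvalues(
            ivs, genome_bins=500, n_boot=200, seed=2, mode="max_count"
        )
        assert all(iv.p_boot > 0.99 for iv in out)

    def test_deterministic_given_seed(self):
        ivs = [IntervalStat("c", i * 1000, 1000, read_count=c) for i, c in enumerate([3, 1, 7])]
        a = bootstrap_interval_pvalues(ivs, 100, 500, seed=9, mode="per_interval")
        b = bootstrap_interval_pvalues(ivs, 100, 500, seed=9, mode="per_interval")
        assert [x.p_boot for x in a] == [x.p_boot for x in b]

    def test_zero_reads_warns_and_returns_one(self):
        ivs = [IntervalStat("c", 0, 1000, read_count=0)]
        with pytest.warns(UserWarning):
            out = bootstrap_interval_pvalues(ivs, 10, 10, seed=1)
        assert out[0].p_boot == 1.0

    def test_per_interval_null_calibration(self):
        """Uniform multinomial null: empirical p-values are valid,
        P(p <= alpha) <= alpha + Monte-Carlo error."""
        rng = np.random.default_rng(12)
        fracs = []
        for seed in range(5):
            counts = rng.multinomial(1000, np.full(400, 1 / 400))
            ivs = [
                IntervalStat("c", i * 1000, 1000, read_count=int(c))
                for i, c in enumerate(counts)
                if c > 0
            ]
            out = bootstrap_interval_pvalues(
                ivs, genome_bins=400, n_boot=400, seed=seed, mode="per_interval"
            )
            p = np.array([iv.p_boot for iv in out])
            fracs.append((p <= 0.05).mean())
        assert np.mean(fracs) <= 0.05 + 0.02


class TestCallCandidateSites:
    def _intervals(self, specs, bin_size=1000):
        # specs: {sample: [(start, count)]}
        return {
            s: [IntervalStat("c", st, bin_size, read_count=c) for st, c in ivs]
            for s, ivs in specs.items()
        }

    def test_pooled_high_support_site_called(self):
        ivs = self._intervals({f"s{i}": [(24_212_000, 16)] for i in range(5)})
        sites = call_candidate_sites(ivs, genome_bins=1000, n_boot=199, seed=1)
        assert len(sites) == 1
        assert sites[0].total_support == 80
        assert sites[0].interval.samples_supporting == 5

    def test_below_min_reads_not_called(self):
        ivs = self._intervals({"s1": [(0, 4)], "s2": [(0, 4)]})
        assert not call_candidate_sites(ivs, genome_bins=100, n_boot=99, seed=1)

    def test_single_sample_support_not_called(self):
        ivs = self._intervals({"s1": [(0, 20)]})
        assert not call_candidate_sites(ivs, genome_bins=100, n_boot=99, seed=1)

    def test_min_reads_monotonicity(self):
        rng = np.random.default_rng(3)
        ivs = self._intervals(
            {
                "s1": [(i * 1000, int(c)) for i, c in enumerate(rng.integers(1, 30, 8))],
                "s2": [(i * 1000, int(c)) for i, c in enumerate(rng.integers(1, 30, 8))],
            }
        )
        previous = None
        for min_reads in (5, 10, 20, 40):
            called = {
                (s.scaffold, s.interval.start)
                for s in call_candidate_sites(
                    ivs, genome_bins=100, n_boot=199, seed=4, min_reads=min_reads
                )
            }
            if previous is not None:
                assert called <= previous
            previous = called

    def test_inconsistent_bin_sizes_rejected(self):
        ivs = {
            "s1": [IntervalStat("c", 0, 1000, read_count=5)],
            "s2": [IntervalStat("c", 0, 500, read_count=5)],
        }
        with pytest.raises(ValueError, match="bin sizes"):
            call_candidate_sites(ivs, genome_bins=100, n_boot=9, seed=1)


def _site(scaffold, start, bin_size=1000, support=20):
    iv = IntervalStat(scaffold, start, bin_size, read_count=support, samples_supporting=2)
    return CandidateSite(scaffold, iv, {"s1": support}, support)


class TestFlagRepetitive:
    def test_unique_sequence_not_flagged(self):
        genome = simulate_reference(1, [20_000], 0.5, seed=21)
        ref = build_amended_reference(genome, SequenceRecord("c", "A" * 100))
        site = flag_repetitive(_site(genome[0].id, 5000), ref)
        assert not site.repetitive and site.status == "candidate"

    def test_tandem_repeat_flagged(self):
        unit = simulate_reference(1, [1000], 0.5, seed=22)[0].sequence
        genome = [SequenceRecord("rep", unit * 10 + simulate_reference(1, [5000], 0.5, seed=23)[0].sequence)]
        ref = build_amended_reference(genome, SequenceRecord("c", "A" * 100))
        site = flag_repetitive(_site("rep", 2000), ref)
        assert site.repetitive and site.status == "rejected_repetitive"

    def test_k_longer_than_interval_rejected(self):
        genome = simulate_reference(1, [3000], 0.5, seed=24)
        ref = build_amended_reference(genome, SequenceRecord("c", "A" * 100))
        with pytest.raises(ValueError, match="shorter than k"):
            flag_repetitive(_site(genome[0].id, 2500, bin_size=1000), ref, k=2000)


class TestRefineBreakpoint:
    def _setup(self, tsd_len, seed=31, n_pairs=2500):
        genome = simulate_reference(1, [40_000], 0.4, seed=seed)
        construct = simulate_reference(1, [1200], 0.45, seed=seed + 1, prefix="c")[0]
        construct.id = "construct"
        pos = 20_480
        locus = SimulatedLocus(genome[0].id, pos, 2, tsd_len)
        modified, _ = insert_concatemer(genome, construct.sequence, locus)
        span = concatemer_span(locus, len(construct))
        pairs, _ = simulate_capture_pairs(
            modified, (locus.scaffold_id, *span), n_pairs, enrichment=50.0, seed=seed + 2
        )
        ref = build_amended_reference(genome, construct)
        return genome, construct, locus, pairs, ref

    def test_tsd_recovered_exactly(self):
        genome, construct, locus, pairs, ref = self._setup(8)
        bp = refine_breakpoint(_site(genome[0].id, 20_000), pairs, ref, construct)
        assert bp.tsd_len == 8
        assert bp.left_junction == locus.insertion_pos - 1
        assert bp.right_junction == locus.insertion_pos - 8
        assert bp.tsd_seq == genome[0].sequence[locus.insertion_pos - 8 : locus.insertion_pos]

    def test_blunt_junction_tsd_zero(self):
        genome, construct, locus, pairs, ref = self._setup(0)
        bp = refine_breakpoint(_site(genome[0].id, 20_000), pairs, ref, construct)
        assert bp.tsd_len == 0
        assert bp.left_junction == bp.right_junction - 1

    def test_one_sided_coverage_leaves_tsd_unset(self):
        genome, construct, locus, pairs, ref = self._setup(8)
        # drop every pair touching the construct 3' end so only the left
        # junction is covered
        tail = construct.sequence[-15:]
        from tolmap.seqio import revcomp

        left_only = [
            p
            for p in pairs
            if tail not in p.seq1
            and tail not in p.seq2
            and tail not in revcomp(p.seq1)
            and tail not in revcomp(p.seq2)
        ]
        bp = refine_breakpoint(_site(genome[0].id, 20_000), left_only, ref, construct)
        assert bp.right_junction is None
        assert bp.tsd_len is None

    def test_repetitive_site_rejected(self):
        genome, construct, locus, pairs, ref = self._setup(8)
        site = _site(genome[0].id, 20_000)
        site.repetitive = True
        with pytest.raises(ValueError):
            refine_breakpoint(site, pairs, ref, construct)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", range(0, 20))
    def test_parameter_recovery_random_loci(self, seed):
        """For random loci (copies 2-20, TSD 0-10) the top candidate
        interval contains the truth and the TSD is recovered exactly from
        error-free reads."""
        rng = np.random.default_rng(1000 + seed)
        params = Parameters(
            genome_length=100_000,
            construct_length=1500,
            copy_number=int(rng.integers(2, 21)),
            tsd_len=int(rng.integers(0, 11)),
            n_pairs=2400,
            n_samples=2,
            seed=seed,
        )
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            ds = simulate_integration_dataset(params, d, seed=seed)
            res = run_integration_mapping(
                ds.reference_path,
                ds.construct_path,
                ds.sample_ids,
                ds.r1_paths,
                ds.r2_paths,
                params,
                d,
                seed=seed,
            )
            top = [c for c in res.candidates if not c.repetitive][0]
            assert (
                top.interval.start
                <= ds.locus.insertion_pos
                < top.interval.start + top.interval.bin_size
            )
            assert res.breakpoint is not None
            assert res.breakpoint.tsd_len == ds.locus.tsd_len
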