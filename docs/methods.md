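# Methods

This note documents the models and procedures implemented in `tolmap`,
the parameters that matter, the design choices made where the published
description left the design open, and what the synthetic data do and do
not establish about behaviour on real data.

## Integration-site mapping

### Alignment and the amended reference

The production path for this analysis is an external spliced/gapped
aligner producing SAM against the genome amended with the construct as an
extra scaffold; `tolmap.seqio.read_sam` ingests such files (QNAME, FLAG,
RNAME, POS, MAPQ, CIGAR; NH used for hit counts when present).  For
self-contained synthetic work the package includes a deliberately small
exact-seed aligner: a mate maps wherever its sequence (or reverse
complement) matches the reference with >= 95% identity (substitutions
only) anchored by an exact seed of `min_exact_seed` bases (default 20).
`n_best_hits` counts equal-best placements and the primary hit is the
deterministic minimum of (scaffold id, position, strand).  This is
sufficient for reads from the substitution-only simulator; it does not
attempt gapped or spliced alignment.

"Unique genomic location" is operationalised as `n_best_hits == 1`
(internal aligner) or MAPQ >= 30 (SAM path) — the conventional
uniqueness proxy; the threshold is a parameter.

Coordinates are 0-based half-open internally; reports print 1-based
positions.

### Chimeric filtering

A pair becomes integration evidence iff one mate maps to the construct
scaffold (any multiplicity — the concatemer makes construct multi-mapping
expected) and the other maps uniquely to a genome scaffold.  Discards are
tallied by reason (both-genome, both-construct, non-unique genome mate,
unmapped) and the tallies always appear in the stage log: they are part
of the method's audit trail, and retained + discarded equals the input
pair count by construction.  Side assignment: a genome mate on the +
strand reads toward the insertion from the left flank, a − strand mate
from the right; the convention is covered by simulator-truth tests.

### Interval enrichment and the bootstrap null

Genome-mate positions are counted in fixed `bin_size` = 1000 bp half-open
bins.  The null model throws the observed total read count N uniformly
over the genome's M bins, B times (`n_boot`, default 999), generated
exactly by a sequential conditional-binomial decomposition of the
multinomial so B×M never has to be materialised.  Two empirical p-values
are available, both with +1 smoothing so p is never 0:

- `per_interval`: each interval's count is compared with its own bin's
  null counts — a per-interval empirical p, uniform up to the
  discreteness of the counts under the null;
- `max_count` (default): each interval's count is compared with the
  per-replicate *maximum* bin count — a family-wise calibrated p,
  appropriate because candidate discovery scans the entire genome and
  only a handful of survivors are wanted.

Candidate calling pools counts across samples (per-sample support is
retained for reporting) and requires pooled support >= `min_reads`
(default 9), distinct supporting samples >= `min_samples` (default 2,
operationalising "multiple samples"), and pooled p <= `alpha` (0.05).
Whether the 9-read rule should be pooled or per sample is not decidable
from the published description; pooled is the default and both knobs are
config.

### Repeat flagging and breakpoint refinement

Candidates are screened for repetitive DNA by k-mer copy number: the mean
genome-wide occurrence of the interval's canonical k-mers (k = 25) must
not exceed `max_copy` = 2, else the site is rejected as non-specific
capture.  This stands in for whatever repeat assessment the original
analysis used, which is not described.

Breakpoint refinement scans all reads (both orientations) for split
composition: >= 15 exactly matching bases of genome joined to >= 15
bases of a construct *end* (5' prefix or 3' suffix).  The left junction
is the maximum genomic coordinate adjacent to a construct 5'-end match;
the right junction the minimum genomic coordinate adjacent to a 3'-end
match.  A positive overlap `left − right + 1` is the target-site
duplication, and its sequence is extracted from the unmodified reference;
a blunt junction gives `left = right − 1` and TSD 0.  A side with no
split reads is reported as unresolved and the TSD left unset — never
fabricated.  Internal copy-to-copy junctions of the concatemer
self-screen: their "genomic" part is construct sequence and finds no
match near the candidate interval.

## Synthetic capture data

`simulate_reference` draws i.i.d. bases at a target GC (0.37 by default
for the genome, roughly teleost-like).  `insert_concatemer` builds
`genome[:pos] + construct×copies + genome[pos−tsd:pos] + genome[pos:]`,
i.e. tandem head-to-tail copies with the `tsd_len` bases immediately
upstream duplicated after the block.  Defaults follow the modelled
design: 8 bp duplication (the Tol2 signature), configurable copy number
(the modelled line carries ~100 copies; mapping-scale simulations use 10
— recovery depends only on the array's outer junctions, so internal copy
count and order are irrelevant, and the real array is known to be
internally disorganised).

`simulate_capture_pairs` draws fragment lengths Normal(250, 30) truncated
below at the read length (the protocol states only "~250 bp"; sd 30 is a
design choice), samples fragment positions uniformly, and accepts
fragments overlapping the construct block with weight `enrichment`
relative to background (default 50 — the real bait-capture enrichment is
unmeasured; the value is exposed in config).  Mate 1 is the fragment 5'
read, mate 2 the reverse complement of the 3' end, 75 bp each, constant
quality, with an optional uniform substitution error model (no indels —
the downstream analysis never models them).  Truth records (origin
class, fragment coordinates) accompany every pair.

The simulation-driven dataset places the insertion at a uniformly drawn
bin with offset drawn from the interior (40–60%) of its 1000 bp
interval, so the ±~350 bp window of flanking evidence from ~250 bp
fragments falls within a single interval; an insertion very close to a
bin boundary would split its support across two adjacent intervals, which
is a property of fixed binning, not of the evidence.

What the capture simulator does **not** emulate: bait hybridisation
thermodynamics, PCR duplicates, barcode errors, indels, coverage bias, or
genuinely repetitive genome background (the genome is i.i.d. random, so
repeat flagging is exercised with explicitly constructed tandem arrays in
tests).  Recovery results on this data show the pipeline logic is
correct, not that it is robust to real-capture artefacts.

## STR linkage

Genotypes are unordered allele-label pairs (L/M/S by PCR product size).
For each marker the set of alleles the transgenic parent could have
transmitted to an offspring is computed from both parental genotypes; the
linked allele is the unique transgenic-parent allele transmissible to
every transgenic sibling and to no non-transgenic sibling.  If no single
allele separates the classes (e.g. both parents share the same
heterozygous genotype, or the panel contains a recombinant) the marker is
uninformative — phasing therefore belongs on a small clean sibling
panel, with recombinant counting on the large panel, as in the original
two-stage design.  Recombinant counting uses only offspring whose
transmitted allele is unambiguous; missing (NA) cells are skipped.  Map
distance is the direct estimator cM = 100·r with no Haldane/Kosambi
correction, matching the 1/100 → 1 cM arithmetic at these distances.
Mendelian transmission uses `scipy.stats.binomtest` (exact, two-sided,
p = 1/2).

The published 20-sibling and 200-offspring tables are encoded in
`tolmap.panels` from their per-marker tallies; the tallies are marginal,
so individuals are assigned genotypes row-wise — all implemented
inference depends only on the marginals.

## No-replicate differential expression

FPKM = count / (gene length in kb × million mapped fragments); the gene
universe is FPKM >= `fpkm_threshold` (default 1) in the reference
sample.

Upper-quartile factors: all-zero genes removed, per-sample 75th
percentile of the remaining counts, scale factors geometric-mean centred
(`factor_s = geomean(UQ)/UQ_s`) so rescaled counts stay on the count
scale.  Re-applying the procedure to already-normalized counts returns
factors of 1.

Per-gene testing follows the published order — normalize, then test.
The two-sided Fisher exact test (point-probability rule; the doubling
rule is available as an option) compares each gene's upper-quartile
rescaled count between the two samples against a **common effective
library size** (the mean of the normalized totals).  Using each sample's
own realized total as the margin instead would make the test sensitive to
library *composition*: strong asymmetric differential expression inflates
one library's total, shifting every null gene's proportion, and at
typical per-gene depths the exact test rejects essentially all of them.
With the common margin the test is the conditional comparison of
normalized expression (asymptotically the binomial p = 1/2 test on the
pair of normalized counts), calibrated whenever the normalization itself
is accurate.  Fold change is the ratio of pseudocounted normalized
counts, `((c_B + 1)·s_B) / ((c_A + 1)·s_A)`; the pseudocount (default 1)
guards the ratio for zero counts and never enters the test.

q-values: Storey's estimator with the λ grid 0.05–0.95 (step 0.05), a
cubic smoothing spline extrapolated to λ = 0.95 for π̂₀, clipped to
(0, 1]; q_i = π̂₀ · min over p_j >= p_i of p_j·m/rank(p_j).  Below 100
tests the smoother is unstable and plain BH (π̂₀ = 1) is used.  Direction
groups take q <= 0.05 and fold change >= 2 (or <= 1/2), and the log2
fold-change heat matrix is exported as TSV.

### Calibration caveats — read before trusting q-values on real data

Two distinct effects limit the no-replicate Fisher design, and the
synthetic defaults are chosen to isolate the machinery from them:

1. **Overdispersion.** Fisher's exact test assumes the two observed
   counts are conditionally binomial, which holds for Poisson libraries
   but not for biological replicates (negative-binomial variation makes
   the test anticonservative).  The generator's `dispersion` parameter
   adds NB noise (var = μ + φμ²); calibration statements in the tests
   use φ = 0 on purpose.
2. **Normalization pollution.** The upper quartile is a null-gene
   statistic only while differential genes stay clear of it.  With a
   realistic expression dynamic range (lognormal abundances, σ ≈ 1) an
   asymmetric 5%-of-genes, 8-fold spike drags the spiked sample's upper
   quartile up by ~10%, and at ~10³ reads per gene the exact test
   resolves a 10% normalization error on every null gene — the false
   discovery rate is then badly inflated *no matter how the test is
   implemented*.  The generator therefore defaults to a homogeneous
   baseline (`abundance_sigma = 0`), under which the upper quartile is
   uncontaminated and the measured FDR reflects the testing machinery.
   Setting `abundance_sigma` to ~1 reproduces the realistic failure
   mode.

Passing parameter-recovery and FDR checks on the default simulation
therefore certifies the implementation, not the method's robustness on
real transcriptomes; on real data the design over-calls, which is the
known cost of a no-replicate study.

### Simulated counts

`simulate_counts` draws gene counts NB(mean = library size × abundance ×
fold) with the first sample as reference; DE genes (a deterministic
`round(de_fraction × n_genes)` of them, chosen uniformly) are spiked
*upward* by `fold_change` in every non-reference sample.  A
single-direction spike keeps "the median estimated fold change of true-DE
genes" a meaningful recovery target; directionally mixed designs can be
composed by calling the generator twice.  Defaults mirror the analysis
scale used throughout: 2,000 genes, three samples
(WildType/Pretumor/Tumor), 2×10⁶-read libraries, 5% DE at fold 8,
Poisson (φ = 0), gene lengths uniform on 500–5000 bp.

## Numerical and reproducibility choices

- One RNG discipline: every stochastic operation takes an explicit seed
  and uses `numpy.random.default_rng`; stage drivers derive child seeds
  (< 2³¹) from the run seed, and the run manifest records it, making
  outputs byte-reproducible.
- Empirical p-values use +1 smoothing (never 0); Fisher ties are grouped
  with a 1 + 1e−7 relative tolerance (safe for exact ties at any table
  total where distinct hypergeometric probabilities are separated by more
  than that).
- Degenerate inputs: zero evidence reads → all bootstrap p = 1 with a
  warning; degenerate Fisher margins → p = 1; a sample whose
  post-exclusion upper quartile is 0 is an error naming the sample; zero
  informative meioses is an error naming the marker.
- Tie-breaks (primary alignment, candidate ordering) are total orders, so
  reruns are identical.

## Known limitations

- The toy aligner is exact-seed, substitution-only; real data should
  enter via SAM from a production aligner.
- Repeat flagging measures k-mer copy number against the supplied
  reference only; it cannot see repeats absent from the assembly.
- Breakpoint refinement requires error-free or near-error-free split
  reads over >= 15 bp on each side of the junction; heavily degraded
  junction reads leave a side unresolved.
- Linkage phasing requires a recombinant-free phasing panel at each
  informative marker.
- The DGE arm reproduces a 2014-era no-replicate design faithfully,
  including its statistical weaknesses (see calibration caveats); it is
  not a substitute for replicate-aware models.
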