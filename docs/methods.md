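# Methods

## Read assignment model

The unit of counting is a read mate: paired-end mates are partitioned,
aligned and counted independently (no fragment-level deduplication), so
a fragment whose mates both land in repeats contributes two units.

A read is **uniquely mapping** when the aligner (or the internal
matcher) reports exactly one genomic placement; it is then assigned to
every subfamily whose annotated instance its genomic interval overlaps
by at least 1 bp (the bedtools-intersect default; a fractional-overlap
threshold is available). A uniquely-placed read overlapping instances
of several subfamilies is treated exactly like a multi-mapping read
with that subfamily set, keeping one uniform N_s semantics.

A **multi-mapping** read is aligned to all per-subfamily pseudogenomes;
its set S_r is the set of subfamilies with at least one alignment
(multiple hits within one pseudogenome collapse). Reads aligning to no
pseudogenome are dropped and reported in the read-fate log. Alignments
that touch only the 15 bp flank of a pseudogenome still count; with the
default flank the effect is marginal.

Counting: total(s) = #{r : s ∈ S_r}; unique(s) = #{r : S_r = {s}};
fractional(s) = Σ 1/N_s(r) over r containing s. Fractional counts are
rounded to the nearest integer for export; rounding ties go to even
(the convention is configurable only in the sense that the unrounded
values are always retained and used for all invariant checks). The
unrounded values satisfy exactly: Σ_s fractional(s) = number of
repeat-assigned reads, and unique ≤ fractional ≤ total per subfamily.

**Library size** defaults to uniquely-mapped reads plus multi-mapping
reads assigned to ≥ 1 pseudogenome; a caller-supplied total (e.g. the
mapping total of an external spliced alignment) overrides it, matching
practice for RNA-seq where the repeat pipeline deliberately excludes
splice-junction reads.

## Pseudogenomes

One sequence per subfamily: each genomic instance extracted on the
**plus strand** (downstream matchers search both strands; the
annotation strand is kept as metadata) with up to `flank_bp` (default
15) of genomic flank, clamped at contig edges, joined by `spacer_bp`
(default 200) copies of `N`. N never matches any base under the
internal matcher or standard aligners, so no read can align across a
junction. Overlapping instances of one subfamily are extracted
independently; counting is per-read, so the duplicated bases are
harmless. Instance order inside a pseudogenome is annotation order,
and pseudogenome files are emitted in sorted subfamily order with
sanitized filenames — all outputs are byte-reproducible.

## Internal matcher

All desk-scale alignment uses an exact all-placements matcher under a
Hamming threshold (default ≤ 2 substitutions, no indels, both
strands). Implementation: the read is split into `m+1` disjoint
pieces; any placement with ≤ m mismatches contains an exact piece
(pigeonhole), so an exact k-mer index over the targets enumerates all
candidates, each verified by direct comparison. The placement set is
therefore provably identical to a naive full scan, which is kept in
`fixtures.brute_force_align` as the test oracle. Ambiguity characters
mismatch everything, including themselves.

## ChIP-seq simulator

A two-state Markov chain (low/high) advances one state per base pair.
Inside user-supplied feature intervals it uses the feature transition
matrix, elsewhere the background matrix. Per-base sampling weights are
drawn Normal(mean_state, sd_state) and clamped at 0; read starts are
drawn from the categorical distribution proportional to the weights
over valid start positions, strands uniform, base calls error-free,
output FASTA (optional constant-quality FASTQ and a true-coordinate
SAM).

Parameter defaults and rationale:

* high-state emission mean 3.0, sd 0.1 (the published simulation
  setting); the low-state mean is not printed anywhere we could find,
  so the default is 1.0 with sd 0.1, giving a 3:1 high:low weight
  ratio consistent with the visible enrichment in the source figures —
  both are configurable;
* background transitions [[0.999, 0.001], [0.20, 0.80]]: the
  background strongly favours low with rare, short high excursions
  (narrow spurious peaks, i.e. normal background variability);
* feature transitions [[0.10, 0.90], [0.01, 0.99]]: predominant
  high-state occupancy (stationary P(high) ≈ 0.99) over enriched
  features.

Technical variance between replicates: replicate r re-draws the hidden
path and the emissions with seed base + r. This is an interpretation —
the original description names "a parameter to introduce technical
variance" without specifying the mechanism; re-drawing the path is the
simplest mechanism that perturbs both peak placement and sampling
weights.

Closed forms used in validation: on a homogeneous stretch the
high-state occupancy converges to a/(a+b) for a = P(low→high),
b = P(high→low); the expected in-feature read fraction equals the
weight-ratio prediction (feature_bp × high_mean) / (feature_bp ×
high_mean + background_bp × low_mean) over valid starts. Note the
occupancy estimator's Monte-Carlo error is inflated by the chain's
autocorrelation (correlation length 1/(a+b)), and the read-fraction
estimator by the randomness of the emission weights (~20 % above the
binomial SE); the seeded checks sit well inside their tolerances.

## True abundance and strategy evaluation

True abundance counts each simulated read, at its true coordinates,
once per subfamily whose instance it overlaps (≥ 1 bp — the same rule
as unique-read assignment), making the benchmark independent of any
counting strategy. Evaluation uses replicate-averaged CPM with a
+0.5-count offset before log2 (the offset handles zeros; the canonical
count-modelling packages use a comparable prior). Strategies are
ranked by Euclidean distance between log2CPM vectors and by
identity-line R² = 1 − Σ(y−x)²/Σ(x−x̄)² with x the truth, clamped at 0
(negative values mean "worse than predicting the mean" and are
reported as 0), overall and per repeat class.

## Consensus profiler

Coverage depth at position p counts alignments whose aligned
(non-soft-clipped) reference span covers p; soft-clipped flanking
sequence therefore never inflates coverage (the original protocol's
local alignment mode exists precisely to clip such sequence — whether
it then counted clipped bases is unstated; we exclude them). The
instance span CDFs use one best alignment per genomic instance
(highest alignment score, ties to the leftmost start): start-CDF(p) =
fraction of instances starting at or before p, end-CDF(p) = fraction
whose last aligned base is at or before p. Paired log2FC tracks divide
each library's depth by its total mapping reads and add a pseudocount
(default 1e-6 on the normalized scale, configurable and recorded in
output headers) before the ratio.

Genic/intergenic partition: an instance is genic if ≥ 99 % of its
length lies inside the union of gene bodies, intergenic if ≥ 99 % lies
outside; anything else is excluded. Per sample, a uniquely-mapped read
counts once per partition it overlaps; counts are CPM-normalized with
the supplied totals (deliberately without TMM) and compared pairwise
as log2FC.

## Normalization

TMM factors follow the published trimmed-mean-of-M-values procedure
with its standard defaults: reference sample = the one whose 75th
percentile of scaled counts is closest to the mean of those
percentiles; per sample, log-ratios M and average abundances A over
features with nonzero counts in both samples; double trim (30 % of M,
5 % of A by rank); weighted mean of the surviving M using inverse
asymptotic binomial variances; factors rescaled to geometric mean 1.
The implementation reproduces the reference R implementation to ~1e-10
on fixture matrices. Exact invariance of the factors under scaling one
sample's counts and library by a constant holds for the unweighted
variant; the precision weights perturb it at ~1e-3 (`weighted=False`
restores exactness).

Per-pair normalized log2FC uses effective (TMM-scaled) library sizes
by default (`use_effective=False` switches to raw totals — the
original analyses do not state which was used for the per-patient
fold-changes) and a pseudocount equivalent to 0.5 reads at the
geometric-mean library size, so the offset is symmetric across a pair.
Differential testing (negative-binomial GLM, FDR) is out of scope by
design: the exported TSV count table + sample sheet feed those
external tools directly.

## Synthetic fixtures

The generator plants repeat copies in uniform-composition background
sequence (configurable GC): each subfamily has a consensus; members of
a homology group derive their consensuses from a shared ancestor
mutated at a per-member rate (emulating the high mutual identity of
recent LINE-1 subfamilies, the regime where counting strategy
matters); each genomic copy mutates the consensus at a per-copy rate,
with random strand and non-overlapping placement (multinomial gaps, a
minimum gap of 100 bp). Mutations are substitutions only, keeping the
Hamming oracle exact — indel divergence, nested insertions, and
realistic repeat landscapes are explicitly out of scope. What passing
tests show is that the *accounting* is exact and the strategy ranking
holds in the homologous-subfamily regime; they do not certify behavior
under indel-rich divergence or aligner-specific heuristics.

Study-condition presets: the oracle landscape (30 kb, two ~90 %
identical LINE-like subfamilies plus one unrelated DNA-class
subfamily) and the benchmark landscape (500 kb; a 3-member LINE-like
group and a 3-member SINE-like group with varied copy numbers — the
spread makes per-class R² non-degenerate — plus independent DNA and
LTR subfamilies). The benchmark plants enrichment on the LINE-like
group's instances and simulates 3 replicates × 100 000 50 bp reads,
a size chosen to finish in about a minute on one CPU while leaving the
strategy ranking far outside Monte-Carlo noise.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; conversions happen only
at parse/serialize boundaries (RepeatMasker .out is 1-based inclusive).
Empty instance sets, all-zero emission profiles, zero library sizes,
all-zero count columns and reads shorter than the mismatch budget all
raise immediately rather than propagating NaNs. R² with zero truth
variance returns 1 for a perfect fit, else 0. Identity-line R² and CDF
curves are deterministic; every stochastic path takes an explicit seed
and derived seeds stay below 2^31.

## Known limitations

No indel handling in the internal matcher (use an external aligner for
indel-rich data); no probabilistic per-locus assignment; no
fragment-length or PCR-duplicate modelling in the simulator; the
Low_complexity class is *not* excluded by default (only simple
sequence repeats are, following the source's literal wording) but the
exclusion set is configurable.
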