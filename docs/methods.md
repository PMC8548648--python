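# Methods

## MYB repeat model and detection

The repeat model is a 52-column position-weight profile per repeat type,
built from a bundled synthetic seed alignment (10 sequences per type,
constructed for this repository around plant-MYB-like consensus sequences),
plus anchor rules: R2 requires tryptophans at columns 5/26/47 with
successive spacings of 20–21 aa; R3 requires Phe (or Trp) at column 5 and
tryptophans at columns 24/43 spaced exactly 19 aa. Detection is
anchor-driven: every chain of anchor residues with admissible spacings
proposes a 52-aa window, scored as a log-odds sum against a uniform
background; windows scoring at or above the bundled threshold survive, and
overlaps are resolved greedily best-score-first with ties to the smaller
start. The threshold (10.0 bits) was calibrated on synthetic data:
anchor-bearing windows of random 300-aa proteins score at most ≈ −17 bits
(0 of 739 candidate windows above 10 in the calibration set, i.e. well
under the 1% false-positive design target), while sampled repeats score
≥ ≈ +45. `X` is tolerated anywhere but never matches an anchor.

Classification counts adjacent repeats (inter-repeat gap ≤ `max_linker`,
default 25 aa): 1→1R, 2→R2R3, 3→3R, 4→4R; repeats violating adjacency (or
more than four) are atypical; zero repeats is a distinct "none" signal.
Conservation statistics take equal-length repeat blocks and report each
column's modal residue and frequency (gaps excluded); a column is conserved
when the modal frequency is ≥ the threshold (default 0.80, inclusive).

## Codon evolution and the planted duplicate truth

`evolve_duplicate_pair` plants a duplicate pair with a **known** divergence
truth. Single-nucleotide codon changes are proposed uniformly at random
(stop codons rejected); a proposal is accepted only if it moves the pair's
realized Nei–Gojobori divergence strictly closer to the target point
(Ks = `target_ks`, Ka = ω·`target_ks`), measured incrementally with the same
fractional-site and pathway-averaged counting as the estimator. The walk
stops within half a substitution increment of the target (tolerance
2/(3·codons) on |ΔKa|+|ΔKs|). The realized dN/dS of the emitted pair
therefore equals ω up to single-substitution granularity — by design, so
that estimator-recovery tests are sharp. A plain ω-probability acceptance
scheme was evaluated first and rejected: the NG86 convention of counting
mutations-to-stop as nonsynonymous sites, together with site-class mixing
at two-fold degenerate positions, biases recovered ω low by ~10% at ω = 1
and ~20% at ω = 2 at Ks 0.4, which defeats the purpose of planting a truth.
Targets whose implied proportion of differences is ≥ 0.70 are refused
(`SaturationError`): the Jukes–Cantor correction diverges at 0.75.

## NG86 Ka/Ks

Per codon, synonymous sites are the fraction of the nine possible
single-nucleotide changes that preserve the amino acid; changes to stop
codons count as nonsynonymous, so S + N = 3 per codon; site counts are
averaged over the two sequences. Differences per aligned codon pair are
averaged over all minimal mutational pathways with equal weights; pathways
through stop codons are excluded, and codon pairs whose every pathway hits a
stop are skipped (counted and reported). pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected; pS or pN ≥ 0.75 yields NA (saturation). The
implementation is checked against an independent exhaustive enumerator on
short inputs (agreement to 1e-12) and spot-checked against Biopython's NG86
during development.

Alignment uses Smith–Waterman (BLOSUM62, gap open −11 / extend −1 in
Biopython's convention); identity is over aligned columns, coverage treats
the shorter sequence as query (the stricter symmetric reading of a
"percent of gene length" coverage rule). The protein alignment is
back-translated onto the CDS for codon-level counting; gap columns become
codon gaps and are excluded from counting.

Dating is T = Ks/(2λ) with λ = 6.96×10⁻⁹ synonymous substitutions per site
per year, reported in million years. Selection classes use a configurable
neutral band, by default degenerate at 1.0 (ω < 1 purifying, ω = 1 neutral,
ω > 1 positive), matching the published classification of an ω of 1.027 as
positive. Tandem vs segmental uses the gap between nearest gene-span ends
(< 100 kb and same chromosome → tandem; exactly 100 kb → segmental, both
printed inequalities being strict). QTL co-localization requires full
containment of the gene span by default, with an any-overlap option.

## Synteny chaining

Anchors are homolog pairs at ordinal gene ranks (start-coordinate order per
chromosome). Within each chromosome pair, the best chain is found by
O(n²) dynamic programming, separately for forward (both ranks increasing)
and reversed (second rank decreasing) orientations, with consecutive
anchors at most `max_rank_gap` (default 25) ranks apart on either genome.
Chain score is anchors − `gap_penalty` × gap events (a gap event is a
consecutive pair skipping ≥ 1 rank on either side; default penalty 0.1) —
penalizing discontinuities rather than their length, in the spirit of
collinearity chainers. Chains are extracted greedily best-score-first;
each anchor joins at most one segment; chains under `min_anchors`
(default 5) are dropped. A refinement pass then moves anchors into a
segment where they sit rank-contiguously whenever total score does not
decrease: greedy extraction can otherwise leave a score tie in which the
flanking collinear chain absorbs one edge anchor of an inverted block.
Consecutive same-partner anchors (tandem arrays) collapse to the
best-scoring anchor before chaining. The DP is verified against exhaustive
best-chain search on small instances, and planted inversion/translocation
blocks in noise-free genome pairs are recovered exactly, with inversions
labeled reversed.

## SSR and cis-element scanning

SSRs are maximal perfect tandem runs of a period-minimal 2–6 nt motif with
≥ 6 full copies (mononucleotide runs excluded by the period-2 floor;
partial trailing copies not counted; `N` never inside a run). Runs are
anchored at their leftmost full copy; a sub-period re-report of the same
run is impossible by period minimality, while overlapping runs of different
minimal periods are all reported. The scanner is property-tested against a
quadratic brute-force oracle on random AT-rich sequences. Cis elements are
exact IUPAC consensus matches on both strands (minus-strand hits reported
at the forward coordinate of the match start); the bundled dictionary holds
PlantCARE-style one-line consensi for the elements commonly reported in
pepper MYB promoters and is editable YAML. Upstream regions are the 1,500
nt before the TSS on the coding strand, reverse-complemented for minus
strand genes and truncated (with a flag) at chromosome edges.

## Expression

TMM: the reference sample is the one whose upper quartile of scaled counts
is closest to the mean upper quartile; per sample, gene-wise M (log2 ratio
of proportions vs the reference) and A values are double-trimmed (30% on M,
5% on A, genes with a zero in either sample excluded) and combined by a
precision-weighted mean; factors are renormalized to geometric mean 1. The
weights are the inverse delta-method variance of M computed on the
proportion scale, 1/((1−p_k)/p_k + (1−p_r)/p_r): relative to weights
written with raw library sizes this changes only the balance between the
two samples' noise terms, and it makes factors exactly invariant to
rescaling any library — a property the test suite asserts at 1e-6.

FPKM = count·10⁹/(effective library × length), effective library = raw
library × TMM factor.

Differential expression is a per-gene negative-binomial likelihood-ratio
test between two groups (log link, library-size offsets; group means fitted
by a vectorized Newton solve). Dispersion is a per-gene moment estimate via
the Pearson estimating equation Σ(y−μ)²/(μ(1+φμ)) = n−2 (solved by
bisection), shrunk 50% toward the all-gene median; the LRT statistic is
referred to χ²(1), p-values are Benjamini–Hochberg adjusted, and a gene is
significant iff adj p < 0.01 and |log2FC| > log2 1.5 (symmetric in
direction; the fold change is the ratio of fitted group means). Under the
generator's null (2,000 genes, dispersion 0.1, 3 vs 3) the mean fraction of
genes at adj p < 0.01 is ≈ 2×10⁻⁴, and recall on planted 4-fold changes is
≈ 0.9.

2^−ΔΔCt averages replicate ΔCt (target − reference Ct) per condition before
differencing against the calibrator; a two-sided two-sample t-test on
replicate ΔCt values supplies p. Co-expression clustering is hierarchical
average linkage on 1 − Pearson correlation of log2(FPKM+1) profiles, cut at
k clusters or a height; zero-variance genes go to a dedicated "constant"
cluster (id 0) since Pearson is undefined for them. The cluster count is a
user parameter.

## Synthetic-data generator: what it emulates, and what it does not

The generator emulates the statistical structure each stage assumes: genes
(UTR5 + CDS + UTR3, each with a dedicated 1.5-kb upstream buffer) laid out
with 2–6 kb intergenic spacing on a small number of chromosomes; MYB
proteins synthesized from the bundled repeat profile (linkers and flanks
free of W/F so planted coordinates are unambiguous); duplicates placed
adjacent to their source (tandem) or on another chromosome (segmental);
SSR runs written with guard bases so they cannot extend or shift; a partner
genome for synteny derived by applying mutually disjoint inversions and
translocations to the gene order; and NB counts with log-normal gene means
(median ~100), ±3-fold uniform-log library depths, and a planted ±log2FC on
a chosen gene fraction between the first two stages. Default study
conditions: 3 stages (EG/MG/Br) × 3 replicates, 2,000 genes, 10% DE at
|log2FC| = 2, dispersion 0.1.

It does **not** emulate: read-level data (sequencing error, mapping
ambiguity, isoform structure), introns, gene-density or GC heterogeneity,
imperfect/compound SSRs, segmental duplications of multi-gene blocks, or
overlapping rearrangements. Passing tests therefore demonstrate
correctness of the computations under their stated models, not robustness
to upstream artifacts of real sequencing data. Genome-scale published
counts (family sizes, total segment counts, DEG counts) depend on the real
genomes and are out of scope; the published Ka/Ks table is used only to
verify the ratio and dating arithmetic against its printed values, at
tolerances limited by the table's printed precision (3 decimals on Ka/Ks,
2 on T).

Randomness: one root seed; each component (lengths, CDS, MYB synthesis,
duplication, SSR assignment, assembly, strands, counts, rearrangements)
draws from its own labeled child stream, so regenerating one component
never perturbs another, and equal configs are byte-identical.

## Numerical choices and degenerate inputs

- Jukes–Cantor corrections return NA (NaN) at or beyond p = 0.75; ω is NA
  when Ks = 0 or either rate is NA; dating propagates NA.
- The NB mean solve clips Newton steps to ±2 on the log scale and starts
  from log((Σy+0.5)/Σ effective library); dispersion is floored at 1e-8.
- Ties: overlap resolution by score then start; modal SSR motif and modal
  conservation residue lexicographically; chain extraction by score with
  deterministic anchor order.
- Degenerate inputs raise typed errors: all-zero samples (TMM/FPKM),
  groups with < 2 replicates, missing calibrator or reference Ct, unknown
  chromosomes, non-alphabet characters, infeasible genome packing, and
  unreachable divergence targets.

## Known limitations

- NG86 is the only Ka/Ks model; maximum-likelihood codon models are out of
  scope, and numeric equality with other calculators on real sequences is
  not claimed — only the published table's internal arithmetic.
- The repeat profile is a repository calibration, not a database-derived
  HMM; sensitivity on real proteomes with diverged repeats is untested.
- The χ²(1) reference for the NB-LRT at n = 3 vs 3 is approximate; the
  shrunk Pearson dispersion makes it conservative under the generator's
  conditions, which is the behavior the acceptance properties require.
- Greedy segment extraction with boundary refinement recovers planted
  blocks exactly in noise-free pairs; with noisy anchors the partition is
  deterministic but not globally optimal.
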