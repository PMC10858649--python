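# Methods

This note documents the models, parameter choices and numerical decisions
behind `dinolnc`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and I/O

All internal coordinates are 0-based, half-open, on the plus-strand genome
axis; strand is a separate field. GFF3 (1-based, inclusive) is converted at
the parsing boundary and writing is the exact inverse, so
write(parse(x)) = canonical(x). Promoters are the ≤ 1000 nt immediately
upstream (strand-aware) of a gene's first CDS base — the CDS rather than
the mRNA start, because dinoflagellate 5′ UTR annotation is unreliable and
core-promoter elements have been mapped relative to coding starts.
Promoters truncated below 20 nt at scaffold edges are dropped: 20 nt is the
minimum triplex length, so they can never contain a target site.

## Identification cascade

Stage order matters and follows the logic of removing the cheapest-to-test
contaminants first: alignment quality (identity ≥ 0.95, coverage ≥ 0.75,
boundaries inclusive), exonic overlap (≥ 1 bp with any exon, either strand
— antisense-exonic transcripts are treated as gene-derived because the
biotype scheme has no exonic-antisense class; configurable via
`ignore_strand`), length and coding potential, protein-domain hits,
redundancy collapse, expression support.

The coding-potential call is a consensus of two intrinsic, deterministic
voters, replacing external machine-learning classifiers with the same
all-must-agree logic:

- **ORF rule** — longest forward-frame ORF (ATG to stop inclusive, or to
  the end of the frame if no stop follows) must be < 100 codons AND cover
  < 50% of the transcript. Only forward frames are scanned: the transcript
  orientation is known from the alignment.
- **Fickett TESTCODE** — positional asymmetry and composition of each base
  converted to probabilities through the published lookup tables and
  summed with the published weights; scores < 0.95 vote non-coding.
  0.95 is the classical "coding" boundary, making the voter conservative
  in what it removes.

Redundancy collapse builds connected components under genomic-span overlap
(≥ 1 bp, same scaffold and strand; a linear sweep — components of interval
overlap are exactly the maximal runs of overlapping spans in sorted order)
and keeps the candidate with the largest spliced length, ties broken by
smallest id for run-to-run determinism. Span-level rather than exon-level
overlap is used because redundant assemblies of one locus usually differ in
exon boundaries. Expression support requires ≥ `min_reads` (10) in
≥ `min_samples` (10) samples; candidates missing from the count table count
as all-zero with a warning.

Printed summary tables round half away from zero (ratios at 2 decimals,
percentages at 1), matching how such tables are conventionally typeset;
G+C% is pooled over nucleotides (length-weighted), not averaged per
transcript.

## Biotype classification

The nearest gene within 5 kb either side is the partner (span overlap wins
with distance 0; among several overlapping genes, largest overlap then
smallest id; equidistant candidates prefer the same strand, then the left
gene). Divergent/convergent labels are decided by the transcript ends that
face the intergenic gap: both 5′ → divergent (head-to-head), both 3′ →
convergent (tail-to-tail). A point worth recording: for opposite-strand
neighbours these are the only possibilities — a minus-strand transcript
presents its 3′ end at its left genomic edge, so the two gap-adjacent ends
always agree — and the `mixed_ends` flag in the output is a defensive field
that cannot fire for antisense pairs. Classification uses geometry and
strand only, never identifiers.

"Expressed" for lncRNA–gene pair correlations means non-zero variance after
normalization; zero-variance members are skipped rather than producing
undefined correlations.

## k-mer profiles and clusters

Counts of overlapping k-mers (k = 4; windows containing N are skipped) are
normalized to rates per 1000 nt of sequence and z-scored per k-mer against
the input set as background; zero-variance coordinates get z = 0. An
optional log2(rate + 1) transform before z-scoring is off by default — the
rate scale keeps the row-sum identity (raw counts sum to the number of
valid windows) interpretable and the z-scores already standardize the
dynamic range. Profiles are compared by Pearson correlation; clustering is
average linkage on the distance 1 − r cut to at most t = 10 flat clusters.
Average linkage is robust to the chaining that single linkage shows on
correlation distances; the distance transform (rather than clustering the
similarity matrix directly) makes the dendrogram heights metric-like.

Cluster-versus-module association uses exact two-tailed Fisher tests per
(cluster, module) pair — two-tailed meaning the sum of hypergeometric
outcome probabilities ≤ the observed one — with Benjamini–Hochberg control
at q ≤ 0.01 and an over/under direction from the sign of the observed minus
expected overlap. The global test permutes one label vector (which fixes
both margins exactly), uses the Pearson chi-square statistic, and reports
the add-one Monte-Carlo p = (1 + #{sim ≥ obs})/(1 + R) with R = 10 000.

## Differential expression

Size factors are DESeq-style medians of ratios to the geometric-mean
reference, computed over features with no zero count; normalized values
are log2(count/sf + 1). Outlier samples are flagged by average-linkage
clustering of pairwise Euclidean distances cut into k = number of condition
groups; a sample whose flat cluster contains no replicate of its own
condition is excluded.

The Wald test models counts as NB with variance μ + αμ². Per-feature α is
estimated by the method of moments from the pooled within-group variance of
normalized counts, clipped to [1e-8, 10], and shrunk 50/50 toward a fitted
α(μ) = a₀ + a₁/μ trend (non-negative least squares over gene-wise
estimates). The log2 fold-change is the ratio of group means of normalized
counts; a 0.5 pseudocount is applied only when a group mean is zero, which
makes the estimate exactly invariant to rescaling all normalized counts
(a constant pseudocount would leak the scale into the estimate). Standard
errors come from the delta method on the NB variance of group means;
p-values are two-sided normal, BH-adjusted; a feature is called up/down iff
padj ≤ 0.01 AND |log2fc| ≥ 2. Features with all-zero counts in both groups
get p = 1 and log2fc = 0. This stand-in preserves the decision rule of the
reference shrinkage-GLM machinery without reproducing its exact estimates;
an adapter can swap in an external engine where exact concordance with a
specific tool is required.

## Co-expression network

Correlation is biweight midcorrelation: Tukey biweights around the median
with u = (x − median)/(9·MAD), the side quantiles at 0.1 rescaled to
|u| = 1 so at most 10% of samples per side can be fully discarded;
features with MAD = 0 fall back to Pearson standardization individually.
The signed adjacency ((1 + cor)/2)^T never maps anti-correlated features to
high adjacency. T is the smallest power in 1..30 whose scale-free fit
index — R² of log10 p(k) against log10 k over 10 equal-width connectivity
bins, counted only under a negative slope — exceeds 0.8, else the
recommended small-sample default of 18.

TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij) with unit
diagonal, symmetrized and clipped to [0, 1] against floating-point drift.
Modules are complete-linkage clusters of 1 − TOM cut at a static height
(the 0.99 quantile of the merge heights); branches below 30 features stay
unassigned (label 0). This is a deliberate simplification of adaptive
branch-cutting: it recovers well-separated planted modules exactly, but it
will not reproduce the fine branch decomposition an adaptive cutter finds
in real, continuous co-expression structure — module counts on real data
will be smaller and coarser. Eigengenes are first right singular vectors of
the per-feature-standardized module submatrix, sign-aligned with mean
module expression; modules whose eigengenes correlate ≥ 0.9 (average
linkage on 1 − cor) are merged iteratively until stable. Trait correlations
are Pearson r of eigengenes against numerically coded factors (temperature
in °C; binary factors as 0/1).

## Triplex search

A hit is an ungapped pairing between a lncRNA segment (TFO, DNA alphabet,
U ≡ T) and a promoter segment (TTS) on either strand of the duplex, under
one of three Hoogsteen motif codes (pyrimidine {T→A, C→G} parallel; purine
{G→G, A→A} antiparallel; mixed {G→G, T→A} both orientations), satisfying:
length ≥ 20, mismatch rate ≤ 5%, no more than 1 consecutive mismatch, TTS
guanine fraction ≥ 0.1, N never matching, and both ends on a paired
position. Only maximal hits — not contained in a longer valid pairing on
the same alignment diagonal — are reported; duplicate coordinates reachable
through several motifs or orientations collapse to the fewest-mismatch
reading (ties: pyrimidine < purine < mixed, parallel < antiparallel). Note
the guanine-rate rule (a stabilizing constraint standard in triplex
software) excludes the textbook poly-T·poly-A:T triplex; set
`min_guanine_rate = 0` to observe it.

Because every motif maps a TFO base to exactly one TTS base, a Hoogsteen
match is literal string equality after translating the TFO, and any valid
window must contain a perfect run of at least
ceil((L − ⌊eL⌋)/(⌊eL⌋ + 1)) ≥ 10 paired positions. The scanner therefore
indexes all promoter-strand seed k-mers once and examines only diagonals
carrying an exact seed match; an exhaustive per-start enumeration oracle in
the test suite verifies exact equality of hit sets. Tandem repeats with
unit period ≤ 3 and total length ≥ 7 are masked to N beforehand; TFO
sequences whose exact sequence recurs at more than 5 distinct lncRNA loci
are discarded (duplicate-feature cutoff), both configurable.

Interaction categories partition triplex-forming lncRNAs by the exclusivity
of their target sets; retained expression-correlated interactions require
the target gene to be differentially expressed and Spearman |ρ| ≥ 0.8 with
two-sided p ≤ 0.05 (average ranks for ties, t approximation). Multi-lncRNA
target genes (≥ 2 correlated partners) are clustered by average-linkage
Euclidean distance between their gene × lncRNA ρ fingerprints (absent pairs
0) into 3 groups, ordered by ascending mean interaction count.

## Synthetic study design

The generator emulates the features of dinoflagellate genome data that the
pipeline's decisions depend on, with defaults chosen to be realistic at
desk scale: 3 scaffolds, 80 genes in same-strand runs (strand flip
probability 0.2 ≈ blocks of 5), mean 4 introns/gene, exons 150–400 nt,
introns 350–800 nt, gene G+C 55% vs lncRNA 49% vs intergenic 45% (the
coral-symbiont contrast), 34 planted lncRNAs covering every biotype with
engineered gap geometry (hosts < 1.6 kb away, competing genes > 5.6 kb,
distant loci > 5.6 kb from everything), and five decoy transcripts per
cascade stage. Counts follow NB with variance μ + 0.1μ² and log-normal
baselines (ln-mean 4.5, ln-sd 1) over a 2-temperature × 2-phase × 3-replicate
design; planted effects are a ±3 log2 temperature fold-change on 10 genes,
±2 log2 growth-phase effects on 30 features (alternating signs so library
sizes stay balanced), two 35-feature modules sharing latent sample factors
that track temperature in opposite directions (strength 0.9 — mirroring
heat-up- and heat-down-regulated programmes), and further modules on
condition-independent latents. Planted triplex pairs write a 30-nt
unmaskable purine tract into a free promoter (pyrimidine-dinucleotide
flanks block extension, so zero-mismatch plants are recovered at exact
coordinates) and the Hoogsteen-complementary TFO into a single-exon lncRNA;
planted mismatches are evenly spaced, which guarantees that a 10% plant
exceeds the 5% budget in every window of minimal length. Target genes and
their lncRNAs share one latent carrying the full heat-stress response with
opposite signs (within-group sd 0.7, baseline boost e^2.5), so the pairs
are strongly anti-correlated and the genes robustly differentially
expressed.

Several truths are enforced, not merely sampled: planted lncRNA transcripts
are mutated until the intrinsic scorer calls them non-coding (stop-codon
insertion, with resampling if frames oscillate), support counts are clamped
to meet or miss the 10 × 10 rule exactly, and tracts/TFOs are redrawn until
they survive repeat masking. Everything is a deterministic function of
(config, seed).

What passing these tests shows — and does not. The planted structures are
well separated: real transcript data have fuzzier alignment-quality
margins, coding potential on a continuum (where intrinsic voters disagree
with ML classifiers), overlapping and partially supported isoforms, and
co-expression structure without clean block boundaries. Recovery of 100% of
plants therefore validates the implementation of each rule, not the
biological error rates of the rules themselves.

## Degenerate inputs and tie-breaks (summary)

Empty annotation → empty gene set, all-distant biotypes. Zero-variance
profiles → correlation 0 with warning. Fewer sequences than clusters →
singletons with warning. All-zero count matrix → error. Modules of
constant features → dropped with warning. Fewer genes than target groups →
fewer groups with warning. All order-dependent choices (redundancy
representative, equidistant genes, duplicate hits, module labels) break
ties lexicographically or by size so repeated runs are identical.
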