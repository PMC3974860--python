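# Methods

## Scope and model

`pseudoshadow` characterizes transcribed pseudogenes from short-read data.
The central difficulty is attribution: a pseudogene shares most of its
sequence with its parent gene, so a read aligned inside a pseudogene locus
may well have been transcribed from the parent. Processed pseudogenes make
this worse — they lack introns, so a parent read spanning an exon–exon
junction has a *better* contiguous genomic alignment at the pseudogene than
at the gene itself.

The read filter resolves this with one rule. Every read whose single
genomic alignment overlaps a pseudogene exon block by ≥ 1 bp is a
candidate. Each candidate is compared against the coding transcriptome: it
is kept as a pseudogene read iff it has **strictly fewer mismatches to the
pseudogene locus than to any coding cDNA** (no cDNA hit within the search
ceiling counts as infinitely many mismatches). Alignments of removed reads
are deleted; all other records pass through untouched. Interpretive choices
the rule itself does not settle:

* **Ties are removed.** A read with equal mismatch counts at pseudogene and
  cDNA is ambiguous; the strict inequality resolves it conservatively
  against the pseudogene. This also removes genuine pseudogene reads whose
  span contains no informative site — a known source of FPKM
  underestimation at very high identities, accepted deliberately.
* **cDNA search ceiling** defaults to 3 mismatches for ≤ 75-bp reads
  (short-read aligner convention); a read whose best cDNA hit exceeds the
  ceiling has "no competitor".
* **One location per read.** The filter adjudicates pre-resolved
  placements; a validator rejects multi-located input instead of guessing.
* Paired ends are adjudicated per read; a fragment counts toward a
  pseudogene only if all of its ends are kept.

## Quantification

FPKM uses deterministic union-exon counting rather than isoform-level EM: a
fragment is assigned to the feature whose exon union it overlaps most (ties
to the lexicographically smallest id), and

FPKM = count / (exon_kb × total_mapped / 10⁶),

with `total_mapped` the number of mapped fragments **after** filtering.
This is an explicit simplification — the package's tests target the closed
form, not isoform-deconvolution parity. A feature is called transcribed
when its maximum FPKM over tissues is strictly above the threshold
(default 1; a "highly transcribed" threshold of 10 is also surfaced).

## Identity-window diagnostic

To verify that filtering removed parent contamination, each
pseudogene–parent alignment is scanned in fixed 200-bp windows: per window,
identity = matching columns / aligned columns × 100 (columns gapped on
either side are not aligned columns; windows with none are skipped) and
read count = kept reads whose 5′ end falls in the window's pseudogene
coordinates. Pearson r over windows (p from the t transform with n−2 df)
should be significantly positive before filtering and flat after. Windows
can be pooled over many pseudogenes, which is how the diagnostic is used
genome-wide; with fewer than 3 usable windows or zero variance the report
is flagged undefined rather than silently zero.

## Tissue specificity

The specificity of a profile p over T tissues is
`max_t [1 − sqrt(JS(p, e_t))]` with Jensen–Shannon divergence in base-2
logs, 0·log0 ≡ 0, and e_t the one-hot profile of tissue t. The score is
scale invariant, 1 exactly for one-hot profiles, and ≈ 0.0898 for a uniform
16-tissue profile. All-zero profiles are excluded with a flag — they have
no defined specificity. Expression-matched control genes are drawn without
replacement from the same 0.5-wide log2(max FPKM) bin, falling back to the
nearest non-empty bin with a warning.

## Correlation structure

Pseudogene–parent co-expression is Spearman's ρ over per-tissue FPKM
(average ranks for ties; parents all-zero across tissues excluded). The
p-value is an exact permutation tail for ≤ 8 tissues and the t
approximation otherwise. The published workflow's cohort filter — keep
pairs whose parent has a JS score > 0.1 — is an on-by-default pipeline
option. Pseudogenes are split into t1/t2 by distance to the nearest coding
gene (minimum span gap, 0 if overlapping; exactly 20 kb is t1, the ≤
convention). The tissue-split statistic sorts tissues by pseudogene level
(descending, ties broken by fixed tissue-name order), splits them into
equal halves and reports the parent's mean and unbiased (n−1) variance per
half; "unbiased" is a documented choice where either estimator would be
defensible.

Strand inference calls sense/antisense when one strand's signal is ≥ 10×
the other (a zero lesser strand counts as dominated), `both` otherwise, and
`no_call` when both values are at or below `min_expr` (default 0; 0.05
exposed for a stricter error rate). miRNA-correlation binning uses
half-open [lo, hi) bins of width 0.1 over [−1, 1] with the last bin closed
(the bin width is a documented choice). Knockdown comparisons drop genes
with fold change ≤ 1.3 and compare classes with the two-sided Wilcoxon
rank-sum test.

## Small RNA

Densities are reads/kb with a read counted where its 5′ end lies; exonic
regions are the block union, flanks are ±1 kb clipped at chromosome edges
with the realized length as denominator. Candidates (exonic density ≥
5/kb) are group I when the flanks hold **exactly zero reads** ("= 0" read
literally, not density < ε), group II when flank density > 5/kb, otherwise
unassigned. Candidates carry an upper-tail Poisson p-value; the null rate
defaults to the genome-wide reads/kb of the same library (the published
test does not state its null rate, so it is an exposed parameter). Size
comparisons report low-medians (lower of the two middle values for even n)
and a two-sample KS test; Dicer-style condition comparisons report the
fraction of pseudogenes (≥ 1 control read) with strictly fewer treated
reads, ties counting as not reduced.

## Chromatin

Tags are 5′-end single-base anchors with no fragment-shift extension.
Window counts normalize to per-500-bp densities. Anchored meta-profiles
accumulate signed tag offsets (minus-strand anchors mirrored) into
100- or 500-bp bins over ±flank and divide by the anchor count; both TSS
and feature-center anchor modes are supported. Promoters are the
strand-aware [TSS − 2 kb, TSS) window, and TF counts deduplicate peaks by
factor label. Overlap enrichment uses an upper-tail binomial with the
default background probability equal to the genome fraction covered by the
targets extended by half the mean feature span (plus any flank).

## Evolutionary constraint

Nucleotide diversity is the frequency-weighted average pairwise difference
π = Σᵢ Σⱼ xᵢ xⱼ πᵢⱼ over ordered pairs, πᵢⱼ being the per-site Hamming
distance; sites missing in either member of a pair are excluded from that
pair's numerator and denominator. No n/(n−1) correction is applied by
default (the weighted form carries the frequencies); an optional flag adds
it. Loci with π = 0 are reported, with an exclusion option for two-
population comparisons. Variant tables are expanded to two haplotypes per
individual, heterozygous alt alleles going to the second haplotype —
phasing information is not modeled. Conservation over a feature is the
mean track score across the non-missing bases of its block union, counted
once regardless of block redundancy.

## Synthetic data: what it emulates, and what it does not

The generators provide every input with planted truth:

* **Toy genome** — genes with uniform exon/intron sizes; processed copies
  of the parent transcript (one merged block), duplicated copies of the
  parent locus, unitary pseudogenes with no parent. Divergence is planted
  as substitutions only (indel rate fixed at 0), so mismatch counts are
  exact under positional alignment and no realignment step is needed.
  Realized identity is within rounding of the target.
* **Reads** — single-end, uniform starts, optional uniform substitution
  errors. The emulated genomic aligner reports one best location: gene
  junction reads go to the intron-less processed copy (there is no
  contiguous alignment at the gene), all other reads are adjudicated
  between the true locus and its homolog by Hamming distance, and ties go
  to the pseudogene — the worst case for contamination, and the case the
  filter must fix. The cDNA aligner searches every coding transcript on
  both strands (vectorized sliding-window comparison) and reports hits
  within the mismatch ceiling.
* **Contamination fixture** — six processed pseudogenes at identities
  0.85–0.95 (the range that holds most annotated pseudogenes), parents
  sequenced ~13× deeper. Tie leakage grows steeply with identity
  (≈ e^(−informative sites per read)), which produces the positive
  pre-filter identity/read-count correlation and leaves the post-filter
  correlation flat.
* **Small RNA** — deterministic read counts (⌈density × kb⌉) at uniform
  positions, lengths uniform within ±2 bp of the group median (so sample
  medians recover the planted ones), zero flank reads for group I.
* **ChIP tags** — piecewise-homogeneous Poisson process: fold × background
  inside anchor windows, background elsewhere; overlapping windows are
  clipped so the earlier window owns the shared stretch.
* **Haplotypes** — singleton segregating sites, one carrier each,
  S = round(target π · L · n² / 2(n−1)), so realized π equals the target up
  to rounding; the recorded truth is recomputed by exhaustive enumeration.
* **Expression profiles** — Gaussian copula with Pearson parameter
  2·sin(π·ρ_s/6) so the expected Spearman correlation equals the planted
  value; the exp transform to the FPKM scale is monotone and preserves
  ranks. Parents are scaled ~20× above pseudogenes, matching the observed
  abundance gap. Tissue-specificity targets are planted as
  one-hot/uniform mixtures inverted by bisection.

Not emulated: realistic error profiles and quality strings, GC and
positional bias, paired-end fragment length distributions, indel
divergence, isoform structure, linkage between planted signals. Passing
tests therefore demonstrate algorithmic correctness and statistical
behaviour under controlled conditions, not performance on real libraries —
in particular, real data would exercise the indel and multi-isoform cases
the filter deliberately does not model.

## Numerical choices and problem sizes

Poisson and binomial tails use survival functions (stable log-space
evaluation); Pearson/Spearman p-values come from the standard t transform;
all RNG is `numpy.random.Generator` seeded from a single
`SeedSequence(seed)` with per-operation child streams, so identical
configuration and seed reproduce byte-identical outputs. Test and
acceptance problem sizes — 10–120 kb toy chromosomes, 2,000–5,000 reads,
1,000 expression pairs, 100 ChIP loci — were chosen so each property is
measured with comfortable statistical margin while the whole suite runs in
seconds on one core.

## Known limitations

* The filter consumes alignments; it cannot rescue reads the upstream
  aligner never reported, and pseudogenes identical to their parents
  receive no reads at all (they are reported as non-transcribed).
* Union-exon FPKM understates genes whose dominant isoform uses a subset
  of exons.
* The positional pseudogene–parent "alignment" used by the synthetic
  fixtures is exact only because divergence is substitution-only; real
  inputs should supply alignments from a proper pairwise aligner.
* The binomial overlap background assumes independently placed features;
  clustered annotations inflate significance.
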