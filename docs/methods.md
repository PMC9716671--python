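# Methods

`strataphy` re-implements, at desk scale, the population-genomic analysis
chain used to resolve sub-species structure of a stratified-lake
cyanobacterium from metagenome read recruitment: two phylotypes of one
species (≈99.6% identical genomes) distinguished by two diagnostic SNPs in
their 16S rRNA genes, deconvolved per sample from marker-allele
frequencies; 16S copy number estimated from stringent read-depth ratios;
niche-specific (ecotype) genes detected as variable-coverage genes across
depth zones; prophage, divergence and defence-gene screens; and rank
correlations of phylotype abundance with the lake's physicochemical
gradients. Every stage is exercised against a synthetic community
generator with planted truth.

## The synthetic community generator

`simulate.simulate_pair` builds a shared gene backbone (default 100 kb,
60% GC, ~40 genes of 0.6–1.2 kb) and derives two genomes from it:

* **Backbone SNPs.** Genome B differs from genome A at Bernoulli(`snp_rate`,
  default 0.004 per eligible base — matching a ~99.6% nucleotide identity)
  positions outside the 16S loci; every planted site is logged in the
  truth table in both coordinate systems.
* **16S rRNA copies.** Each genome carries `rrna_copies` (1–3) copies of a
  1489 bp 16S gene. Genome A carries A/G and genome B carries T/T at the
  1-based within-gene marker offsets (default 217 and 231) in *every*
  copy. Copies within a genome differ at `rrna_copy_divergence` bases
  (default 1), planted beyond position 700 so the marker neighbourhood
  stays identical between copies; the true within-genome copy divergence
  is not known more precisely than "very similar", so it is a parameter,
  not a constant.
* **Accessory genes** are insertions private to one genome, with a
  per-zone population carriage fraction. Carriage is realised at read
  time by thinning reads whose midpoint falls in the gene, which
  reproduces the target coverage in the gene interior (edges are
  intermediate over one read length — the per-gene mean is dominated by
  the interior for ≥900 bp genes at 150 bp reads).
* **A prophage cassette** (optional) is a gene run emitted at a per-sample
  copy multiplier, emulating integrated virus progeny outnumbering host
  genomes.

Reads are single-end, fixed-length (default 150 bp), drawn from either
genome with probability `fraction_b`, uniform start positions modulated by
the carriage/prophage weights, 50% reverse-complemented, with independent
substitution errors (default 0.002/base; quality models, paired ends and
indel sequencing errors are deliberately out of scope — observed indels
are biological). Read names encode sample, source genome, start and
strand, so every downstream statistic can be checked against truth
without trusting the mapper. All randomness flows from one
`numpy.random.Generator`; outputs are byte-identical for a fixed seed.

What the generator does **not** emulate: real error profiles and quality
strata, GC-coverage bias, strain microdiversity beyond two phylotypes,
chimeras, and a full background community (only an optional random-read
background). Passing tests therefore demonstrate the correctness of the
estimators under the stated model, not robustness to every artefact of
real sequencing.

## Fragment recruitment

`recruit.map_reads` is a k-mer-seeded mapper: 15-mer seeds at three read
offsets against a sorted reference k-mer index, ungapped Hamming scoring
of all candidate diagonals, then banded gapped rescue (edlib, edit-distance
bounded by the identity floor) for reads whose best ungapped placement
fails `min_identity` (default 85%). Up to two substitution errors can
never break all three seeds, so ungapped sensitivity is exact in that
regime; an exhaustive-offset oracle pins the mapper's behaviour in tests.
Ties are resolved to the smallest reference coordinate ("first best
site"), then to the forward strand — multi-copy loci therefore stack
their coverage on the first copy, and such genes can exceed 100% relative
coverage (a display cap, e.g. 120%, is available but off by default).

`pileup` accumulates per-base depth and A/C/G/T/deletion counts; depth
equals the sum of allele counts, and total depth equals total aligned
bases (conservation is asserted in tests). Coordinates are 0-based
half-open internally and 1-based in reports and VCF.

Coverage arithmetic follows the study's definitions exactly:
genome abundance is the **median** per-base depth over the whole
reference (zeros from unmapped regions included; even-length ties take
the mean of the central values); *gene coverage* is the mean per-base
depth over the gene; *relative coverage* is gene coverage over genome
median × 100, read as the fraction of the population carrying the gene;
zone means average relative coverage over all samples of a depth zone.

## Stringent 16S recruitment and copy number

The copy-number statistic divides the median read depth at the marker
sites — from 100%-identity recruitment onto one 16S gene sequence — by
the genome median depth. Identical copies collapse onto the single gene
coordinate system, so a two-copy genome shows a ratio near 2 and a
single-copy genome near 1. "100% identity" is implemented as *local*
error-free segments (minimum 30 bp, clipped at mismatches): a read with
one sequencing error still covers the markers through its clean fragment.
Full-read exact matching would discard (1−(1−e)^150) ≈ 26% of reads at
the default error rate and bias the ratio low by exactly that factor.
In a mixed sample the stringent marker-site depth counts only reads
carrying that phylotype's own marker alleles (the other phylotype's
reads are clipped at the mismatches), so the correct denominator is the
*phylotype's* depth — contribution × genome median — rather than the
total genome median; for pure samples the two coincide.
`estimated_copies` rounds the ratio (floor 1 for positive ratios) and
flags clearly fractional ratios rather than resolving them.

## Phylotype deconvolution

Marker-site frequencies are reported at any value (no frequency floor —
the minority phylotype is a sub-population signal), flagged unusable
below 20× depth. The B-phylotype contribution is the **minimum** of the
two marker frequencies × 100, a proxy for reads carrying both diagnostic
alleles at once; `both_marker_read_fraction` computes that per-read
quantity directly as a cross-check when the read length spans both sites.
When the two frequencies disagree strongly the residual (extra
phylotypes vs noise) is reported, never resolved. Phylotype read depths
are contribution × genome median, so the two depths always sum to the
median. The estimator's min-of-two-noisy-frequencies construction has a
small downward bias (≪1 point at ≥300× marker depth); recovery error
stays within 3 percentage points MAE across 5–50% mixtures in the test
conditions.

## Variant calling

SNPs are called from allele counts: depth ≥ 20 and the most frequent
non-reference base at ≥ 90% of **all** covering reads (deletion-bearing
reads stay in the denominator; only the top alternate is reported — at a
0.9 floor co-occurring alternates are impossible). No depth ceiling is
applied. Indels come from the gapped-rescue alignments, left-aligned and
anchored VCF-style at the base before the event; equal-cost split
representations of one contiguous indel are re-merged across gaps of ≤3
matched bases before support counting. A variant is *stable* when, at
some depth stratum, it appears in every time period sampled there (≥2
periods required); everything else observed is dynamic. Output
round-trips through a minimal fixed-column VCF with depth, frequency and
type in INFO.

## Differential coverage (ecotype detection)

Reads are assigned to genes by their alignment midpoint (one increment
per read; overlap ties go to the smaller start). Size factors are
median-of-ratios over genes with no zero count, with a warned
total-count fallback. The per-gene test is a negative-binomial Wald test
on normalised counts: pooled within-group variance gives a
method-of-moments dispersion (floor 1e-8, no shrinkage across genes —
defensible at these small sample counts but less powerful than shrinkage
estimators), a 0.5 pseudocount stabilises zero groups, and the statistic
is referred to a t distribution with n−2 degrees of freedom as a
small-sample correction. Measured type-I error on all-null simulations
is ≈0.045–0.05. Positive log2 fold change means higher coverage in the
numerator group; swapping groups negates every fold change and leaves P
unchanged. The significance flag is the volcano rule — |log2FC| > 1 and
raw P ≤ 0.05 — with BH-adjusted P reported alongside; the flag is a pure
function of the emitted columns.

## Screens

* **Match classification** applies the ladder no-match → low-identity
  (<80%) → low alignment fraction (<50% of the *query* aligned — the
  denominator choice is documented since it is otherwise ambiguous) →
  short (<1 kb aligned) → good.
* **GC-vs-depth** keeps contigs ≥10 kb with 30–80% GC, flags the 45–80%
  GC neighbourhood for alignment follow-up, and labels
  divergent-candidates (<95% identity, AF >50%) vs target-like.
* **Prophage** regions need >95%-identity matches to **at least two
  distinct** viral sequences (alignment evidence) and/or gene relative
  coverage ≥ `hc_multiplier`×100% (default 5× — the observed prophage
  coverages run ~10× the host genome, and 5 separates cleanly on
  synthetic data); overlapping regions merge and report their evidence.
* **Defence genes** are screened by local protein alignment (BLOSUM62,
  gap open −11 / extend −1) with pure post-filters: e-value < 1e-5
  (Karlin–Altschul with ungapped constants λ=0.318, K=0.13 over the
  searched database size — the permutation control, not the constants,
  is the accuracy anchor), identity > 30%, query coverage > 50%.
  Loosening any filter can only grow the hit set.

The nucleotide aligner behind the screens is a seeded single-diagonal
local aligner (match +1 / mismatch −1, X-drop 20, minimum score 25)
adequate for substitution-divergent desk-scale sequences; an exhaustive
affine-gap DP oracle checks it on small fixtures. It is not a general
rearrangement-aware aligner.

## Environment correlation

Spearman's rho is computed literally as rank-then-Pearson with mean-tie
ranks; significance is the ANOVA F-test of the simple regression of
rank(y) on rank(x) (equivalently the slope t-test), computed as
F = ρ²(n−2)/(1−ρ²) on (1, n−2) df — the regression is taken on ranks,
a documented choice. Zero-variance rank vectors are flagged undefined.
Only rows with complete environmental data enter (≥4 required).
Dissolved-oxygen harmonisation across sonde instruments is accepted as
pre-normalised input, not re-implemented.

## Problem sizes

Validation runs use 50–100 kb genomes with 30–40 genes as stand-ins for
the 2.6 Mb source genomes, 150 bp reads at 60–300× depth, 10–20 seeds
per stochastic check. These sizes are the package's chosen desk-scale
study conditions: they keep every distributional feature the estimators
rely on (binomial marker sampling, NB count dispersion, coverage ratios)
while letting the whole suite re-run from scratch in minutes.
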