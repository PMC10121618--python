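# Methods

## Problem setting

Fusing an RNA-binding protein (RBP) to the catalytic domain of ADAR deposits
A-to-I edits — read out as A→G mismatches in RNA-seq — on transcripts the RBP
binds (the HyperTRIBE strategy). Comparing editing between cells expressing
the fusion ("S_ADAR") and an empty-vector control ("EV") therefore identifies
the RBP's direct mRNA targets. `tribekit` implements the downstream analysis
of such an experiment, starting from per-site reference/alternate read
counts, together with the sequence, multi-omics and cell-biology analyses
that typically accompany it: binding-motif discovery around edit sites,
intersection of target lists with knockout transcriptome/proteome profiling,
and scoring of symmetric vs asymmetric stem-cell divisions from
paired-daughter immunofluorescence.

## Edit calling

**Frequencies.** The editing frequency of a sample at a site is
f = alt/(ref+alt). The per-condition mean is the *unweighted* mean over
samples with nonzero depth; whether the original analysis weighted by depth
is not something the printed description resolves, and the unweighted choice
makes each biological replicate count equally. Sites with zero depth across
an entire condition are excluded from testing.

**Test.** The default statistic (`fisher_pooled`) pools replicate counts per
condition and applies a two-sided Fisher exact test to the 2×2
(alt, ref) × condition table. The test is computed by exact integer
enumeration of the hypergeometric support: the two-sided p-value is the
total probability of all tables no more probable than the observed one, with
ties decided by exact integer comparison — no floating-point tie tolerance
is needed, and the implementation agrees with an independent
`Fraction`-probability enumeration to < 1e-12 for every table with margins
≤ 30 (checked exhaustively). A replicate-aware alternative
(`betabinom_lrt`) fits beta-binomial models with a shared dispersion and a
shared vs per-condition mean and refers twice the log-likelihood ratio to a
χ²(1); it is offered because published ADAR-fusion pipelines use
replicate-aware models, but both tests here are this package's own
implementations, and the downstream thresholds are identical.

**Thresholds.** Benjamini–Hochberg FDR is applied once across all tested
sites of a dataset (one cell type = one dataset). A site is called when
q < 0.05 (strict) and the differential frequency Δf = f_S-ADAR − f_EV
exceeds 0.1 (strict). A site must carry ≥ 10 summed reads in *each*
condition to be tested; the source analysis states no depth rule, but
without one, frequency estimates at depth 1–2 are degenerate. Output is
sorted by q, then decreasing Δf, with site-id as a reproducible tie-break.

**Annotation.** Genic location is assigned by interval overlap against
BED-like transcript models (0-based, half-open). Multi-isoform conflicts
resolve by the fixed priority 3'UTR > CDS > 5'UTR > other, reflecting that
3'UTR assignments are the biologically operative category for this RBP.
Strand is metadata used only for sequence extraction; frequencies always
come from the reported (ref, alt) counts.

## Motif analysis

Foreground sequences are sense-strand RNA windows of ±250 nt around each
called site (clipped at transcript ends, reverse-complemented for
minus-strand genes). Background windows are drawn around random positions of
non-target transcripts, region-matched to the foreground; the background
construction is this package's design — de novo motif tools leave it
implicit. Every k-mer (k 4–7) present in the foreground is scored by
*per-sequence presence* (avoiding length bias) with a one-sided binomial
tail against the background presence rate (floored at half a count so unseen
k-mers don't yield zero-probability nulls), BH-corrected across k-mers, and
ranked by q then enrichment. No PWM refinement is attempted: the motifs of
interest are short exact words (e.g. ACUUAG, UAGG, G/AGUAAG), and exact or
IUPAC-degenerate matching (plus a leading "X/Y" alternation) covers them.

Nearest-motif distances are signed (motif start − site position), nearest by
absolute value with exact ties resolved to the upstream (negative) side;
sites with no occurrence inside the window are excluded and counted. The
density is a Gaussian KDE with Silverman bandwidth on a 501-point grid over
±window.

## Multi-omics integration

Raw label-free protein intensities are normalised by scaling each sample so
all column totals equal the mean input total (a fixed point when totals are
already equal; homogeneous of degree 1). Per-gene log2 fold changes use
means of normalised intensities (means rather than medians — the printed
description does not say which; means keep the estimator linear in the
normalisation) with a pseudo-count of half the smallest nonzero intensity in
the matrix guarding zeros. Significance is a one-sided Wilcoxon rank-sum
test oriented by the observed fold-change sign (the one-sided orientation is
otherwise unstated), exact for small groups, BH-corrected across genes.

Differential-expression filters use *inclusive* fold-change boundaries
(FC ≥ 2 / FC ≤ −2, i.e. |log2FC| ≥ 1) and *strict* FDR boundaries
(FDR < 0.05 for mRNA, < 0.1 for protein), mirroring the printed operators.
Venn regions over 2–3 gene sets are computed by exact membership patterns
and verified to partition each input set. Gene identifiers are matched as
exact strings; no alias resolution is attempted.

## Division scoring

All classifiers consume per-object intensity sums (image segmentation is
upstream and out of scope):

* **NUMB pairs** — asymmetric when the between-daughter ratio is ≥ 2
  (inclusive); symmetric pairs split into commitment (high mean intensity)
  vs renewal (low) against a high/low threshold.
* **LAMP1/TMI pairs** — asymmetric when |log2(i1/i2)| ≥ 0.6 (inclusive);
  symmetric pairs split into high/low the same way.
* **Tubulin polarity** — polar when the two cell halves differ by
  |log2(h1/h2)| > 0.6 (*strict*, unlike the pair rules).

Threshold comparisons treat values within one part in 10¹² of the boundary
as exactly at the boundary, so the inclusive/strict semantics survive float
round-off (e.g. a ratio of 2^0.6 computed in floats). The high/low threshold
is set per experimental replicate; the default is the replicate's median
pair-mean intensity, overridable with an explicit number — the original
scoring set these thresholds per replicate without publishing values, so the
median is this package's documented choice. The "±" in the printed
"Log2FC ≥ ±0.6" rule is read as an absolute value of the signed log2 ratio.

Co-segregation of two markers classified on the same pairs is summarised as
a 3×3 contingency table, the high-side concordance among doubly-asymmetric
pairs, and a Fisher exact p for the asymmetric/asymmetric association on
the 2×2 collapse. Genotype comparisons aggregate per-replicate category
fractions (mean ± s.e.m.) and use two-tailed two-sample t-tests on
replicate-level fractions, matching a design of a few mice per genotype.

## Synthetic data

The generators define the study conditions the tests run under:

* **Editing counts** — beta-binomial alternate counts parameterised by mean
  p and intra-class correlation ρ (ρ = 0 degenerates to binomial; default
  ρ = 0.02), with p = 0.005 background everywhere and p = baseline + Δ at
  true sites in S-ADAR samples (default Δ = 0.3; 3 vs 3 replicates). Depth
  is negative-binomial (mean 100, size 10, floor 1 read). The background
  editing level of the control condition is not a published number; 0.005 is
  a realistic low background, exposed in the config. Transcripts are
  single-isoform, plus-strand, 200 nt 5'UTR + 900 nt CDS + 600 nt 3'UTR on
  one contig per gene; candidate sites number ~Poisson(1.5) per gene
  (matching the observed one-to-two edit sites per transcript) and fall
  mostly in the 3'UTR (region weights 0.05/0.30/0.65). Sequences are
  uniform-random RNA with every candidate site forced to A and the motif
  (default ACUUAG) planted within a Normal(0, 50 nt) offset of each true
  site, clamped to ±(250 − k) and never overwriting a candidate site's A —
  so the "every true site has a motif within 250 nt" guarantee is
  constructive. Sequences are RNA-alphabet in memory and written as DNA
  FASTA (T on disk, U in memory).
* **Expression tables** — planted down-regulated genes get log2FC ≤ −1 and
  FDR below the cutoff; everything else is kept clear of both filters.
  The RBP-target down-subsets are nested so planted Venn-region sizes are
  exact; totals can be topped up with non-target genes. The companion
  intensity matrix (2 groups × 3 samples, log-normal with 5% CV) is
  consistent with the planted protein fold changes.
* **Daughter pairs / polarity cells** — mixture draws with asymmetric
  ratios in [4, 8] (well past the 2-fold rule), symmetric ratios below 1.5,
  low/high intensity scales 100/400, multiplicative log-normal noise
  (default CV 0.1); polar cells draw |log2 half-ratio| strictly above 0.6,
  non-polar below 0.5.

One master seed drives named per-stage child streams (an FNV-hash spawn key
per stream), so identical configurations reproduce byte-identical files.

**What the generators do not emulate:** alignment artefacts, SNP
contamination and non-A-to-I mismatch classes; positional coverage bias
along transcripts; correlated editing between neighbouring sites; realistic
codon/UTR sequence composition (backgrounds are uniform random, which makes
motif recovery easier than in real UTRs); shared-peptide ambiguity and
missing-not-at-random dropout in proteomics; segmentation error in
intensity measurements. Passing tests demonstrate the statistical machinery
is correct under the declared generative laws, not that those laws capture
every property of the deposited datasets.

## Problem sizes and numerical choices

Null-calling and recovery checks run at ~10,000 sites (6,667 genes × 1.5
sites/gene) with 5 seeds for the null; motif recovery uses 20 seeds of the
default 500-gene configuration; mixture recovery uses 10,000 pairs. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping a full run in tens of seconds. Degenerate inputs
are handled explicitly: zero-depth samples drop out of means, all-zero
conditions are flagged untestable, empty call tables return empty results,
constant vectors make correlations report "undefined" rather than raise,
and zero doubly-asymmetric pairs make concordance NaN with the count
reported.
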