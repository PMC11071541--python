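# Methods

`strainreg` analyses how two inbred mouse strains (labelled B6 and BALB
throughout, for C57BL/6 and BALB/c) differ in their transcriptional and
chromatin response to in-vivo cytokine treatment, and how those differences
are wired through enhancers, chromatin loops and TAD organisation.  This
note records the models, the numerical choices, and what the synthetic
cohort does and does not establish.

## The count model

RNA-seq and ATAC-seq counts are modelled as negative binomial,
NB(mu, alpha) with var = mu + alpha * mu^2, under a log-linear model of the
two-factor design

    log mu = intercept + strain + treatment + strain:treatment + log s_j

with per-sample size factors `s_j` from the median-of-ratios procedure
(per-gene geometric-mean reference, genes with any zero excluded, factors
rescaled to geometric mean 1).  GLMs are fitted by IRLS on the log link
(statsmodels, fixed-alpha NB family) with the log size factors as offset;
fits that fail to converge or produce coefficients beyond +/-30 on the log
scale fall back to a Welch test on log2(normalized + 1) and are flagged in
the output.

**Dispersion.**  Per gene, a method-of-moments estimate pools numerators
and denominators across every strain x treatment cell of the design:
`alpha = sum_c (n_c - 1)(v_c - m_c) / sum_c (n_c - 1) m_c^2` (cell mean
`m_c`, unbiased cell variance `v_c` of normalized counts).  Pooling the
ratio this way keeps the estimate consistent when cell means genuinely
differ; a pooled-mean variant is biased upward for responding genes.  With
n = 3 replicates per cell the raw estimate carries only ~16 degrees of
freedom, which makes plugin chi-square/normal references anticonservative
(we measured a null rejection rate of 0.090 at nominal 0.05) and costs
large amounts of power at strict FDR thresholds.  We therefore apply the
standard empirical-Bayes squeeze (the limma/edgeR-quasi-likelihood
convention): the per-gene quantity `x = alpha + 1/mean` — the squared
per-sample coefficient of variation the NB model implies on the log scale —
is treated as a scaled chi-square; the spread of `log x` across genes in
excess of its sampling variance (trigamma(dof/2)) determines a prior
degree-of-freedom d0, each gene's `x` is squeezed toward the common value
with weight d0/(dof + d0), and all downstream references gain dof + d0
degrees of freedom.  When the between-gene spread is fully explained by
sampling noise, d0 is effectively infinite and the test approaches the
known-dispersion oracle.  The floor on alpha is 1e-8.

**Tests.**
* *Pairwise differential test* (`fit_pairwise`): NB Wald test of a
  two-group contrast; z is referred to Student t with the moderated
  dispersion dof.  The reported log2 fold-change is computed from
  normalized group means with a pseudocount of 1 (finite for all-zero
  groups; disclosed in the results object).  The expression filter is
  FDR <= 0.05 (Benjamini-Hochberg) and |log2FC| >= 1; the accessibility
  filter for peak classification is FDR <= 0.001.
* *Interaction test* (`fit_interaction`): per-gene likelihood-ratio
  statistic of the full model against `strain + treatment`, the same
  moderated alpha shared by both fits.  With one degree of freedom per
  interaction column (3 for two strains x four treatments), stat/df is
  referred to F(df, moderated dof) — the quasi-likelihood small-sample
  reference; an asymptotic chi-square is anticonservative here for the
  same reason as above.  The statistic is clipped at 0 (nesting).  The
  direction label names the strain with the larger treatment response,
  taken from the largest-magnitude fitted interaction coefficient.
* *Synergy score*: S = log2FC(IL4+LPS vs Ctrl) − log2FC(IL4 vs Ctrl) −
  log2FC(LPS vs Ctrl) on pseudocounted normalized means; a gene is flagged
  synergistic when S > 0 and the pairwise IL4+LPS-vs-LPS test passes the
  expression filter.
* *Fano factor*: variance/mean of size-factor-normalized counts across a
  condition's replicates; 1 under Poisson noise, 1 + alpha*mu under NB.
  Zero-mean features are reported as undefined and excluded from
  summaries.
* *Group comparisons* (motif partition expression/induction, promoter-to-
  boundary distances) use Welch's unequal-variance two-sided t-test; each
  comparison records group sizes, means and SDs.  Identical-constant
  groups are flagged degenerate rather than given a p-value.

**Profile clustering.**  k-means under correlation distance
d(x, c) = 1 − Pearson(x, c): rows are centered and unit-normalized, Lloyd
iterations run on the standardized vectors, centroids are re-standardized
means.  Best of 5 restarts by total within-cluster distance; ties go to
the lowest restart index; an emptied cluster is re-seeded to the farthest
row; constant rows (undefined correlation) are dropped and reported.
Defaults k = 3 for treatment-response patterns and k = 6 for the
IL-4-priming synergy patterns.

## Interval conventions

All coordinates are 0-based, half-open.  BED/BEDPE are native; GTF
(1-based, closed) is converted on read, with the TSS of a '−' gene at
`end − 1`.  The promoter window is the strand-aware −400..+100 bp around
the TSS (501 bp, clipped at chromosome bounds).  Overlap queries use a
sorted-starts sweep with prefix running maxima, verified against an
all-pairs oracle in the tests; "sharing" between peak sets needs >= 1 bp.
Genomic-category annotation is by interval midpoint with precedence
promoter > exon > intron > intergenic.  Nearest-TSS assignment minimizes
|TSS − midpoint|, ties to the smaller TSS coordinate, then the smaller
gene id; signed distances are negative upstream of the TSS.

## Motif engine

PWMs are 4 x w position-probability matrices; log2-odds scores use a
pseudocount of 0.01 per cell against the background base composition.
Scores are discretized to a 1e-3-wide integer lattice; the exact
distribution of a random background word's score is computed by
column-wise convolution over that lattice, which equals full 4^w
enumeration at every lattice point (tested).  A scan threshold for target
p is the smallest lattice score whose exact tail probability is <= p
(default p = 1e-4); the scanner compares discretized window scores to
that threshold on both strands (reverse-complement = full flip of the
score matrix in ACGT order), reports reverse-strand hits on the forward
axis, skips windows containing N, and attaches the exact tail p-value of
each hit's score.  Note that short or low-information motifs can make
small p targets unattainable (the best word's probability exceeds p); the
threshold then sits above the maximum score and the scan returns nothing,
which is the correct reading of the request.

Set-level enrichment counts regions with >= 1 hit and computes the
hypergeometric upper tail of the foreground count drawn from the pooled
region set, BH-corrected across motifs.  This exact test suits
fixture-scale region sets; it is not HOMER's ZOOPS binomial, and
GC-matched background selection is out of scope.  The promoter/distal
gene partition marks a gene motif-bearing when a hit occurs in its
promoter window or in any ATAC peak overlapping a distal anchor of one of
its loops (accessibility-gated); genes without sequence coverage are
excluded and reported.

## 3D genome

A loop (BEDPE, intra-chromosomal, anchors ordered) is promoter-based when
an anchor overlaps a promoter window by >= 1 bp; the opposite anchor
becomes that gene's promoter-distal region (both genes served when both
anchors sit on promoters).  TAD boundary regions are the 100-kb flanks
outside each TAD edge, clipped at chromosome bounds, duplicates from
adjacent TADs retained.  Promoter-to-boundary distance is the interval
gap (0 on overlap) — not midpoint-to-midpoint; the alternative would
shift all distances by ~half the promoter length and does not change the
group comparison.  Cross-strain TAD sharing uses reciprocal overlap
(both fractions >= 0.5 by default, exposed as a flag).

## Enhancers and super-enhancers

An enhancer is an induced ATAC peak (FDR <= 0.001, positive fold-change)
with >= 1 bp of H3K27ac support; the reported geometry is the ATAC peak.
Super-enhancer calling follows the ROSE/HOMER convention: drop H3K27ac
peaks within 2 kb of any TSS, stitch the rest at gaps <= 12.5 kb, rank
stitched regions by total constituent signal, rescale rank and signal to
[0, 1], and call everything beyond the point where the curve's tangent
reaches slope 1 — identified discretely as the point farthest below the
diagonal, which the tests verify against evaluating every candidate cut.
A flat signal curve calls nothing; ties are ordered by (signal, chrom,
start, end) so the call set is invariant to input order.  Constituent
signal totals are conserved by stitching (tested).  Gene association is
nearest-TSS; a gene counts once however many elements point at it.

## The synthetic cohort

The generator emulates the study design — two strains x {Ctrl, IL4, LPS,
IL4+LPS} x 3 replicates — at desk scale with planted, exactly recorded
ground truth.  Defaults: 1,000 genes on 2 chromosomes of 4 Mb; NB
dispersion alpha = 0.05 and mean baseline ~100 counts (log-normal spread
0.5 log2); log-normal(0, 0.1^2) size factors; strain effect sd 0.25 log2
and treatment effect sd 0.5 log2 shared between strains; 20% of genes
carry a planted strain x treatment interaction of +2 log2 on the IL-4
response (half per strain); half of the designated strain's interaction
genes additionally carry a planted distal NF-kB consensus (GGGAATTTCC)
occurrence and +1.5 log2 extra induction; 5% of genes are synergy genes —
LPS-inducible (>= 1 log2), no standalone IL-4 response, +1.5 log2 above
additivity under IL4+LPS in the designated strain only, mirroring the
LPS-amplified cluster the method is meant to find.  ATAC peaks (baseline
~50 counts) comprise one constitutive promoter peak per gene, 300
background peaks, and one distal peak per interaction gene that gains
4-fold accessibility under IL-4 in its strain.  Every interaction gene
gets a loop from its promoter (5-kb anchors) to a distal anchor 60-120 kb
away containing its peak; planted motif occurrences sit at the peak
center, written into both strains' genomes (SNPs — rate 1e-3/bp — avoid
motif sites by default, with a flag to plant disrupting SNPs).  TADs tile
each chromosome with sizes 300-500 kb; the designated strain's
interaction genes have their TSS within +/-50 kb of an interior TAD
junction (inside the 100-kb boundary flanks by construction) while the
other strain's sit at TAD centers; 10% of the second strain's TADs are
shrunk past the 50% reciprocal threshold to register as strain-unique.
All draws flow from one seed through named sub-streams (annotation,
sequence, counts, landscape, peaks), so identical configs give
byte-identical fixture files (sha256 manifest).

What the cohort does **not** emulate: GC or mappability bias, peak-width
variation, replicate-level batch effects, dispersion trends in the mean,
overlapping genes or isoforms, inter-chromosomal loops, and real motif
information content (the planted PWM is sharp).  Passing tests therefore
establish internal correctness and statistical calibration under the
stated NB model — not performance on real sequencing artifacts.

The planted fraction is deliberately kept at ~25% of genes: the
median-of-ratios normalization assumes most features unchanged, and in an
early design with ~50% planted genes the size factors absorbed ~0.3 log2
of every planted fold change.  This interaction between planted density
and normalization is worth remembering when configuring custom fixtures.

## Problem sizes and runtime

The shipped validation runs use: a 2,000-gene null cohort for test
calibration; the 1,000-gene default cohort for recovery and the
end-to-end pipeline (run twice for byte-level determinism); 1,000-element
random interval fixtures for the brute-force oracles; widths 4/6/8 for
the 4^w motif enumerations.  These sizes give stable Monte-Carlo
estimates (binomial sd of a 0.05 rate at n = 2,000 is ~0.005) while the
whole suite completes in about a minute and the acceptance script in
about one minute on a single CPU.

## Known limitations

* The moderated-dispersion tests assume genes are approximately
  exchangeable after the alpha + 1/mean transform; strongly bimodal
  dispersion landscapes would weaken the squeeze (the prior dof adapts
  downward, at a power cost).
* Fold-change estimates use a pseudocount of 1, so they are compressed
  for very low counts and are not exactly invariant to rescaling a single
  sample (the median-of-ratios reference includes that sample); p-values
  and significance calls are stable at the 1e-2 level under such
  rescaling.
* EBSeq's empirical-Bayes pairwise machinery is not reimplemented; the
  pairwise NB Wald test with the same printed filter defines the
  downstream gene sets.
* Motif discovery, chromVAR deviations, GO enrichment, contact-map
  processing, and read-level simulation are out of scope; loops and TADs
  are consumed as BEDPE/BED produced upstream.
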