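# Methods

This note records the models, parameter choices and numerical decisions
behind beetlnc, and what the synthetic ground truth does and does not
establish about real data.

## Coordinate and sequence conventions

All intervals are 0-based half-open `[start, end)` on the forward strand;
GTF I/O converts at the boundary (GTF is 1-based inclusive). This makes
overlap and window arithmetic exact: two intervals overlap iff
`a.start < b.end and b.start < a.end`, and lengths are plain differences.
Sequences are stored in the DNA alphabet (`U` → `T` on read); the
binding-site scanner accepts either alphabet and compares in a common space.
Transcript sequences are spliced 5'→3' (reverse complemented for minus-strand
transcripts).

## lncRNA identification

The screen is a fixed filter cascade; each transcript receives exactly one
disposition, so the dispositions partition the input and the report is
order-independent.

- **Exon filter**: ≥ 2 exons. Single-exon assemblies are too often
  fragments or repeats to carry positional-class information.
- **Length filter**: strictly > 200 nt, i.e. retain ≥ 201 nt. 200 nt is the
  conventional lower bound of the "long" non-coding class; the strict
  reading keeps the boundary testable.
- **Exon-overlap filter**: ≥ 1 bp same-strand overlap between any transcript
  exon and any annotated protein-coding exon rejects the transcript.
  Restricting to the same strand is deliberate: an antisense lncRNA
  *necessarily* overlaps coding exons on the opposite strand, and a
  strand-blind filter would empty that class before classification.
  Overlap queries go through an interval tree; tests compare against an
  all-pairs scan.
- **Coding-potential gate**: three predicates, each with an explicit cut,
  all required to call non-coding (the intersection of a three-way Venn):
  - longest ORF < 300 nt (100 codons, the usual smallest-protein heuristic);
  - ORF coverage (ORF length / transcript length) < 0.5 — a long transcript
    dominated by one ORF is suspect even under 300 nt;
  - Fickett TESTCODE score < 0.95, the published cut below which sequences
    read as non-coding. The score combines per-base codon-position
    asymmetry (max/(min+1) of the three position counts) and base
    composition through the published lookup tables; it is deterministic
    and needs ≥ 200 nt.

  The gate is monotone by construction: removing any predicate can only
  grow the retained set.

The **ORF finder** scans the three forward frames of the spliced sense
sequence only (mature transcripts are single-stranded); an ORF must start
ATG and end at an in-frame stop (length includes the stop). Ties are broken
by smallest start, then lowest frame, making the result unique. Codons
containing `N` match neither ATG nor stop.

**Known-lncRNA exclusion** uses k-mer containment (k = 25, shared fraction
≥ 0.5, both strands indexed) rather than alignment: it is dependency-free,
exactly reproducible, and directly checkable by hand counting. k = 25 makes
random 25-mer collisions vanishingly rare at toy-genome scale, so the
shared fraction is essentially the aligned-identity fraction.

**Positional classification** applies precedence antisense > intronic >
lincRNA: (a) any exonic overlap with an opposite-strand gene's exons →
antisense; (b) else containment in a single same-strand gene span without
exon overlap → intronic; (c) else no gene-span overlap at all → lincRNA.
Transcripts that match none (partial span overlap without exon overlap) are
binned intronic: the label least likely to overstate independence from the
gene. The precedence yields a single deterministic label per transcript.

## Differential expression

Counts are NB with variance μ + φμ²; φ = 0 degenerates to Poisson.

- **Size factors**: per-sample trimmed mean (30 % each side) of log-ratios
  against the per-feature geometric-mean reference, over features positive
  in every sample, rescaled to geometric mean 1. The trim keeps the
  minority of strongly expressed or regulated features from tilting the
  scale — which is also why downstream co-expression is computed on
  size-factor-normalised counts rather than raw counts or per-matrix totals
  (a small feature panel's totals are dominated by exactly the features
  under study).
- **Dispersion**: per-feature method of moments on normalised counts,
  pooled within groups, floored at 0, then shrunk with weight 0.8 toward a
  common value. The common value is the across-feature *mean* of the
  unfloored estimates: the pooled variance is unbiased, so its mean
  recovers the true common dispersion, whereas the median of 2-df variance
  estimates sits ~30 % low at three replicates and would make the exact
  test anticonservative. Heavy shrinkage is appropriate at n = 3 per group,
  where individual estimates carry almost no information.
- **Exact test**: replicate counts are normalised to a common effective
  library size, summed per group, and rounded; conditional on the total
  `t`, the group-A sum follows NB(n_A/φ, p) (a sum of iid NB variables),
  and the two-sided p-value is the probability of all splits of `t` whose
  conditional probability does not exceed the observed one. A relative
  log-probability slack of 1e-9 absorbs floating-point ties (the symmetric
  binomial case has exact ties that double the p-value). At φ = 0 the
  conditional law is binomial; the NB path converges to it numerically
  (max |Δp| ≈ 1e-7 at φ = 1e-7 over all totals ≤ 200 — below that, gammaln
  at r = 1/φ loses precision, above it the NB deviation shows).
- **Calls**: lncRNAs (and miRNAs) at q < 0.05 alone; mRNAs additionally at
  |log₂FC| ≥ 1. The fold change uses normalised group means with a
  pseudo-mean of 0.5 so zero groups stay finite. The two tissues are
  independent CV-vs-LN comparisons.
- **BH FDR**: textbook step-up, `q_(i) = min_{j≥i} p_(j)·m/j`, clipped at
  1, stable under input order.
- **FPKM**: `count · 10⁹ / (length · library)`; invariant to uniform
  scaling of a sample's counts.

Calibration under the study design (3 v 3, φ = 0.1, 1,000 null features):
empirical P(p < 0.05) ≈ 0.055; with 60 planted |log₂FC| = 2 features at
base mean 100, recall ≈ 0.98 and empirical FDR ≈ 0.09 at q < 0.05 (the
acceptance suite recomputes these).

## Target inference

- **Cis**: window of 100,000 bp measured between the DEL's genomic *span*
  and the gene *span* (not TSS — the rule names the locus), overlap = 0,
  boundary inclusive; protein-coding genes on the same chromosome only.
  The signed distance is negative when the gene lies upstream (left) on
  forward coordinates.
- **Trans**: sample Pearson correlation across all 12 samples (a per-tissue
  mode exists) on size-factor-normalised counts; a pair requires strictly
  |r| > 0.95, restricted to (DEL, DEG) pairs. Zero-variance features are
  skipped with a warning. The trans/cis ratio is reported to 2 decimals,
  half-even.

## Enrichment

Upper-tail hypergeometric p-value via `scipy.stats.hypergeom.sf` (tests
verify it against exact rational enumeration for every N ≤ 30
parameterisation), BH across all tested terms, enriched at q ≤ 0.05
(inclusive, matching the cut's usual statement). The default universe is
the expressed gene set; zero-overlap terms are dropped before correction by
default since they carry p = 1 and only dilute it.

## ceRNA networks

The scanner is deliberately minimal: the full-length miRNA, ungapped, no
seed weighting, no thermodynamics — the two stated constraints only
(mismatches ≤ 3, i.e. "fewer than 4", and no G·U). G·U oppositions are
tallied as wobble, a category of their own: they are not counted as
mismatches, and any wobble disqualifies a site unless `allow_gu=True`. All
overlapping sites are reported; a pair keeps its best site (fewest
mismatches, earliest offset). Only the spliced sense strand is scanned.
miRNA–mRNA pairs use the same scanner and thresholds, keeping the pipeline
self-contained under one documented rule.

Triads require all three members differentially expressed in the tissue
and, by default, lncRNA–mRNA Pearson r > 0 across the tissue's samples
(`consistency="positive"`): a ceRNA and its protected mRNA should respond
co-directionally when competing for the same miRNA pool. The filter is a
switch (`"none"`) since co-direction is a modelling assumption, not part of
the binding rule. Hubs are the lncRNA(s) of maximal miRNA-degree, ties all
reported in lexicographic order. Exports are two typed edge lists
(`binds_lnc`, `targets_mrna`) plus a node-kind table, deterministic order,
SIF or TSV.

## qPCR

ΔCt subtracts the arithmetic mean of the reference Cts per sample
(equivalent to geometric-mean normalisation of linear quantities — the
standard multi-reference practice when no combination rule is specified);
ΔΔCt compares each treatment replicate to the calibrator-condition mean;
rel = 2^−ΔΔCt with amplification efficiency fixed at 2. Two exact
identities hold and are tested: a global Ct shift leaves rel unchanged, and
rel(A,B)·rel(B,A) = 1 on replicate means. Concordance marks a gene `agree`
/ `disagree` by direction against the RNA-seq call, `indeterminate` at rel
exactly 1, `not_comparable` for ns calls.

## The synthetic generator

What it emulates: a small genome (default 2 chromosomes × 2 Mb) with 60
multi-exon coding genes on both strands and a gene-free tail per chromosome
so > 100 kb cis edge cases exist; 104 planted lncRNAs (60 lincRNA, 30
intronic, 14 antisense — lincRNA-dominant, mean lincRNA length ≈ 400 nt)
plus transcripts built to fail each filter (single-exon, ≤ 200 nt including
the exact boundary, and ORF ≥ 300 nt "coding-like" rejects); the 12-sample
design with NB counts (mRNA mean 200, lncRNA mean 80, miRNA mean 300;
dispersions 0.05/0.1/0.05; log-normal library factors, sd 0.1); planted DE
at |log₂FC| = 2 (12 foliage / 24 root lncRNAs — root-dominant; 15 + 15
mRNAs; 7 miRNAs); correlated lncRNA–mRNA pairs; 21-nt miRNAs (inside the
18–30 nt small-RNA window) with one site per plan entry at 0–3 mismatches
plus negative controls (4 mismatches; a forced G·U); one term with
membership odds 40× higher for DE genes; and a Ct table consistent with the
planted fold changes.

Correlated pairs share a per-sample log-normal latent factor of unit mean.
For two NB features of mean m and dispersion φ sharing a latent with
squared CV c, the count correlation is `c / (1/m + φ(1+c) + c)`; the
generator inverts this to hit a target r exactly in expectation (raising an
error beyond the ceiling 1/(1+φ)). Positive planted pairs use r = 0.99 at
m = 5000, φ = 0.001; negative pairs oppose the planted DE direction
instead, which drives r ≈ −0.98 once library effects are normalised away.
Triad clusters share a milder latent (r = 0.9) so the positive-consistency
check holds. Sequence constraints are enforced by rejection sampling
(non-coding: ORF and coverage and Fickett below their cuts; coding:
constructed ORFs), and every planted site is verified by the scanner at
generation time, with site windows reserved so later plantings cannot
overwrite earlier ones. Antisense transcripts read the overlapped exon
chunk *from* the genome (never overwriting the host mRNA) and design only
their free parts; genes carrying an antisense lncRNA are excluded from
mRNA site planting.

What it does not emulate — and hence what green tests do not show about
real data: read-level artefacts (sequencing error, mapping ambiguity,
isoform deconvolution), GC or length biases, batch effects, outlier
samples, realistic genome composition (repeats, paralogy, real codon
usage), miRNA biogenesis, or thermodynamic binding. The geometry of planted
classes is deliberately unambiguous, so class recall/precision of 1.0
certifies the interval logic, not robustness to borderline annotations.

Problem sizes throughout (toy genome, ≤ ~170 expressed features, 12
samples) were chosen so the full pipeline runs in seconds and the entire
test suite in well under a minute on one core; they are study-shaped, not
study-sized.

## Known limitations

- The exact test rounds normalised group sums to integers; at very low
  counts this quantisation can shift p-values slightly.
- Dispersion shrinkage assumes a broadly shared dispersion; a handful of
  genuinely high-dispersion features will be over-liberal (their planted
  counterparts here are detected regardless because the effect is large).
- The enrichment background is a configuration choice (expressed vs all
  annotated genes); with a 60-gene universe the planted term is obvious,
  but subset selections (e.g. cis-target DEGs only) can miss it at some
  seeds — enrichment on small universes is noisy by nature.
- `exclude_known` is containment-based and will not recognise homology
  below ~50 % identity or heavily shuffled similarity.
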