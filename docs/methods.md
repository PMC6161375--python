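# Methods

`pmdscape` implements a pipeline for discovering and interpreting partially
methylated domains (PMDs) in whole-genome bisulfite sequencing (WGBS)
methylomes: single-sample segmentation, multi-sample meta-segmentation,
replication-timing classification, read-level methylation-pattern
statistics, and PMD/TAD topology comparison. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Data model

Coordinates are 0-based half-open throughout; BED and bedGraph files are
read and written as-is. A methylome is a per-CpG table (chrom, pos, strand,
coverage, methylated count); methylation level is methylated/coverage.
Strand merging (on by default in the CLI) sums the counts of a CpG dyad at
the plus-strand position; a minus-strand call with no partner is anchored
at pos−1 and logged. Segments with no covered CpGs get a missing score
(NaN), never 0. Sex chromosomes are excluded by default (`GenomeSpec`
exposes the exclusion list).

## Single-sample segmentation

CpGs with coverage < 5 are dropped and levels smoothed by a running mean
over 3 CpGs (truncated at chromosome ends, never crossing chromosomes).

**PMD/HMD caller.** A two-state hidden Markov model over smoothed per-CpG
levels: a foreground state with high methylation (HMD) and a background
state with low/intermediate methylation (PMD). Emissions are Beta
distributions on levels clamped to (1e−3, 1−1e−3) — levels are fractions
with boundary mass, which a Gaussian handles poorly. EM details:

- Initialization: state means 0.9 / 0.45 at concentration 10, sticky
  symmetric transitions (self-transition 0.999). Percentile-based
  initialization was rejected because it collapses on one-state inputs.
- M-step Beta updates are weighted maximum likelihood (L-BFGS on
  log-parameters with analytic digamma gradients), so the EM
  log-likelihood is monotone — asserted in tests.
- Decoding is per-CpG maximum posterior; ties go to the lower state index.
- Degenerate data: if the fitted state means end up within 0.1 of each
  other the split is arbitrary, so the chromosome is emitted as a single
  label chosen by its overall mean.
- Run-to-segment conversion places boundaries at the midpoint between the
  flanking CpGs of adjacent runs; chain ends clip to the first/last CpG
  (or the chromosome end when a genome is supplied).
- The 300 kb filter is applied symmetrically: any run shorter than
  `min_region_bp` is absorbed into its flanks, shortest first. Because
  two-state runs alternate, the receiving label is always well defined.
  Filtering only hypomethylated runs is subtly wrong: one mis-decoded
  high-state blip inside a true PMD splits it into two sub-threshold
  halves that would both be discarded.
- Chromosomes with fewer than 202 usable CpGs (twice the 101-CpG sliding
  window of the reference segmentation parameters) are skipped with a
  warning.

**UMR/LMR caller.** Outside PMDs, candidates are maximal runs of ≥ 4 CpGs
whose smoothed level is below 0.5. False discovery is controlled
empirically: raw levels are permuted within chromosome (B = 20), the
permuted sequence is re-smoothed, and candidates are re-detected. Permuting
*raw* levels and then smoothing matters — the null must carry the same
smoothing-induced autocorrelation as the observed scan, otherwise the null
candidate rate is understated by more than an order of magnitude. The
minimum-CpG-count cut is raised until (mean permuted candidates ≥ cut) /
(observed candidates ≥ cut) ≤ 0.05. Surviving regions with more than 30
CpGs are UMRs (promoter-like), the rest LMRs (enhancer-like).

`segment_full` composes the two callers; UMR/LMR/PMD/HMD partition the
non-gap, non-excluded genome exactly (gaps are consumed as a BED; they are
not fetched from annotation services). `fuse_and_filter` (50 kb fuse,
> 300 kb keep) prepares PMDs for the topology analyses and is idempotent.

## ChromH3M meta-segmentation

Per-sample PMD calls are binarized on a 1 kb genome grid (1 iff ≥ 1 bp
overlap) and modelled with a multi-state HMM whose emission for state k is
a product of independent per-sample Bernoullis — each hidden state is a
combinatorial occupancy pattern (shared PMD, group-specific PMD, shared
HMD, ...). Choices:

- 15 states by default (configurable; synthetic benchmarks use the
  generating architecture's state count).
- Baum-Welch with scaled forward-backward (numba-compiled); chains restart
  at chromosome boundaries; log-likelihood is monotone and convergence is
  declared at Δll < 1e−4 per 10⁶ bin-observations or 500 iterations.
- Initialization: k-means centroids over bin vectors plus seeded jitter of
  sd 0.02, clipped into [0.02, 0.98]; transitions start at 0.95
  self-transition. Fixed seed throughout.
- Bins with undefined PMD status carry code −1 and are marginalized out of
  the emission likelihood (not coded 0).
- Decoding is per-bin maximum posterior (ties: lowest state index); the
  per-state genome fractions and a BED state map are derived from it.

Samples are clustered on their emission-probability columns (and states on
rows) with Ward linkage on Euclidean distances — scipy's `ward` on raw
distances reproduces R's `ward.D2`. Emission probabilities are clustered
raw, not rescaled. Cluster uncertainty uses pvclust-style multiscale
bootstrap: features resampled with replacement at 10 scale factors r in
[0.5, 1.4], n = 10,000 by default; for each observed clade the recovery
frequencies are mapped through z = −Φ⁻¹(BP) and fitted by weighted least
squares to z(r) = v√r + c/√r; the approximately unbiased support is
AU = 100·(1 − Φ(v − c)). Clades recovered always/never short-circuit to
100/0. The package resamples emission-matrix rows by default (resampling
genome bins is available by passing the binary matrix instead).

## Region profiles and downstream clustering

`scale_regions_matrix` reproduces deepTools scale-regions semantics: the
region body is mapped linearly onto a fixed length, flanks are taken in
true coordinates, and each output bin is the length-weighted mean of the
bedGraph step function over its source interval. Means are computed from
the cumulative integral of the step function (exact; verified against a
per-bp oracle at 1e−9). Uncovered or out-of-chromosome source intervals
give NaN, never 0. Regions shorter than one source bin get their overall
mean in every body bin (logged).

On top of this sit: the 10 kb-bin methylation matrix with k-means (k = 6,
k-means++ with 10 restarts, fixed seed; clusters reported in decreasing
mean methylation; rows with any missing sample dropped), the PMD erosion
classes across a sample series (PMDs ≥ 20 kb, bodies normalized to 150 kb
in 1 kb bins, k = 3, classes numbered by decreasing methylation in the last
sample), the 80% gene-to-segment assignment rule (majority label, ties by
larger overlap), log10(FPKM+1), and DMR stratification: each DMR takes the
label covering its majority, and is retained iff its methylation delta
deviates from that compartment's global delta by more than tol = 0.1
(split into gain/loss); DMRs over unlabeled ground are kept unfiltered as
"unassigned".

## Replication timing

PMDs (≥ 300 kb after fuse-and-filter in the reference layout) are profiled
against the six Repli-seq phases (G1, S1–S4, G2) in scale-regions layout
and clustered by k-means into three classes. Classes are *named* by
ranking mean late-phase (S4+G2) signal: lowest = early/mid S, highest =
late S/G2. The classes are then re-predicted from H3K27me3/H3K9me3/H3K36me3
profiles with a random forest: stratified 75/25 split, model selection by
10-fold CV repeated 5 times over a small grid (trees ∈ {200, 500},
features-per-split ∈ {√p, 0.2p}), accuracy as the selection metric, and a
single evaluation on the held-out quarter. Reported accuracy is one-vs-all:
per class (TP+TN)/N in the class-vs-rest binarization, averaged over the
three classes (chance level for a balanced 3-class problem is 5/9).
Missing profile cells (flanks beyond chromosome ends) are imputed with the
region mean and logged.

## Read-level 4-CpG patterns

Within each read carrying ≥ 4 CpG calls, windows of 4 consecutive CpGs
(sliding, step 1 by default; both window and step configurable) are
classified fully methylated / fully unmethylated / mixed. Stratification by
segment label attributes each window to the label under the midpoint of its
first and last CpG. Under independent per-CpG demethylation with
probability q applied to fully methylated DNA, the expected fully
methylated fraction is (1−q)⁴ and fully unmethylated q⁴ — the calibration
check used in tests. A stable mixed fraction with mass moving from fully
methylated to fully unmethylated is the signature of gradual,
replication-coupled methylation loss.

## PMD/TAD comparison

Border association: for each TAD border, the distance to the nearest PMD
border on the same chromosome, against a null of uniform random borders
count-matched per chromosome; the two distance samples are compared with a
two-sided Mann-Whitney rank-sum test (they are unpaired by construction),
pooled across chromosomes. TADs are split into two classes by k-means on
their mean H3K27me3/H3K9me3/H3K36me3; the cluster with the higher
(H3K27me3 + H3K9me3) − H3K36me3 contrast is heterochromatic regardless of
cluster index. PMD vs heterochromatic-TAD base-pair overlap is exact
interval-sweep arithmetic (verified against a bitmap oracle).

## Synthetic-data generator

The generator emulates the qualitative structure of consortium WGBS
cohorts at desk scale, with every draw flowing from one integer seed:

- **State map**: blocks drawn per chromosome; states are shared-HMD,
  shared-PMD (26% of the genome by default, matching large-cohort
  estimates), and one PMD state per sample group (8% each). Block lengths
  are exponential (means 600 kb PMD / 800 kb HMD) truncated below at
  350 kb so planted domains sit above the pipeline's 300 kb working scale;
  draw probabilities are corrected by expected block length so bp shares
  hit their targets (law-of-large-numbers checked at 1 Gb).
- **Methylomes**: CpG positions with geometric spacing (mean 100 bp);
  per-CpG true levels Beta-distributed around label means HMD 0.9 /
  PMD 0.5 / LMR 0.25 / UMR 0.05 (concentrations 30/8/10/10 — PMDs are
  deliberately the most disordered); coverage negative-binomial
  (mean 30, size 10); methylated counts binomial. Short UMRs (5 kb) and
  LMRs (1 kb) are planted sparsely in HMD ground.
- **Tracks**: 5 kb-bin step functions; heterochromatic marks are 4× enriched
  over PMDs, H3K36me3 over HMDs; Repli-seq phase profiles peak in different
  phases per planted replication class; Gaussian noise with sd = 0.1 of the
  class peak.
- **Reads**: runs of 6 consecutive CpGs with Bernoulli calls from the true
  levels; an erosion option applies independent per-CpG demethylation.
- **TADs**: PMD borders jittered by N(0, 5 kb) plus sparse random extra
  borders.
- `perturb_segments` adds sample-level call variability (border jitter sd
  10 kb, 2% segment dropout) so multi-sample benchmarks do not cluster
  identical columns.

What the generator does *not* emulate: sequence context and actual CpG
density variation (CpG islands), bisulfite conversion errors, copy-number
or mappability artifacts, correlated noise between marks, and the
continuous (rather than block-wise) erosion spectrum of real cancer
methylomes. Passing recovery benchmarks therefore demonstrates algorithmic
correctness and calibration on the generating model, not performance on
real cohorts.

## Benchmark problem sizes

The verification surface (`pmdscape.benchmarks`, driven by
`scripts/acceptance.py` and the test suite) uses desk-scale sizes chosen to
make every statistic well estimated: exact forward-vs-enumeration toys of
≤ 8 bins / ≤ 3 states; 50,000 bins × 4 samples for meta-HMM parameter
recovery; 12 samples in 3 groups on a 50 Mb genome for the end-to-end
meta-segmentation; a 10 Mb genome for segmentation recovery; 300 PMDs of
120 kb with 10 kb profile bins (body 100 kb, flanks 50 kb) for the
replication classifier — the API defaults remain at the reference 1 kb /
500 kb / 250 kb layout; 1,000 random reads for pattern statistics; 100
planted and 200 null replicates for the border test. AU bootstrap defaults
to n = 10,000 (a few seconds for a 12-sample tree); tests use smaller n.

## Known limitations

- The PMD caller is the two-state Beta HMM described above; it follows the
  published parameterization of the reference segmentation but is not a
  bit-exact reimplementation of MethylSeekR's α-distribution caller.
- The UMR/LMR FDR cut is one-dimensional (CpG count); a joint
  (count, mean-level) cut could be sharper for borderline regions.
- The AU fit uses the two-parameter signed-distance/curvature model
  without pvclust's higher-order corrections; values can differ by a few
  points for weakly supported clades.
- `stratify_dmrs` is a lightweight screen against the global compartment
  delta; it does not re-estimate per-DMR uncertainty.
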