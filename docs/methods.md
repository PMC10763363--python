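# Methods

This note records the models implemented in `dvburst`, the conventions and
defaults chosen where the analysis design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinates and counting

All coordinates are 0-based half-open (BED convention); 1-based dialects
are converted at the file boundary. The TSS of a minus-strand gene is the
end coordinate of its annotation, and every window is strand-aware: the
promoter window is [tss−50, tss+100) on the plus strand and its mirror
image [tss−99, tss+51) on the minus strand, clipped at position 0.
Run-on reads are represented by their 3′-end single base — the position of
the transcriptionally engaged polymerase. Gene bodies are CDS intervals
(avoiding intronic eRNA signal); for multi-isoform genes the transcript
with the highest length-normalized gene-body count is used, ties broken
lexicographically.

## Normalization and the pausing index

Size factors are median-of-ratios (the DESeq2 estimator): the median over
all-positive features of the log-ratio to the per-feature geometric mean,
exponentiated and rescaled to geometric mean 1. Note the median is taken
in log space, so an even feature count interpolates geometrically — this
matches the reference implementation exactly.

The pausing index PI = PC/(PC+GBC) is a within-sample ratio, so
normalization cancels inside a sample; it matters only when replicates are
combined. We compute PI per replicate on normalized counts and average
afterwards (the alternative — pooling counts before the ratio — weights
replicates by depth; averaging after treats replicates symmetrically).
Genes with PC + GBC = 0 have undefined PI, are flagged NaN, excluded from
summaries, and counted in the stage logs. The low-count filter removes
genes with fewer than 10 gene-body reads **summed across samples**; a
per-sample rule would drop borderline genes condition-dependently and bias
differential calls.

## Latent-axis tissue scoring

Counts are transformed as log2(count/size_factor + 1) and feature-centered
before PCA (SVD on the samples × features matrix). Sign convention: each
PC is oriented so its largest-magnitude feature loading is positive,
making decompositions reproducible across BLAS implementations. The PC
subspace used for scoring is configurable; the automatic rule selects the
smallest leading set of PCs — starting at (number of conditions − 1),
since fewer dimensions cannot separate all condition means — whose sample
scores separate every pair of condition means by at least twice the
within-condition spread.

Condition latent vectors run from the origin through the mean of the
condition's sample scores, normalized to unit length. Features are
projected into the sample-score space by the biplot convention
(loading × singular value) so feature coordinates and sample scores share
a scale; the raw score is the dot product with the condition's unit
vector, standardized to a z-score over all features. The z ≥ 3 call is
inclusive and applied globally (not per condition); multi-condition
features are assigned by argmax with ties broken by a fixed condition
order.

## Enhancer calling and pairing

Regions overlapping any TSS ± 150 bp are excluded up front (the flank is
configurable; the intent is to keep promoter elements out of the enhancer
set). Per-assay z-scores come from the same latent-axis machinery. A
region is a candidate enhancer for a condition when its z lies strictly
above the (1 − fraction) quantile in at least one assay, capped at
⌊fraction·n⌋ regions with ties broken by region name. The strict
inequality matters in degenerate data: regions exactly tied at the
threshold (e.g. a flat background) are not candidates, while in continuous
data the rule reduces to the familiar "top 5 %".

The combined chromatin-state score of a region in a condition is the sum
of its ATAC, CBP, and H3K27ac z-scores. Candidates pair to every
same-condition tissue-specific gene whose TSS lies in the same TAD;
regions spanning a TAD boundary are assigned by midpoint (and logged).
Distance is measured from the nearest region edge to the TSS (0 if the TSS
is inside); ≤ 700 bp is proximal, inclusive. The score-versus-expression
regression pools enhancer–gene pairs within a condition (genes with
several enhancers contribute several points); gene-level averaging is
available behind a flag in the integration layer. Accessibility dynamics
use log2((later+1)/(baseline+1)) against the 3 h time point with the
gained/lost boundaries at ±0.5 inclusive. eRNA counting is strand-aware:
intergenic enhancers count both strands, genic enhancers only the strand
antisense to the host gene, with a +1 pseudocount for fold changes.

False-positive candidates are worth flagging: a background region that
sneaks into the candidate set carries a near-zero combined score while its
TAD partner gene may have a large z, creating a high-leverage outlier in
the regression. The default toy genome is calibrated so planted enhancers
per condition fill just under the 5 % cut, which keeps this contamination
out of the clean-recovery checks; larger genomes deliberately re-expose
it.

## Two-state burst-kinetics inference

The telegraph model has four rates; mRNA degradation is fixed to 1, so
k_on, k_off, k_syn are per mean mRNA lifetime and no absolute-time
calibration is attempted. The steady-state pmf is a Beta-Poisson mixture,
evaluated by 50-node Gauss–Jacobi quadrature under the Beta(k_on, k_off)
weight — accurate for sub-unity shape parameters where the density
diverges at the endpoints — with a confluent-hypergeometric closed form
(Kummer-transformed so all series terms are positive) as an independent
route; the two agree to < 1e−8 wherever the hypergeometric evaluation
stays finite (it overflows for k_syn ≳ 700).

Maximum likelihood runs in log-parameter space (Nelder–Mead) within bounds
k_on ∈ [1e−3, 1e3], k_off ∈ [1e−3, 1e4], k_syn ∈ [1e−2, 1e4], enforced by
clipping plus a quadratic penalty; parameter regions where the quadrature
mass overflows yield non-finite likelihoods and are rejected by the same
guard. The start point inverts the first three factorial moments in
closed form (falling back to (1, 10, 2·max) on degenerate solutions), and
two seeded log-normal jittered restarts (sd 0.5) reduce local-optimum
risk. Genes with all-zero counts in a cluster are reported as "not
inferred", never assigned boundary estimates.

Bootstrap CIs resample cells with replacement 100 times and refit each
resample exactly as the original data are analysed — starting from the
resample's own moments estimate — with slightly looser simplex tolerances
(xatol 1e−3, fatol 1e−4), which are ample for interval endpoints.
Intervals are bias-corrected percentiles (BCa with acceleration 0): the
percentile levels are shifted by the median bias of the bootstrap
distribution relative to the point estimate, the standard no-extra-cost
correction for skewed estimators; with zero median bias it reduces to the
plain 2.5/97.5 percentile interval at the default 0.95 level. Measured
coverage of the true k_on at the reference configuration (k_on = 1,
k_off = 10, k_syn = 100, 1,000 cells, pooled over replicate genes) is ~0.91.
"CI" in the width filter means upper − lower. If more than half the
refits fail, the CI is flagged unreliable.

Two quality filters follow. (1) The burst-size mixture filter fits a
two-component Gaussian mixture by EM on log10 burst size per cluster
(zeros dropped first) and keeps genes whose posterior probability of the
higher-mean component is ≥ 0.5. Unimodality is decided primarily by BIC
(1 vs 2 components): a forced two-component fit to a genuinely unimodal
Gaussian places its means ~1.4σ apart, so a fixed mean-separation
threshold cannot detect unimodality by itself; the separation (< 0.25
log10) and weight (< 0.01) guards are retained as secondary checks, and EM
non-convergence keeps all genes, flagged. The log scale stabilizes EM
relative to raw burst sizes. (2) The CI-width inequalities
log10 CI(k_on) < 1.3 + 0.8·log10 k_on and log10 CI(bs) < 1.0 + 0.8·log10 bs
discard noisy inferences; both are strict and monotone — widening a CI can
only flip pass → fail.

Cross-cluster comparison: "inactive" clusters are all clusters other than
the active one in which the gene itself passed both filters. A frequency
(or size) change is significant only if the active cluster's CI is
disjoint from **every** inactive cluster's CI; the class is frequency,
size, both, or none accordingly, and fold changes are log2(active / mean
of inactive). Derived parameters: promoter mean occupancy
k_on/(k_on+k_off), switching correlation time 1/(k_on+k_off), mean
synthesis rate k_syn·k_on/(k_on+k_off).

## Integration

Per-feature condition deltas are z_active − mean(z_inactive). Genes with
several enhancers aggregate enhancer-layer deltas by mean (per-pair mode
available). Layer–kinetic association is Pearson r with R² = r² and a
two-sided t-test p (n − 2 df); no multiple-testing correction is applied
across the layer × kinetic matrix by default (a Benjamini–Hochberg option
exists). The proximal-versus-distal comparison is a two-sided Wilcoxon
rank-sum; the exact null is used for group sizes ≤ 12 without ties,
otherwise the tie-corrected normal approximation.

## Synthetic data: what it emulates, what it does not

The bulk generator reproduces the 3-genotype × 2-replicate design:
negative-binomial counts (Var = μ + αμ², α = 0.05 — typical bulk replicate
noise) around log-uniform baselines in [20, 2000] gene-body reads, 5 %
very-low genes (baseline < ~1) to exercise the read filter, planted genes
boosted 2^3 in one condition, promoter counts at a shared 2× pause
enrichment (tissue-invariant pausing), and per-sample size factors uniform
in [0.5, 2]. At this noise level the 2-vs-4-replicate log2 ratio of a
planted gene has an sd of ≈ 0.28, so ~92 % of planted genes land within
±0.5 of the planted effect — the tests assert that analytic expectation,
not a tighter one.

The toy genome packs 8 non-overlapping 100 kb TADs on one synthetic
chromosome "chrS", 3 genes per TAD (one per genotype, so TAD + condition
pairing is uniquely resolving), 2 enhancers per gene placed inside the
target's TAD and clear of every TSS ± 150 bp, with 20 % placed within
700 bp of the TSS. A single per-enhancer latent signal, correlated with
the standardized gene effect at the requested coupling, drives all three
assays (offset so the condition boost never dips below ~2×); background
regions at 6× the enhancer count carry condition-flat signal. Zero-noise
mode replaces sampling with exact means, giving the exactness limits
(recovery 1.0, R² = 1).

UMI counts are drawn gene-by-gene from the generative Beta-Poisson process
per cluster. None of the generators model ambient RNA, doublets, capture
efficiency, cell-size variation, batch structure, mappability, or GC bias
— passing tests demonstrate correctness of the estimators under the
model's own assumptions, not robustness to those artifacts.

## Problem sizes and numerical choices

The self-check suite uses 2,060 bulk genes (60 planted), the default toy
genome (48 enhancers, 336 regions), a 3 × 2 kinetic grid × 10 replicate
genes at 2,000 cells for recovery error, 100 replicate genes at the
reference rates (1,000 cells, 100 bootstraps each) for CI coverage, and a
10⁶-draw Monte-Carlo pmf oracle — sizes chosen so each check is statistically decisive while
the whole suite runs on a single CPU in minutes. The enhancer R² at
coupling 0.9 is reported as the mean of per-condition regressions over 5
replicate genomes: a single 16-pair regression has an R² sampling sd of
~0.07, and the per-condition form matches how the score-versus-expression
relation is defined. Monte-Carlo pmf agreement is asserted as ≥ 98 % of
support points within 3 binomial SEs (≈ 0.3 % fall outside by chance) and
all within 6 SEs.

## Known limitations

Pausing itself may constitute an additional promoter state; the two-state
model absorbs it into OFF, and no pause-extended (3- or 4-state) model is
attempted. k_off and k_syn are individually weakly identified at low
occupancy (their ratio — burst size — is what the data constrain).
Bootstrap CIs inherit the usual percentile-bootstrap undercoverage at
small cell counts. The interval engine is a simple sorted sweep, adequate
for desk-scale region sets, not a genome-scale interval tree.
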