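# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not establish about
real data.

## Differential protein abundance

Input is a proteins × samples matrix of raw, strictly positive DIA
intensities with a sample → genotype design. Every present value is
log2-transformed; no normalisation or imputation is applied before testing.
That choice is deliberate: the packaged tables reproduce the reference
fold changes (NALP5 −8.47 Hom vs WT, −0.55 Het vs WT; 0.3% and 68% of the
WT level) under plain per-group means of log2 intensities, which implies no
width/median normalisation was involved in producing them. Fold change is
the difference of per-group mean log2 intensities — not the log of the
ratio of mean raw intensities, which would be dominated by single large
samples. The test is Student's two-sample *t* (equal variance), the common
default for intensity matrices of this kind; Welch is available via
`equal_var=False`. Proteins with fewer than two present values in either
group are flagged untestable and excluded from the Benjamini–Hochberg
family rather than polluting it. Significance is q < 0.1 and |log2FC| > 0.5
(both strict). Reported percentages follow the field's rounding: one
decimal below 10%, integers above; stored values are full precision.

One packaged-table observation worth recording: KDM2B shows a 38.8%
reduction under these conventions, whichever of the log-mean or
arithmetic-mean definitions is used — a percent in the high thirties, not
above forty. The heatmap standardisation `dataset_zscore_then_row_center`
divides by the global *variance* (not the standard deviation), matching the
convention of the comparative display it implements; `center_rows` is the
plain per-protein centring.

## Single-cell methylome

Coordinates are 1-based inclusive internally (the Bismark coverage
dialect); BED input is converted at the boundary. Coverage files are
assumed destranded. The percentage column of coverage files is ignored and
recomputed from counts.

**QC screen.** Somatic DNA contamination in an oocyte library breaks three
independent signatures simultaneously, and the screen tests each:

1. *X-CGI methylation*: oocyte X-chromosome CpG islands are hypomethylated;
   pooled methylation strictly above 10% flags contamination.
2. *Context ratios*: oocytes show mCpG < 40%, mCHG > 3%, mCHH > 4% (all
   strict, as printed); somatic DNA has high mCpG and near-zero non-CpG
   methylation.
3. *Bimodality*: over tiles with ≥5 calls, the fractions of tiles at ≤25%
   (low), ≥75% (high) and in between (mid) are computed. The criterion is
   described in the field only visually ("peaks at 0% and 100%"), so it is
   operationalised here as mid ≤ 0.20 with both tails ≥ 0.05; all three
   thresholds are keyword arguments. Cells with fewer than 50 informative
   tiles are untestable.

Untestable criteria exclude the cell conservatively, with the reason in the
per-cell report. Cells failing the read-count filter are not evaluated
further (criteria reported as `not_tested`).

**Tiling and statistics.** Tiles contain exactly 100 consecutive reference
CpGs; trailing partial windows are dropped rather than emitted short, so
tile statistics are homogeneous. Domain bands 0–25% / 75–100% are closed
intervals; screening and significance thresholds (>10%, <40%, >3%, >4%,
>25 pp, >75%, >100 calls/kb) are strict, as printed. The per-tile test is
the Pearson chi-square on the 2×2 (methylated, unmethylated) × group table,
df = 1, without Yates continuity correction, computed on pseudo-bulked
counts — individual cells are far too sparse for per-cell testing.
"Adjusted p-value" is implemented as Benjamini–Hochberg. The gDMR coverage
filter (>100 CpG calls/kb) is applied to both groups by default, the
conservative reading; `density_mode="either"` relaxes it. Per-cell global
methylation is the unweighted mean of informative tile percentages with a
default of 5 calls per tile (the per-cell histogram convention; the
pseudo-bulk convention of 30 is a keyword); groups are compared with a
Welch *t*-test and the difference of group medians.

## Expression and staging

QC bounds follow the printed inequalities; "37–50% genes measured" is
closed on both ends, reads ≥ 4 million passes. The NSN/SN staging score is
the mean z-scored log1p-CPM of SN markers minus NSN markers, with a
symmetric margin (default 0.5) below which a cell is ambiguous; the
statistic and margin are exposed because the underlying classification is
described only as marker-based with unclear cells excluded. Zero-variance
marker genes contribute zero to the score, so an all-zero-marker cell is
ambiguous, never mis-staged. DEG significance is inclusive (q ≤ 0.05,
|log2FC| ≥ 0.5), as printed. Differential expression is pluggable: the
built-in `surrogate_de_test` is a Welch *t* on library-size-normalised
log2(CPM+1) — adequate for planted-effect recovery and null calibration on
synthetic data, and explicitly not a negative-binomial shrinkage model;
externally computed per-gene tables in the same (gene, log2fc, p) schema
drop into `threshold_degs` unchanged.

## Integration

The hypergeometric universe is the set of features detected in both omics
layers under a one-to-one gene ↔ protein map, since overlap probabilities
are meaningless over features only one layer could have called. The test is
upper-tail (enrichment); depletion is available via `tail="lower"`.

## Synthetic data

The generators are pure functions of (spec, seed) — identical inputs give
byte-identical outputs — and every planted effect is recorded exactly once
in the emitted `SimTruth`.

**Methylome.** The default genome is 5 autosomes plus X, 20,000 CpGs per
chromosome at 50 bp spacing — small enough for desk-scale runs, large
enough for 1,200 full 100-CpG tiles, and CpG-dense enough that gDMR
coverage in calls/kb reaches realistic CGI-like values. Tiles alternate
hypomethylated blocks (6 tiles at 5%) and hypermethylated blocks (4 tiles
at 90%), giving a genome-wide oocyte mCpG just under 40% — inside the
context-QC bound, as in real oocytes. Each CpG is covered independently
with probability coverage_rate/total sites (default expectation 50,000
covered CpGs per cell), with zero-truncated Poisson read depth (mean
parameter 2), matching the sparsity that motivates the call-count
thresholds. Contamination acts at the read level: each read is drawn from
the somatic profile with the cell's mixing probability, so CpG sites, the
context summary and X-CGI methylation shift jointly — the property the
three-criterion screen relies on. The somatic profile is unimodal at 70%
CpG methylation with 40% X-CGIs and 0.5% non-CpG methylation; the true
contaminant's global level is not documented in the screen-development
setting, so these are conventional somatic values, not fitted ones. Ten
gDMRs (40 CpGs each, 85% in WT) sit inside hypermethylated blocks; three
carry a planted −30 pp knockout effect, mirroring the three hypomethylated
gDMRs the analysis is designed to detect. The global knockout effect
subtracts 12.5 pp from hypermethylated-block levels, which under the 40%
hyper-tile layout induces a ≈5 pp deficit in mean-of-tiles global
methylation — the magnitude of the real effect; the exactly realised
expectation is recorded in `SimTruth.extras`.

**Proteome.** log2 intensity = per-protein baseline (Uniform(15, 25)) +
planted group shift + Normal(0, sd = 0.25); intensities are 2 to that
power, with optional missingness. The sd default is a typical
between-replicate spread for bulk DIA at this sample size.

**Transcriptome.** Counts are negative binomial (dispersion 0.1) with
20-gene NSN and SN marker modules at 10× stage-specific multipliers, and
planted knockout shifts applied in KO cells of both stages. The default
cell layout (4+4 NSN, 6+2 SN) mirrors the post-QC design the staging
analysis faces.

**What passing tests do and do not show.** The generators carry the
*assumed* statistical structure — binomial site sampling, independent
coverage, clean marker modules, log-normal intensities. Passing tests
establish that the pipeline's statistics are correct and calibrated under
that structure (oracle equivalence, FDR control, planted-effect recovery,
screen monotonicity). They do not establish robustness to what real data
add: correlated coverage along the genome, bisulfite conversion failure,
batch effects, overdispersion beyond the NB, or partially contaminated
reference annotations.

## Problem sizes and numerical choices

Test and acceptance runs use the default synthetic genome (120,000 CpGs,
10 cells per group) for recovery experiments; a 3-chromosome, 12,000-CpG
genome for replicated screen experiments; 1,000 tiles × 20 replicates for
null FDR control; and 3,000–4,000 proteins for null calibration — sizes at
which the Monte-Carlo error bands quoted in the tests are meaningful and a
full run completes in seconds. Ties and degenerate inputs: a 2×2 table
with a zero margin is an error (the statistic is undefined); identical
constant groups in the Welch comparison return p = 1; zero-variance genes
z-score to 0; BH is applied only over the tested family.
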