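# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind `dualscreen`, and what the synthetic-data generators do
and do not emulate.

## Screen normalization and phenotype correlation

High-content screens measure many colony features per well; absolute
feature values carry strong plate-level batch effects (staining intensity,
imaging session). `zscore_by_plate` therefore normalizes each
(plate, feature) group to mean 0 and **sample** SD 1 (ddof = 1; plate
groups in screens are small, so the sample estimator is the appropriate
one). By default the moments come from all wells on a plate; a
`controls=` argument switches to control-well moments for screens in which
many perturbations are expected to shift the plate distribution. Both
modes are exposed because either convention is defensible; all-wells is
the default for robustness when controls are few.

Replicates are averaged **after** Z-scoring, one profile per knockdown;
knockdowns present in fewer than `min_replicates` (default 2) replicates
are excluded and reported rather than silently averaged. Knockdown
similarity is the Pearson correlation of profiles over the feature axis.
Correlation needs at least 3 features and strictly positive per-profile
variance; degenerate profiles raise by name instead of propagating NaNs.
The feature subset used for correlation is configurable (screens often
curate a reduced feature panel, e.g. ~27 informative features); the
default is all features. A consequence of Z-scoring worth noting: the
composed pipeline (Z-score → average → correlate) is invariant to any
per-feature affine rescaling applied uniformly across knockdowns, so
feature units never matter.

Zero-variance (plate, feature) groups are a hard error listing the groups:
silent NaN propagation in a screen with hundreds of downstream consumers
is far more expensive than an early failure.

## Differential expression

Counts are normalized as `log2((count + 0.5) / (libsize + 1) × 1e6)`.
This fixed prior/offset formula is a deliberately simple, documented
stand-in for edgeR's `cpm(log=TRUE)`; the cited implementation rescales
the prior per library, which is not replicated here (differences are
negligible for counts well above the prior).

`simple_de` is the package's DE engine for the common knockdown-vs-control
contrast; it is a substitute for a full negative-binomial GLM framework
(DESeq2/edgeR), which can also be used externally, with results ingested
via `read_de_table`. The engine:

1. excludes genes with zero counts in every sample (reported, not tested);
2. re-centers each sample's log2-CPM by its median log-ratio to the
   gene-wise mean profile. This is a median-of-ratios size correction:
   when a sizeable fraction of genes is differentially expressed, the DE
   genes distort the library totals and every null gene would otherwise
   inherit a coherent spurious fold change. The median over genes is
   robust to realistic DE fractions (tens of percent);
3. computes a two-sample t statistic per gene with **empirical-Bayes
   variance moderation**: the pooled per-gene variance (df = nₐ + n_b − 2)
   is squeezed toward a scaled inverse-chi-square prior fitted by the
   method of moments on log variances (Smyth 2004), with the prior scale
   following the mean-variance trend over average log2-CPM (estimated by
   quantile-binned means, linearly interpolated — counts have higher
   relative variance at low expression, and a constant prior would shrink
   low-expression genes anticonservatively). The moderated t has
   df = d₀ + d; when the excess log-variance spread is non-positive the
   prior df is infinite and the test reduces to a z-test against the
   trend variance;
4. adjusts p-values by Benjamini–Hochberg (statsmodels).

Moderation is the default because at the 2–3 replicates typical of
knockdown screens the raw per-gene variance estimate has ~2–4 df: a plain
Welch test then lacks the power to detect even 4-fold changes at
genome-wide correction. `moderated=False` gives the plain Welch test for
users who prefer it. Undefined tests (identical constant groups) get
p = 1 rather than NaN.

DE gene sets use a **strict** cutoff `padj < α` (default 0.05), split by
log2FC sign, with the universe defined as all tested genes. The universe
is explicit and mandatory in every enrichment computation — overlap
statistics are meaningless without it. Gene symbols are uppercased before
any join, since symbol joins across datasets routinely mix `Ncor1` /
`NCOR1` casings.

## Overlap enrichment

For sets A, B in universe N: expected overlap `|A||B|/N`, fold enrichment
`k·N/(|A||B|)` (computed as one rounding from the exact rational), and
significance `P(X ≥ k)` for X hypergeometric — the upper tail *including*
k, the standard over-representation convention. The tail is summed in log
space from log-gamma binomial coefficients (log-sum-exp), so `log10_p`
remains finite and accurate for probabilities far below the double
underflow threshold; `p` itself is floored at the smallest positive
double. The arguments are canonicalized so the tail is bitwise symmetric
in (marked, drawn). No multiple-testing correction is applied across the
handful of overlap tests a study reports (raw p-values are what such
tables print); a BH pass can be applied by the caller to the result list.

## Clustering and trajectories

Log2FC matrices over (condition, timepoint) columns are assembled from
per-condition DE tables; genes absent from a table are filled with 0 and
warned about (`fill-zero`), or dropped (`drop-gene`). Hierarchical
clustering uses SciPy agglomerative linkage (euclidean or correlation
distances; average/complete/ward) cut to exactly k clusters; k is
user-set — studies of this kind choose k by inspecting the dendrogram, and
no automatic selection is attempted. Labels are renumbered by decreasing
cluster size (ties by first row index), making partitions deterministic
and row-order invariant up to relabeling.

Trajectory summaries divide each gene's time course by its own maximum
(each gene peaks at exactly 1), then report the per-timepoint median over
the gene set with a bootstrap percentile 95% CI obtained by resampling
genes (default 1000 resamples, seeded). The bootstrap was chosen because
the underlying studies report a CI band without stating its construction;
percentile-of-median is the simplest assumption-free choice. The interval
is clipped to contain the observed median, which percentile bootstraps on
very small sets can otherwise nick. Max-normalization requires strictly
positive input (log-scale expression of expressed genes); non-positive
values raise with instructions rather than producing sign-flipped curves.

## Genomic integration

All coordinates are 0-based half-open (BED); GFF3 is converted on read
(start − 1). Promoter windows are strand-aware around the TSS with
explicit extents (default −2000/+500 bp) — "promoter" has no universal
definition, so the window is configuration, not convention. Peak-to-gene
assignment offers a case-normalized symbol join (for pre-annotated peaks)
and a summit-in-promoter-window mode; a summit inside several overlapping
windows maps to all of them — no arbitrary tie-break.

Interval intersection is a per-chromosome sweep line (ends processed
before starts at equal positions, so abutting half-open intervals do not
overlap), with deterministic output ordering.

Coverage tracks are sorted non-overlapping scored intervals under the
convention that one read contributes one score unit over one base, so the
integral of score over a region is a read count: RPM = raw × 10⁶ /
total_reads and RPKM = RPM × 10³ / length follow directly.
`total_reads` is stored explicitly (or inferred as the total score mass).
Summit matrices bin the window [summit − flank, summit + flank)
(default ±5 kb, 100 bins — bins must be even so the summit sits on a bin
boundary) and normalize each bin like a region, so the mean over bins of
bin-RPKM equals the whole-window RPKM exactly. Windows running off a
chromosome are zero-padded with a warning. Optional hierarchical row
ordering reuses the clustering machinery (average-linkage euclidean leaf
order).

## Synthetic data: what it emulates, what it does not

The generators are pure functions of (parameters, seed); each call derives
a fresh NumPy `Generator` and no global state is touched.

* **Screens** use a latent-factor model: each planted module owns one
  loading vector over features, every member's profile is
  `effect_size × loading + N(0, noise_sd²)` plus an additive
  per-(plate, feature) offset. One shared factor per module is the
  simplest structure that produces the between-knockdown correlations the
  analysis detects; plate offsets are additive because plate Z-scoring
  must have a removable bias to remove. Knockdowns are split round-robin
  into plate layouts, each replicate of a layout being one physical plate,
  so every knockdown appears once per plate. Defaults (30 knockdowns, 27
  features, 4 replicates, 2 layouts, one 3-member module at effect 2 SD,
  noise SD 1) mirror the secondary-screen scale of the motivating study
  design.
* **Counts** are Gamma–Poisson (NB) with Var = μ + αμ²; α = 0 degenerates
  to exact Poisson. Condition means are `baseline_μ · 2^log2FC` scaled by
  per-sample library size relative to the mean. Baseline means default to
  log-uniform in [100, 1000] — the well-expressed range a DE analysis
  would actually test — and library sizes to uniform [0.8, 1.2] × 10⁶.
  Dispersion defaults to 0.05, a typical within-group value for cell-line
  RNA-seq. The multi-knockdown generator plants one shared signature per
  module (default 100 genes at |log2FC| = 2) plus private DE genes per
  knockdown (default 30), all against one shared control group — which
  also reproduces the shared-control correlation floor a real screen has.
* **Time courses** are strictly positive:
  `baseline × level(t) × exp(N(0, σ²))` with geometric interpolation
  between planted start/end levels (monotone for decay sets) and
  multiplicative log-normal noise (σ = 0.2).
* **Genomic tracks** place genes uniformly on the given chromosomes,
  plant a peak in the ±flank TSS window of each target gene with
  probability `frac_targeted` (elsewhere uniformly), and synthesize
  point-read coverage as normal piles around each summit plus uniform
  background.

Not emulated: image-level data and segmentation, sequencing reads and
alignment, batch structure beyond additive plate offsets, correlated
gene-gene expression noise, isoforms/overlapping transcription, and
mapping artifacts. Passing tests therefore demonstrate that the analysis
recovers planted structure under these idealized noise models — they bound
implementation correctness, not performance on any particular real
dataset.

## Numerical conventions and degenerate inputs

* Sample SD (ddof = 1) everywhere a Z-score is formed; group moments are
  verified to 1e-9 and Z-scoring is idempotent at that tolerance.
* Strict inequalities at both decision thresholds (`padj < α`,
  `r > threshold`), matching how such cutoffs are conventionally printed.
* Negative correlations never form network edges by default (the analysis
  filters for the *highest* similarity scores); `use_absolute=True` is
  available where anticorrelation is of interest.
* Constant rows/profiles/columns: raised or excluded **by name**, never
  silent NaN.
* Empty significant sets report absent (`None`) fractions, not zeros.
* Undirected edges are stored in lexicographic (a < b) canonical order and
  all exports are deterministically ordered, so reruns are byte-identical.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives all stage seeds from the single config seed.

## Problem sizes

The test suite exercises the planted-module network recovery at the full
study scale (30 knockdowns × 27 features × 4 replicates; 2000 genes × 93
samples) over 100 seeds, DE calibration over 50 seeds, and interval/tail
oracle equivalence exhaustively for universes N ≤ 15 and 1000-interval
sets over 20 seeds. `scripts/acceptance.py` re-runs the same computations
at 25–50 seeds per quantity, which is ample for the rates it reports.

## Known limitations

* The DE engine assumes approximate normality of log2-CPM within groups;
  it is calibrated on NB data at moderate expression but is not a
  replacement for count-model inference at very low counts.
* The hypergeometric model treats gene sets as exchangeable draws from the
  universe; real DE sets are correlated with expression level, so fold
  enrichments against a naive universe can be inflated — choosing the
  universe (all *tested* genes, not all annotated genes) is the user's
  main lever.
* Symbol joins are only as good as the annotations; the interval join
  depends on the promoter window definition, which is a free parameter.
* BAM/bigWig binary formats are out of scope; coverage is accepted as
  bedGraph or read positions.
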