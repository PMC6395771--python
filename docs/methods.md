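# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Study design being modelled

The pipeline targets a two-group bulk RNA-seq comparison with small,
unequal groups (the motivating design has 6 cases and 8 controls per brain
region, with three striatal regions analyzed independently).  Each region's
analysis runs the same chain: expression filtering and normalization,
hidden-covariate estimation, negative-binomial differential expression,
control-network construction, module preservation against the case data,
hub conservation in the least preserved module, and gene-set enrichment.
Cross-region steps (DEG overlap, log2FC direction concordance) run
afterwards on the per-region results.

## Synthetic data generator

Counts are negative binomial with variance `mu + alpha*mu^2`, sampled as a
gamma–Poisson mixture (`alpha = 0` degenerates to Poisson).  The log-mean
of gene *g* in sample *s* is assembled on the natural-log scale:

```
log mu_gs = baseline_g + a_m * f_ms + deg_g * 1[s is case]
            + b_g,batch(s) + log(L_s / L_ref)
```

- `baseline_g` ~ Uniform(base_mean_log_range), default (3.0, 7.5) in
  natural-log units, i.e. mean counts of roughly 20–1800 at the reference
  library size.  This covers the bulk of a filtered bulk-RNA-seq dynamic
  range without extreme-count genes dominating.
- `f_ms` is a standard-normal per-sample factor shared by all genes of
  module *m*; the loading `a_m ∈ [0,1)` tunes within-module correlation
  (population log-scale correlation ≈ `a² / (a² + alpha + 1/mu)`).
- Planted DEGs shift case means by `±deg_log2fc` (log2 units, half up and
  half down).  DEGs are drawn from genes *outside* the disrupted module so
  that the disrupted module's marginal means stay group-invariant — the
  disruption is connectivity-only by construction.
- `b_g,batch` ~ N(0, batch_effect_sd) per gene and batch level
  (`batch_effect_sd` in log2 units, converted internally); batches are
  assigned round-robin.  Default 0 — batch structure is opt-in.
- Library sizes are log-uniform over `library_size_range` (default 5–15
  million, bulk scale); `L_ref` is the geometric mean of the range.
- `dispersion` defaults to 0.05, a mid-range biological dispersion for
  bulk tissue; the mean–variance relation is verified empirically in the
  test suite.

Under `break_correlation`, case samples of the disrupted module receive
i.i.d. per-gene factors instead of the shared one: marginal laws are
untouched (same loading, same variance), only co-variation is destroyed.
`attenuate` halves the loading in cases instead.  Sexes are a shuffled
balanced vector so that sex is not confounded with group or batch.  All
randomness flows from a single seed; outputs are byte-reproducible.

What the generator does **not** emulate: read-level sampling (FASTQ),
isoforms, unannotated transcription, gene length effects, GC/batch
interactions, outlier samples, and correlated module factors.  Passing
recovery tests on this generator therefore demonstrates the statistical
machinery under its stated assumptions, not robustness to every artifact
of real tissue data.

## Preprocessing

Genes are kept when CPM ≥ 0.3 in at least 50% of the samples of either
group (boundary inclusive).  Normalized expression is
`log2(CPM + 0.5)` after median-of-ratios size-factor scaling — a
variance-stabilized log scale that preserves what the correlation network
needs; it stands in for regularized-log transforms whose empirical-Bayes
shrinkage is implementation-defined.

Surrogate variables are the right singular vectors of the expression
residual after regressing out the known design (group plus adjustment
variables).  The number of components is chosen by permutation parallel
analysis: each gene's residuals are permuted independently (20 draws),
the permuted matrix re-residualized, and component *i* is retained while
its **variance proportion** exceeds the null 95th percentile (raw singular
values are not comparable because re-residualization removes mass from
every component; the proportion scale fixes this).  This two-step
estimator captures what the downstream model needs — recovery of
unmodelled structure such as a batch shift — without iterative
reweighting.

Sample weights summarize per-sample residual variance about the fitted
gene-wise means (leverage-adjusted mean squared residual, inverted and
normalized to geometric mean 1).  They are diagnostics — compared between
designs with and without surrogate variables via the two-sample
Kolmogorov–Smirnov test — and do not enter the DE fit.

## Differential expression

Dispersions are method-of-moments estimates on normalized counts,
`max(0, (s² − mu)/mu²)`, shrunk 50/50 toward a fitted `a0 + a1/mu` trend.
This fixed-blend shrinkage is deliberately simpler than empirical-Bayes
MAP estimation; the contracts it must satisfy (type-I error within
[0.03, 0.07] at n = 20/20, ≥ 90% sensitivity at |log2FC| = 2) are tested
directly.  The GLM is fitted by iteratively reweighted least squares with
the design matrix shared across genes (vectorized over genes), Fisher
weights `mu/(1 + alpha*mu)`, size factors as offsets, and a convergence
tolerance of 1e-8 with a 50-iteration cap; non-converged or all-zero genes
are flagged and reported with p = 1, excluded from DEG sets.  Standard
errors come from the inverse Fisher information; the group coefficient is
reported as log2(case/control).  Multiple testing uses Benjamini–Hochberg
(the conventional default where the adjustment method is not otherwise
specified); one shared implementation serves both the DE and enrichment
modules.

## Coexpression network

The scale-free fit index discretizes connectivity into 10 equal-width
bins and regresses log10(bin frequency) on log10(mean bin connectivity);
the index is R² signed by the slope, so an *increasing* degree
distribution cannot satisfy the criterion.  The chosen power is the
smallest with index ≥ 0.8, falling back to the argmax with a warning.

The network is unsigned (`|cor|^β`).  TOM follows the standard
similarity; clustering is average linkage on `1 − TOM`.  The static cut
sweeps 200 evenly spaced heights downward from 0.99 of the maximal merge
height and keeps the largest height whose clusters of size ≥ `min_size`
cover the most genes; sub-threshold clusters become unassigned (label 0),
and modules are numbered by decreasing size.  This rule is deterministic
and reproducible, at a cost documented under Limitations: average-linkage
chaining lets background genes accrete onto module cores, so detected
modules are supersets of the planted ones.

Module eigengenes are first right singular vectors of the gene-standardized
module submatrix, sign-oriented so the mean member kME is non-negative;
variance explained is reported.  kME is the Pearson correlation of each
gene with each eigengene.

## Module preservation

Observed statistics per module: density on the test data (mean within-
module correlation, mean adjacency at β, eigengene variance explained,
mean signed kME) and connectivity between reference and test (correlation
of intramodular connectivities, of kME vectors, and of the vectorized
within-module correlation matrices).  The permutation null redraws random
gene sets of the module's size from the analysis universe (not label
shuffles), recomputing all statistics; `Z = (obs − mean)/sd` per
statistic.  `Zsummary` is the mean of the median density Z and the median
connectivity Z; `medianRank` is the median across statistics of the
module's rank, rank 1 being the most preserved per statistic (average
ranks on ties), so the least preserved module has the highest medianRank.
Zero permutation sd yields a signed-infinity flag excluded from medians.
The module kME correlation (control vs case, own-module kME over module
genes) uses the standard correlation t-test for its p-value.

Selection: if the highest-medianRank module is also the lowest-Zsummary
module, it is returned directly; otherwise the union of the three least
preserved modules under each criterion forms the candidate pool (the
permissive reading of the tie-break) and the candidate with |kME
correlation| closest to zero wins.  A rationale record logs both
criteria, the candidates and their correlations.

Calibration of the Z scale is checked against the planted modules at the
standard recovery design (2000 genes; modules 100/150/200 at loading 0.8;
the size-150 module disrupted; n = 20/20; β = 6; minimum module size 30;
100 permutations): intact planted modules exceed Zsummary 10 and the
disrupted one falls below 2 in 10/10 evaluation seeds, and the full chain
(including module detection) returns the disrupted module in 19/20 seeds.
These problem sizes keep the studies to a few minutes on one CPU while
leaving the per-seed statistics stable.

## Hubs

A hub is a module gene whose expression correlates with the module
eigengene at |r| ≥ 0.9 (i.e. |kME| ≥ 0.9) — the kME reading of the hub
definition; correlating a gene's expression with a kME *vector over
genes* is dimensionally incoherent and is not implemented.  The case-side
eigengene is recomputed on case data for the mapped module, so hub loss
reflects case connectivity rather than a projection of control structure.

## Enrichment

ORA uses the hypergeometric upper tail with the analysis universe as
background and BH across sets (enriched at FDR ≤ 0.05).  The
randomization test draws query-sized gene sets uniformly without
replacement and reports `(1 + #{overlap ≥ observed}) / (n_iter + 1)`, a
valid permutation p that is never zero (significance read at p ≤ 0.05).
Gene identifiers are harmonized by case-folding and stripping trailing
version suffixes; no ortholog mapping is performed.  The GWAS gene filter
keeps genes with association p strictly below 10⁻⁵.  Direction
concordance counts shared genes with equal log2FC signs; zero fold
changes count as neither direction and are reported separately.

## Degenerate inputs and tie-breaks

Zero contingency cells: Haldane–Anscombe +0.5 on all cells, flagged.
Values at the grand median in the median test side with "≤".  Zero-variance
genes: correlation/kME 0 with a flag, excluded from hub calls.  All-zero
genes: dispersion 0, DE p = 1, flagged.  Zero library sizes, empty groups,
rank-deficient designs, disjoint gene universes: errors naming the
offender.  Cluster ties in the static cut resolve toward the larger
height; rank ties average.

## Limitations

- Module detection under the static height cut admits background genes
  into module clusters (and can fold a planted module into a larger
  cluster); dynamic tree cutting would sharpen boundaries at the cost of
  determinism guarantees kept here.
- The dispersion and surrogate-variable estimators are intentionally
  simple; they meet the stated calibration contracts but are not drop-in
  replacements for empirical-Bayes machinery on real data.
- Sample weights are per-sample summaries, not observation-level
  precision weights, and serve only the distributional diagnostics.
- The synthetic generator's independence and normality assumptions are
  stated above; conclusions about real striatal tissue require the real
  count data.
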