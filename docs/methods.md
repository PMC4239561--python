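# Methods

## Model and procedure

`fracres` analyses duplicate-gene retention after a whole-genome doubling
(WGD) at the level of *homology sets*: the surviving copies of one
ancestral gene across S surveyed species, as produced by an upstream
syntenic comparison (set construction itself is out of scope; the package
consumes a tab-separated table of per-species gene lists).

**Fractionation resistance.** F = N + 1 with N the number of species
retaining at least `duplicate_threshold` copies. The threshold defaults
to 2 ("still in duplicate") and is configurable because a genome
descending from a triplication can retain 3 copies; with the default, 2
and 3 retained copies count the same. A species with no surviving copy is
legal and simply contributes 0 to N. Range: 1 to S + 1.

**GO propagation.** Terms are loaded from OBO 1.2 (obsolete terms
dropped). Only `is_a` and `part_of` edges propagate, following standard
true-path practice; regulatory relations and cross-namespace parent links
are discarded. Annotation closure is reflexive (a hit term counts itself)
and proceeds in two steps: each direct gene hit is closed over its
ancestors, and a homology set takes the union over member genes; member
genes then inherit the set-level terms for gene-level analyses. The
closure is idempotent by construction. "Top-level categories" are the
depth-1 children of each namespace root -- the mutually exclusive classes
used for enrichment; with a full GO release these are the familiar
headline terms (metabolic process, response to stimulus, membrane, ...).
Sets with no annotation in a namespace are excluded from that namespace's
analyses rather than zero-filled.

**Enrichment.** Hit(F, C) counts sets (not genes -- a set counts once per
category however many members hit it), and P(F, C) normalizes over all
top-level categories of the namespace within each F stratum, so the
scarce high-F strata can be compared with the dominant F = 1 stratum.
Strata with zero annotated sets are reported missing, not zero.

**Expression.** Per gene the pipeline uses the *maximum* RPKM over
conditions (tissue-restricted genes would be misrepresented by means or
medians). Genes in the top `filter_percent` (default 1%) of maxima are
removed globally, once per dataset, before every expression analysis; the
percentile is nearest-rank with removal only *strictly above* the
threshold, so full ties remove nothing, and the filter degrades to a
no-op (with a warning) below 100/percent genes. Log transform is
log10(RPKM + 1); the pseudocount keeps unexpressed genes finite and in
the lowest bin. Bins default to 8 equal-width intervals over the observed
log range (half-open, last bin closed); the count and edges are
configurable since no canonical binning exists for these data.
E(F, C) is the plain mean of *unlogged* post-filter maxima; the log scale
is used only for binning and the trend regression (both choices
switchable in code).

**Trend tests.** Classification of a category as fractionation
resistant/prone is by the sign of a significant regression slope at
`alpha` (default 0.05, raw p-values; a Benjamini-Hochberg helper exists
but is off by default, matching the per-category reporting convention of
comparable analyses):

* functional trend -- OLS of the 0/1 set-level membership indicator on F,
  over all sets annotated in the namespace (observations = sets, which
  are independent);
* expression trend -- OLS of log10(max RPKM + 1) on F over all post-filter
  genes, with **cluster-robust standard errors grouped by homology set**.
  Genes of one set share F exactly and (in both real and simulated data)
  most of their expression signal; naive OLS treats them as independent
  and over-rejects badly under the null (~30% at nominal 5% in
  simulation), while the clustered variant is calibrated (~5-7% across
  500+ null replicates). The slope estimate is the ordinary OLS slope
  either way. The small residual anticonservativeness traces to the few
  high-leverage maximum-F clusters.

Degenerate inputs (constant regressor or response, fewer than 3
observations) return a not-significant result with p = 1 rather than an
error. Regressions are unweighted; missing strata are dropped, never
imputed.

## The synthetic-data generator

The simulator emulates the study design the analysis expects: S species
(default 3, one lineage of a WGD), every set starting at copy count 2 per
species, category- and expression-dependent independent loss per species.
Per set: 1-3 leaf terms drawn uniformly from a deterministic toy GO DAG
(3 namespaces x 4 top-level categories x 1 intermediate x 2 leaves, one
part_of diamond per category); a latent expression level
e ~ LogNormal(meanlog 2.3, sdlog 1.5) (median ~10 RPKM, heavy right tail,
RPKM-like); per-species duplicate retention Bernoulli with log-odds
alpha_0 + sum of the set's category effects + beta*log10(e + 1)
(defaults alpha_0 = -1, all alpha_C = 0, beta = 0, i.e. ~27% retention
and a neutral null); per-tissue RPKM = e * exp(N(0, 0.5)) over 6 tissues.
All randomness flows from one integer seed; emitted files round-trip
bit-identically through the package's readers.

What the generator does **not** emulate: realistic GO topology and
annotation sparsity, more than one WGD round (re-run the generator on its
own output to stack events), between-species expression divergence
(one latent level per set), mappability/length biases of real RNA-seq,
and correlated gene loss along chromosomal segments. Passing tests
therefore demonstrate correctness and calibration of the *statistics*
under the stated generative model, not biological conclusions about any
real lineage.

`recover_effects` refits the exact generative logistic model (retention
per set x species on category indicators + log10(latent + 1)) using the
ground-truth latent expression from the cohort's `truth.tsv`. It is the
quantitative companion to the pipeline's directional trend tests: the
trend regressions establish sign and significance from observed data; the
logistic refit checks that alpha_C and beta are recovered within
asymptotic standard errors (~95% coverage at 2 SE in simulation).

## Numerical and design choices

* Nearest-rank percentile (no interpolation) for the expression filter:
  deterministic and tie-safe.
* Bin assignment by `searchsorted` on explicit edges; a value equal to
  the last edge joins the last bin; values outside the edges raise (edges
  are built from the data, so an excursion indicates a pipeline bug).
* Hit tables and all output tables are emitted in sorted deterministic
  order with fixed float formatting (`%.10g`), so identical config +
  inputs reproduce identical bytes; the run manifest records parameters,
  seed and SHA-256 checksums of inputs and outputs.
* Degenerate log-range (all genes equal) widens the bin span by 1 rather
  than failing.
* Simulation scale in the test and acceptance suites is 2000 sets x 3
  species (and 100-500 replicates for calibration/recovery checks),
  chosen as the package's own desk-scale study size: large enough that
  the planted +-1 log-odds and beta = 0.8 effects are detected with high
  power while whole suites complete in minutes.

## Known limitations

* Top-level categories are the literal depth-1 children of each namespace
  root; with a real GO release this approximates, but is not identical
  to, curated GO-slim sets.
* The expression trend's clustered inference assumes many clusters; with
  few homology sets (tens) its p-values become unreliable.
* Cross-dataset absolute expression comparisons are intentionally
  unsupported (platform/depth differences make them invalid); only
  within-dataset normalized comparisons are produced.
* The functional and expression trends are marginal regressions; the
  package does not fit a joint multi-feature retention model to real
  data (the logistic refit applies only to synthetic cohorts, where the
  latent expression is known).
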