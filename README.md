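# fracres

Fractionation resistance of duplicate genes after whole-genome doubling
(WGD): how a gene's functional category and its expression level each
predict whether its WGD duplicates survive or are lost again.

## The problem

After a whole-genome doubling or tripling, every gene is duplicated, and
most duplicates are subsequently lost -- *fractionation*. Loss is not
random: in plants, some Gene Ontology classes (e.g. response to stimulus,
biological regulation) resist fractionation while others (metabolic
process, catalytic activity) are prone to it, and more highly expressed
genes tend to keep their duplicates. `fracres` implements the comparative
analysis that quantifies both effects jointly, for anyone with
(i) cross-species homology sets from a syntenic comparison,
(ii) a GO ontology and per-gene annotations, and (iii) an RPKM expression
matrix -- or for nobody's data at all, via a built-in generative simulator.

## The statistics

For each homology set (the surviving copies of one ancestral gene across
S species), the **fractionation resistance** is

    F = N + 1,

where N is the number of species still carrying the set in duplicate
(&ge; 2 copies); a set returned to singleton everywhere has F = 1, and
1 &le; F &le; S + 1. Functional enrichment compares the mutually exclusive
top-level GO categories C of each namespace through normalized
proportions over sets at each resistance level,

    P(F, C) = Hit(F, C) / Σ_C' Hit(F, C'),

where Hit(F, C) counts sets of level F annotated (after true-path and
across-set propagation) with C. A category is **fractionation resistant**
if P(F, C) rises with F and **prone** if it falls; significance comes from
an OLS regression of the per-set membership indicator on F over all
annotated sets, not the few summary points. Expression enters as the
per-gene maximum RPKM over tissues, with the top 1% of genes removed;
per stratum the pipeline reports the plain mean E(F, C) and the
log10(RPKM+1) bin distribution P_B(F), and tests the trend by OLS of
log-expression on F over all genes (standard errors clustered by homology
set, since member genes share F and expression).

The simulator draws homology sets whose per-species duplicate retention is
Bernoulli with log-odds `alpha_0 + Σ_C alpha_C + beta * log10(e + 1)`,
`e` a log-normal latent expression level shared by the set's genes, so
known category effects (alpha_C) and an expression effect (beta) can be
planted and recovered end to end.

## Worked example

`examples/04_trend_analysis.py` plants alpha = +1 on one category,
alpha = -1 on another and beta = 0.8, then runs the package's regressions
(2000 sets, 3 species, seed 7):

```
functional trends (membership-on-F regression over all sets):
  biological_process class 1: slope=+0.1867, p=4.3e-42, verdict=resistant (true alpha=+1.0)
  biological_process class 2: slope=-0.1492, p=2.5e-30, verdict=prone (true alpha=-1.0)
  biological_process class 3: slope=-0.0078, p=0.59, verdict=not_significant (true alpha=+0.0)

expression trend (log RPKM on F over 8777 genes): slope=+0.1942, p=1.3e-49, verdict=resistant
logistic refit of the retention model: beta = 0.833 +/- 0.050 (true 0.8)
```

The two perturbed categories are classified correctly with p-values many
orders of magnitude below 0.05, the neutral category is not significant,
mean expression rises with F, and the logistic refit recovers the planted
beta within one standard error. The other examples cover F scoring, GO
propagation, expression filtering/binning, and the full pipeline
(`fracres simulate | run | report` from a shell, or
`examples/05_full_pipeline.py` from Python), which writes
`category_profiles.tsv`, `expression_profiles.tsv`, `trend_results.tsv`
and a `manifest.json` of parameters and checksums.

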