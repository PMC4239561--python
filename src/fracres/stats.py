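"""Summary statistics and trend tests for fractionation resistance.

Three quantities summarize a cohort, per GO namespace:

* ``Hit(F, C)`` -- the number of homology sets at fractionation level F
  annotated with top-level category C (a set counts at most once per
  category, however many member genes hit it);
* ``P(F, C) = Hit(F, C) / sum_C' Hit(F, C')`` -- proportions normalized
  over all top-level categories of the namespace, so scarce high-F strata
  can be compared fairly with the abundant F = 1 stratum;
* ``E(F, C)`` -- the plain average (unlogged, post-filter) per-gene maximum
  RPKM in stratum (F, C), together with ``P_B(F)``, the share of the
  stratum's genes in each log-expression bin B.

A category is called *fractionation resistant* when P(F, C) rises with F
and *prone* when it falls.  Significance comes from per-observation
regressions, not from the few plotted summary points: category membership
(0/1) on F over all annotated sets for the functional trend, and
log-expression on F over all genes for the expression trend.  Because all
genes of a homology set share one F (and, in data like ours, strongly
correlated expression), the expression regression uses cluster-robust
standard errors grouped by homology set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .expression import BinScheme
from .go_annotation import AnnotationMap, GoDag
from .homology import GeneRecord, HomologySet

__all__ = [
    "CategoryProfile",
    "ExpressionProfile",
    "TrendResult",
    "hit_counts",
    "hit_table",
    "normalized_proportions",
    "category_profiles",
    "gene_table",
    "expression_profile",
    "functional_trend_test",
    "expression_trend_test",
    "adjust_benjamini_hochberg",
]

ALL_GENES = "all_genes"


@dataclass
class CategoryProfile:
    """Hit counts and normalized proportions of one top-level category."""

    namespace: str
    category: str
    hits: dict[int, int]
    proportions: dict[int, float]


@dataclass
class ExpressionProfile:
    """Mean expression E(F, C) and bin shares P_B(F) for one category."""

    category: str  # top-level term id or "all_genes"
    mean_by_F: dict[int, float]
    bin_props_by_F: dict[int, np.ndarray]
    n_by_F: dict[int, int]


@dataclass
class TrendResult:
    """Slope of a trend-on-F regression and its classification.

    verdict is ``resistant`` for a significantly positive slope, ``prone``
    for a significantly negative one, else ``not_significant``.
    """

    category: str
    slope: float
    p_value: float
    n: int
    verdict: str

    @staticmethod
    def classify(slope: float, p_value: float, alpha: float) -> str:
        if p_value < alpha and slope > 0:
            return "resistant"
        if p_value < alpha and slope < 0:
            return "prone"
        return "not_significant"


def _annotated_sets(
    sets: Sequence[HomologySet], amap: AnnotationMap, dag: GoDag, namespace: str
) -> list[HomologySet]:
    """Sets annotated in the namespace (propagation witnesses the root)."""
    out = []
    for hs in sets:
        if hs.F is None:
            raise ValueError(f"set {hs.set_id} has no F; run compute_all_F first")
        if amap.is_annotated(hs.set_id, dag, namespace):
            out.append(hs)
    return out


def hit_counts(
    sets: Sequence[HomologySet],
    amap: AnnotationMap,
    dag: GoDag,
    category: str,
) -> dict[int, int]:
    """Hit(F, C): sets per fractionation level annotated with ``category``.

    Set-level and deduplicated: a set contributes at most 1 per category.
    Only sets annotated in the category's namespace are considered.
    """
    if category not in dag:
        raise KeyError(f"unknown category {category}")
    namespace = dag.terms[category].namespace
    counts: dict[int, int] = {}
    for hs in _annotated_sets(sets, amap, dag, namespace):
        if category in amap.set_terms(hs.set_id):
            counts[hs.F] = counts.get(hs.F, 0) + 1
    return counts


def hit_table(
    sets: Sequence[HomologySet],
    amap: AnnotationMap,
    dag: GoDag,
    namespace: str,
) -> pd.DataFrame:
    """Hit(F, C) for every top-level category of a namespace.

    Rows are the F strata observed among annotated sets, columns the
    namespace's top-level categories (sorted by term id).
    """
    categories = dag.top_level_categories(namespace)
    annotated = _annotated_sets(sets, amap, dag, namespace)
    strata = sorted({hs.F for hs in annotated})
    table = pd.DataFrame(0, index=strata, columns=categories, dtype=int)
    for hs in annotated:
        terms = amap.set_terms(hs.set_id)
        for cat in categories:
            if cat in terms:
                table.at[hs.F, cat] += 1
    table.index.name = "F"
    return table


def normalized_proportions(hit_df: pd.DataFrame) -> pd.DataFrame:
    """P(F, C) = Hit(F, C) / sum over the namespace's categories at F.

    Strata whose total is zero are returned as NaN (missing, not zero).
    """
    totals = hit_df.sum(axis=1).astype(float)
    props = hit_df.div(totals.where(totals > 0), axis=0)
    return props


def category_profiles(
    hit_df: pd.DataFrame, namespace: str
) -> list[CategoryProfile]:
    """Package a hit table and its proportions into per-category profiles."""
    props = normalized_proportions(hit_df)
    return [
        CategoryProfile(
            namespace=namespace,
            category=cat,
            hits={int(f): int(hit_df.at[f, cat]) for f in hit_df.index},
            proportions={
                int(f): float(props.at[f, cat])
                for f in props.index
                if np.isfinite(props.at[f, cat])
            },
        )
        for cat in hit_df.columns
    ]


def gene_table(
    records: Iterable[GeneRecord],
    sets_by_id: Mapping[str, HomologySet],
    per_gene_max: pd.Series,
    retained: pd.Index | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Gene-level analysis frame: F, max RPKM and log10(max + pc) per gene.

    ``retained`` (from the top-percentile filter) restricts the genes; genes
    without an expression value are dropped.  Genes inherit F from their
    homology set.
    """
    keep = set(per_gene_max.index if retained is None else retained)
    rows = [
        (r.gene_id, r.set_id, r.species_id, sets_by_id[r.set_id].F)
        for r in records
        if r.gene_id in keep
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "set_id", "species_id", "F"])
    df["max_rpkm"] = per_gene_max.reindex(df["gene_id"]).to_numpy()
    df["log_max"] = np.log10(df["max_rpkm"] + pseudocount)
    return df


def expression_profile(
    gene_df: pd.DataFrame,
    scheme: BinScheme,
    category: str | None = None,
    amap: AnnotationMap | None = None,
) -> ExpressionProfile:
    """E(F, C) and P_B(F) over a gene table.

    ``category=None`` profiles all genes; otherwise only genes whose
    homology set is annotated with the category (which requires ``amap``).
    Empty strata are simply absent (missing, never zero-filled).
    """
    if category is not None:
        if amap is None:
            raise ValueError("category filter requires an AnnotationMap")
        in_cat = gene_df["set_id"].map(lambda s: category in amap.set_terms(s))
        gene_df = gene_df[in_cat]
    mean_by_F: dict[int, float] = {}
    bin_props: dict[int, np.ndarray] = {}
    n_by_F: dict[int, int] = {}
    for f, grp in gene_df.groupby("F", sort=True):
        f = int(f)
        mean_by_F[f] = float(grp["max_rpkm"].mean())
        counts = np.bincount(
            scheme.assign(grp["log_max"].to_numpy()), minlength=scheme.n_bins
        )
        bin_props[f] = counts / counts.sum()
        n_by_F[f] = len(grp)
    return ExpressionProfile(
        category=category if category is not None else ALL_GENES,
        mean_by_F=mean_by_F,
        bin_props_by_F=bin_props,
        n_by_F=n_by_F,
    )


def _degenerate(category: str, n: int) -> TrendResult:
    return TrendResult(
        category=category, slope=0.0, p_value=1.0, n=n, verdict="not_significant"
    )


def functional_trend_test(
    sets: Sequence[HomologySet],
    amap: AnnotationMap,
    dag: GoDag,
    category: str,
    alpha: float = 0.05,
) -> TrendResult:
    """Is category membership associated with fractionation resistance?

    Ordinary least squares of the 0/1 category-membership indicator on F
    over *all* sets annotated in the category's namespace; two-sided slope
    p-value.  A positive significant slope marks the category fractionation
    resistant, a negative one prone.
    """
    if category not in dag:
        raise KeyError(f"unknown category {category}")
    namespace = dag.terms[category].namespace
    annotated = _annotated_sets(sets, amap, dag, namespace)
    x = np.array([hs.F for hs in annotated], dtype=float)
    y = np.array(
        [category in amap.set_terms(hs.set_id) for hs in annotated], dtype=float
    )
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return _degenerate(category, len(x))
    fit = sps.linregress(x, y)
    return TrendResult(
        category=category,
        slope=float(fit.slope),
        p_value=float(fit.pvalue),
        n=len(x),
        verdict=TrendResult.classify(fit.slope, fit.pvalue, alpha),
    )


def expression_trend_test(
    gene_df: pd.DataFrame,
    category: str | None = None,
    amap: AnnotationMap | None = None,
    alpha: float = 0.05,
) -> TrendResult:
    """Does gene expression rise with fractionation resistance?

    OLS of log10(max RPKM + pc) on F over all (post-filter) genes in the
    category, with standard errors clustered by homology set: member genes
    of one set share F and typically expression, so treating them as
    independent would overstate significance.
    """
    label = category if category is not None else ALL_GENES
    if category is not None:
        if amap is None:
            raise ValueError("category filter requires an AnnotationMap")
        in_cat = gene_df["set_id"].map(lambda s: category in amap.set_terms(s))
        gene_df = gene_df[in_cat]
    x = gene_df["F"].to_numpy(dtype=float)
    y = gene_df["log_max"].to_numpy(dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return _degenerate(label, len(x))
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": gene_df["set_id"].to_numpy()}
    )
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    return TrendResult(
        category=label,
        slope=slope,
        p_value=p,
        n=len(x),
        verdict=TrendResult.classify(slope, p, alpha),
    )


def adjust_benjamini_hochberg(
    results: Sequence[TrendResult], alpha: float = 0.05
) -> list[TrendResult]:
    """Optional FDR control across categories (off by default upstream).

    Returns new results with BH-adjusted p-values and re-derived verdicts.
    """
    if not results:
        return []
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    return [
        TrendResult(
            category=r.category,
            slope=r.slope,
            p_value=float(p),
            n=r.n,
            verdict=TrendResult.classify(r.slope, p, alpha),
        )
        for r, p in zip(results, p_adj)
    ]
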