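"""End-to-end orchestration: inputs (real or simulated) -> tidy result tables.

A run reads the four inputs (homology-set TSV, OBO ontology, gene-annotation
TSV, RPKM expression TSV) -- or generates them synthetically -- then scores
fractionation resistance, propagates GO annotation, filters and bins
expression, and writes three tidy tables plus a machine-readable manifest:

* ``category_profiles.tsv``   -- namespace, category, F, Hit(F,C), P(F,C)
* ``expression_profiles.tsv`` -- category (or all_genes), F, n, E(F,C), P_B(F)
* ``trend_results.tsv``       -- per-category trend slopes, p-values, verdicts
* ``manifest.json``           -- parameters, seed, input/output checksums

Identical config and inputs reproduce every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import BinScheme, filter_top_percent, read_expression
from .go_annotation import NAMESPACES, annotate_sets, load_obo, read_gene_annotations
from .homology import compute_all_F, gene_index, read_homology_sets
from .simulate import DagSpec, SimulationConfig, simulate
from . import stats as fstats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report"]

OUTPUT_FILES = (
    "category_profiles.tsv",
    "expression_profiles.tsv",
    "trend_results.tsv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one run needs; exactly one of file inputs or a
    simulation block must be provided."""

    outdir: str | Path = "fracres_run"
    seed: int = 0
    homology: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    expression: str | None = None
    simulation: SimulationConfig | None = None
    duplicate_threshold: int = 2
    filter_percent: float = 1.0
    n_bins: int = 8
    pseudocount: float = 1.0
    alpha: float = 0.05

    def validate(self) -> None:
        file_inputs = [self.homology, self.ontology, self.annotations, self.expression]
        have_files = all(p is not None for p in file_inputs)
        some_files = any(p is not None for p in file_inputs)
        if self.simulation is not None and some_files:
            raise ValueError("give either input paths or a simulation block, not both")
        if self.simulation is None and not have_files:
            missing = [
                name
                for name, p in zip(
                    ("homology", "ontology", "annotations", "expression"), file_inputs
                )
                if p is None
            ]
            raise ValueError(f"missing input path(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            dag_spec = DagSpec(**sim.pop("dag_spec", {}))
            sim = SimulationConfig(dag_spec=dag_spec, **sim)
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@contextmanager
def _stage(name: str, created: list[Path]):
    """Tag failures with the stage name and drop partial outputs."""
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the result tables; returns the outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    with _stage("inputs", created):
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate(sim_cfg, out_dir=outdir / "inputs")
            paths = cohort.paths
            input_paths = {
                "homology": paths["homology"],
                "ontology": paths["ontology"],
                "annotations": paths["annotations"],
                "expression": paths["expression"],
            }
        else:
            input_paths = {
                "homology": Path(config.homology),
                "ontology": Path(config.ontology),
                "annotations": Path(config.annotations),
                "expression": Path(config.expression),
            }
            for name, p in input_paths.items():
                if not p.is_file():
                    raise FileNotFoundError(f"{name} input not found: {p}")

    with _stage("homology", created):
        sets = read_homology_sets(input_paths["homology"])
        compute_all_F(sets, config.duplicate_threshold)
        sets_by_id = {hs.set_id: hs for hs in sets}
        records = gene_index(sets)

    with _stage("ontology", created):
        dag = load_obo(input_paths["ontology"])

    with _stage("annotation", created):
        gene_hits = read_gene_annotations(input_paths["annotations"])
        amap = annotate_sets(sets, gene_hits, dag)

    with _stage("expression", created):
        table = read_expression(input_paths["expression"])
        per_gene_max = table.per_gene_max
        retained, threshold = filter_top_percent(per_gene_max, config.filter_percent)
        gene_df = fstats.gene_table(
            records, sets_by_id, per_gene_max, retained, config.pseudocount
        )
        scheme = BinScheme.from_data(gene_df["log_max"].to_numpy(), config.n_bins)

    with _stage("statistics", created):
        cat_rows, trend_rows, expr_rows = [], [], []
        for ns in NAMESPACES:
            categories = dag.top_level_categories(ns)
            if not categories:
                continue
            hit_df = fstats.hit_table(sets, amap, dag, ns)
            props = fstats.normalized_proportions(hit_df)
            for cat in categories:
                for f in hit_df.index:
                    cat_rows.append(
                        {
                            "namespace": ns,
                            "category": cat,
                            "category_name": dag.terms[cat].name,
                            "F": int(f),
                            "hits": int(hit_df.at[f, cat]),
                            "P": props.at[f, cat],
                        }
                    )
                res = fstats.functional_trend_test(
                    sets, amap, dag, cat, config.alpha
                )
                trend_rows.append(
                    {
                        "test": "functional",
                        "namespace": ns,
                        "category": cat,
                        "category_name": dag.terms[cat].name,
                        "slope": res.slope,
                        "p_value": res.p_value,
                        "n": res.n,
                        "verdict": res.verdict,
                    }
                )

        profiles = [fstats.expression_profile(gene_df, scheme)]
        etests = [fstats.expression_trend_test(gene_df, alpha=config.alpha)]
        for ns in NAMESPACES:
            for cat in dag.top_level_categories(ns):
                profiles.append(
                    fstats.expression_profile(gene_df, scheme, cat, amap)
                )
                etests.append(
                    fstats.expression_trend_test(gene_df, cat, amap, config.alpha)
                )
        for prof in profiles:
            for f in sorted(prof.mean_by_F):
                row = {
                    "category": prof.category,
                    "F": f,
                    "n_genes": prof.n_by_F[f],
                    "E": prof.mean_by_F[f],
                }
                row.update(
                    {f"bin_{b}": prof.bin_props_by_F[f][b] for b in range(scheme.n_bins)}
                )
                expr_rows.append(row)
        for res in etests:
            trend_rows.append(
                {
                    "test": "expression",
                    "namespace": (
                        dag.terms[res.category].namespace
                        if res.category in dag.terms
                        else ""
                    ),
                    "category": res.category,
                    "category_name": (
                        dag.terms[res.category].name
                        if res.category in dag.terms
                        else fstats.ALL_GENES
                    ),
                    "slope": res.slope,
                    "p_value": res.p_value,
                    "n": res.n,
                    "verdict": res.verdict,
                }
            )

    with _stage("write-outputs", created):
        tables = {
            "category_profiles.tsv": pd.DataFrame(cat_rows),
            "expression_profiles.tsv": pd.DataFrame(expr_rows),
            "trend_results.tsv": pd.DataFrame(trend_rows),
        }
        for name, df in tables.items():
            path = outdir / name
            created.append(path)
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")

        manifest = {
            "fracres_version": __version__,
            "seed": config.seed,
            "parameters": {
                "duplicate_threshold": config.duplicate_threshold,
                "filter_percent": config.filter_percent,
                "filter_threshold_rpkm": threshold,
                "n_bins": config.n_bins,
                "bin_edges": list(scheme.edges),
                "pseudocount": config.pseudocount,
                "alpha": config.alpha,
                "simulation": (
                    dataclasses.asdict(
                        dataclasses.replace(config.simulation, seed=config.seed)
                    )
                    if config.simulation is not None
                    else None
                ),
            },
            "inputs": {k: _sha256(p) for k, p in sorted(input_paths.items())},
            "outputs": {name: _sha256(outdir / name) for name in tables},
        }
        manifest_path = outdir / "manifest.json"
        created.append(manifest_path)
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return outdir


def report(outdir: str | Path, plots: bool = False) -> str:
    """Human-readable summary of a finished run (never alters the tables).

    Lists gene counts per fractionation level, the categories classified
    resistant or prone by the functional trend, and the all-genes
    expression trend.  With ``plots=True`` writes P(F,C)-vs-F and E-vs-F
    figures beside the tables.
    """
    outdir = Path(outdir)
    for name in ("category_profiles.tsv", "expression_profiles.tsv", "trend_results.tsv"):
        if not (outdir / name).is_file():
            raise PipelineError("report", f"missing table {name} in {outdir}")
    trends = pd.read_csv(outdir / "trend_results.tsv", sep="\t")
    expr = pd.read_csv(outdir / "expression_profiles.tsv", sep="\t")

    lines = [f"fracres run summary: {outdir}"]
    all_genes = expr[expr["category"] == fstats.ALL_GENES]
    if len(all_genes):
        lines.append("genes per fractionation level (all genes):")
        for _, row in all_genes.iterrows():
            lines.append(
                f"  F={int(row['F'])}: n={int(row['n_genes'])}, "
                f"mean RPKM={row['E']:.2f}"
            )
    func = trends[trends["test"] == "functional"]
    for verdict in ("resistant", "prone"):
        cats = func.loc[func["verdict"] == verdict, "category_name"].tolist()
        lines.append(
            f"fractionation-{verdict} categories ({len(cats)}): "
            + (", ".join(cats) if cats else "none")
        )
    eall = trends[(trends["test"] == "expression") & (trends["category"] == fstats.ALL_GENES)]
    if len(eall):
        r = eall.iloc[0]
        lines.append(
            f"expression trend (all genes): slope={r['slope']:.4f}, "
            f"p={r['p_value']:.3g}, verdict={r['verdict']}"
        )
    lines.append(
        f"trend tests run: {len(func)} functional, "
        f"{int((trends['test'] == 'expression').sum())} expression"
    )
    summary = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(summary, encoding="utf-8")
    if plots:
        _write_plots(outdir, trends, expr)
    return summary


def _write_plots(outdir: Path, trends: pd.DataFrame, expr: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = pd.read_csv(outdir / "category_profiles.tsv", sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for (ns, cat), grp in cats.groupby(["namespace", "category"]):
        axes[0].plot(grp["F"], 100 * grp["P"], marker="o", label=grp["category_name"].iloc[0])
    axes[0].set_xlabel("fractionation resistance F")
    axes[0].set_ylabel("normalized proportion P(F,C) [%]")
    axes[0].legend(fontsize=5)
    for cat, grp in expr.groupby("category"):
        axes[1].plot(grp["F"], grp["E"], marker="o", label=cat)
    axes[1].set_xlabel("fractionation resistance F")
    axes[1].set_ylabel("mean max RPKM E(F,C)")
    axes[1].legend(fontsize=5)
    fig.tight_layout()
    fig.savefig(outdir / "profiles.png", dpi=120)
    plt.close(fig)
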