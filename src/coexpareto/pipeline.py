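"""End-to-end orchestration: data -> DE -> condition networks -> permutation
check -> differential networks -> Pareto genes -> annotation -> replication.

Every stage writes its intermediate as TSV under the output directory, and a
manifest records the configuration, the seed and content hashes of all
outputs, so a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import coexpression as cx
from . import diffcoex as dcx
from . import diffexpr as de
from . import essentiality as ess
from . import replication as rep
from . import synthetic as syn
from .study import CONDITIONS, ExpressionStudy, read_expression_tsv, \
    write_expression_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs: either a synthetic spec ("demo", or a YAML path), or TSV paths
    synthetic: str | None = "demo"
    expr: str | None = None
    meta: str | None = None
    replication_expr: str | None = None
    replication_meta: str | None = None
    gmt: tuple[str, ...] = ()
    fnet: str | None = None
    # analysis constants
    de_fdr: float = 0.05
    edge_alpha: float = 0.01
    permutations: int = 1000          # 0 skips the permutation check
    prob_threshold: float = 0.70
    pair_p_convention: str = "max"    # or "partial_only"
    pareto_network: str = "differential"  # or "full"
    seed: int = 0
    out_dir: str = "coexpareto_out"

    def __post_init__(self) -> None:
        for name in ("de_fdr", "edge_alpha", "prob_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")
        if self.pair_p_convention not in cx.PAIR_P_CONVENTIONS:
            raise ValueError(f"unknown pair_p_convention {self.pair_p_convention!r}")
        if self.pareto_network not in ("differential", "full"):
            raise ValueError(f"pareto_network must be differential|full")
        if self.synthetic is None and (self.expr is None or self.meta is None):
            raise ValueError("need either a synthetic spec or expr+meta paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "gmt" in raw and raw["gmt"] is not None:
            raw["gmt"] = tuple(raw["gmt"]) if not isinstance(raw["gmt"], str) \
                else (raw["gmt"],)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_study(config: PipelineConfig, out: Path) -> tuple[ExpressionStudy,
                                                            syn.SyntheticTruth | None]:
    if config.expr is not None:
        return read_expression_tsv(config.expr, config.meta), None
    if config.synthetic == "demo":
        spec = syn.demo_spec(seed=config.seed)
    else:
        spec = syn.spec_from_yaml(config.synthetic)
        spec.seed = config.seed
        spec.validate()
    study, truth = syn.simulate(spec)
    write_expression_tsv(study, out / "expression.tsv", out / "samples.tsv")
    syn.write_truth_tsv(spec, truth, out / "truth_edges.tsv")
    return study, truth


def _analysis_universe(study: ExpressionStudy, de_genes: set[str]) -> list[str]:
    """DE genes that are non-constant in both conditions (network-eligible)."""
    keep = []
    for g in study.genes:
        if g not in de_genes:
            continue
        if all(study.subset(c).loc[g].std() > 0 for c in CONDITIONS):
            keep.append(g)
    return keep


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        study, _ = _load_study(config, out)

        _stage("differential expression")
        de_table = de.run_de(study, fdr=config.de_fdr)
        de_table.to_csv(out / "de.tsv", sep="\t", index=False,
                        float_format="%.6g")
        de_genes = de.select_de_genes(de_table, fdr=config.de_fdr)
        universe = _analysis_universe(study, de_genes)
        summary["n_de_genes"] = len(de_genes)

        _stage("coexpression networks")
        nets = {}
        for cond in CONDITIONS:
            nets[cond] = cx.build_network(
                study, cond, universe=universe, alpha=config.edge_alpha,
                convention=config.pair_p_convention)
            cx.write_edges_tsv(nets[cond], out / f"edges_{cond}.tsv")
            summary[f"n_edges_{cond}"] = nets[cond].n_edges

        if config.permutations > 0:
            _stage("permutation null")
            perm_rows = []
            for k, cond in enumerate(CONDITIONS):
                null = cx.permutation_null(
                    study, cond, universe=universe, alpha=config.edge_alpha,
                    B=config.permutations, seed=config.seed + 7919 * (k + 1),
                    convention=config.pair_p_convention)
                perm_rows.append({
                    "condition": cond, "B": null.B,
                    "statistic": null.statistic,
                    "observed_count": null.observed_count,
                    "null_max": int(null.null_counts.max()),
                    "null_mean": float(null.null_counts.mean()),
                    "empirical_p": null.empirical_p})
                summary[f"permutation_p_{cond}"] = null.empirical_p
            pd.DataFrame(perm_rows).to_csv(out / "permutation.tsv", sep="\t",
                                           index=False, float_format="%.6g")

        _stage("differential coexpression")
        dc = dcx.classify_edges(nets["pre"], nets["post"])
        dcx.write_diffcoex_tsvs(dc, out)
        summary.update(dc.summary())
        diff_pre, diff_post = dcx.differential_networks(dc)

        _stage("Pareto essentiality")
        pareto_nets = {"pre": diff_pre, "post": diff_post} \
            if config.pareto_network == "differential" else nets
        fronts = {}
        for cond in CONDITIONS:
            profiles = ess.connectivity_profiles(pareto_nets[cond])
            result = ess.pareto_front(profiles)
            ess.write_profiles_tsv(result, out / f"pareto_{cond}.tsv")
            fronts[cond] = result.front
            summary[f"pareto_front_{cond}"] = ",".join(result.front)
        for cond, focal in fronts.items():
            ego_rows = []
            for g in focal:
                ego_pre, ego_post = ess.ego_subnetwork(g, diff_pre, diff_post)
                for label, edges in (("pre", ego_pre), ("post", ego_post)):
                    for _, e in edges.iterrows():
                        ego_rows.append({"focal_gene": g, "condition": label,
                                         "gene_i": e["gene_i"],
                                         "gene_j": e["gene_j"],
                                         "sign": "+" if e["sign"] > 0 else "-"})
            pd.DataFrame(ego_rows, columns=["focal_gene", "condition",
                                            "gene_i", "gene_j", "sign"]) \
                .to_csv(out / f"ego_{cond}_front.tsv", sep="\t", index=False)

        tables = tuple(ann.read_gmt(p) for p in config.gmt)
        fnet = ann.read_functional_network(config.fnet) if config.fnet else None
        if tables or fnet is not None:
            _stage("annotation")
            for cond in CONDITIONS:
                support, fraction = ann.evidence_support(
                    nets[cond].edges, tables, fnet,
                    prob_threshold=config.prob_threshold)
                support.to_csv(out / f"support_{cond}.tsv", sep="\t",
                               index=False, float_format="%.6g")
                summary[f"supported_fraction_{cond}"] = fraction
            if tables:
                excl = ann.exclusive_shared_terms(dc.exclusive_post,
                                                  dc.exclusive_pre, tables[0])
                excl.to_csv(out / "post_exclusive_terms.tsv", sep="\t",
                            index=False)

        if config.replication_expr is not None:
            _stage("replication")
            repl_study = read_expression_tsv(config.replication_expr,
                                             config.replication_meta)
            table = replication_analysis(
                study, repl_study, de_fdr=config.de_fdr,
                edge_alpha=config.edge_alpha,
                convention=config.pair_p_convention,
                tables=tables, fnet=fnet, summary=summary)
            table.to_csv(out / "replicated_edges.tsv", sep="\t", index=False,
                         float_format="%.6g")

        pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t",
                                       index=False, float_format="%.6g")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "outputs": {p.name: _sha256(p)
                    for p in sorted(out.glob("*.tsv"))},
        "summary": {k: v for k, v in summary.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest


def replication_analysis(discovery: ExpressionStudy,
                         replication: ExpressionStudy,
                         de_fdr: float = 0.05, edge_alpha: float = 0.01,
                         convention: str = "max",
                         tables: tuple = (), fnet=None,
                         summary: dict | None = None) -> pd.DataFrame:
    """Two-cohort replication: DE in both -> networks per cohort ->
    differential objects -> replicated treatment-induced edges."""
    de_disc = de.run_de(discovery, fdr=de_fdr)
    de_repl = de.run_de(replication, fdr=de_fdr)
    shared = rep.intersect_de(de.select_de_genes(de_disc, de_fdr),
                              de.select_de_genes(de_repl, de_fdr))
    universe = sorted(set(_analysis_universe(discovery, shared))
                      & set(_analysis_universe(replication, shared)))
    if summary is not None:
        summary["n_de_shared"] = len(shared)

    def _dc(study: ExpressionStudy) -> dcx.DifferentialCoexpression:
        nets = {c: cx.build_network(study, c, universe=universe,
                                    alpha=edge_alpha, convention=convention)
                for c in CONDITIONS}
        return dcx.classify_edges(nets["pre"], nets["post"])

    if len(universe) < 2:
        logger.warning("fewer than 2 shared DE genes; no replication possible")
        table = rep.replicate_induced_edges(
            dcx.empty_differential(universe, edge_alpha),
            dcx.empty_differential(universe, edge_alpha),
            de_discovery=de_disc, tables=tables, fnet=fnet)
    else:
        table = rep.replicate_induced_edges(
            _dc(discovery), _dc(replication),
            de_discovery=de_disc, tables=tables, fnet=fnet)
    if summary is not None:
        summary["n_replicated_edges"] = len(table)
    return table
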