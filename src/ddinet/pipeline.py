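"""End-to-end run orchestration and report emission.

Given a cohort and knowledge base (loaded from disk or generated
synthetically), runs profiling, cohort statistics, network construction
and the metric suite, and writes every table the analysis produces:
per-patient profiles, the long-format interaction table, summary JSON,
frequency/severity/risk tables, sex and age stratifications, the edge
list and GraphML, node/graph metrics for the full network and the top-k
hub subgraph, a plain-text summary, and a manifest with input hashes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import Cohort, ExclusionReport, load_cohort
from .knowledge import KnowledgeBase, load_knowledge_base
from .metrics import graph_metrics, node_metrics_frame
from .network import DrugGraph, build_network, edge_list_frame, top_k_subgraph, write_graphml
from .profiles import interactions_long_frame, profile_cohort, profiles_to_frame
from .simulate import GeneratorConfig, generate, write_bundle
from .stats import (
    CohortSummary,
    drug_frequency_table,
    drug_severity_breakdown,
    pair_frequency_table,
    risk_distribution_frame,
    severity_distribution_frame,
    stratify,
    summarize_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``cohort_path`` + ``kb_path``) or ``generator`` must
    be supplied.
    """

    outdir: Path
    cohort_path: Optional[Path] = None
    kb_path: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    top_k: int = 25
    strict: bool = False
    weighted_metrics: bool = False
    include_isolated: bool = False

    def __post_init__(self) -> None:
        has_files = self.cohort_path is not None and self.kb_path is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ValueError(
                "supply either cohort_path+kb_path or a generator config, "
                "not both")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run computed."""

    cohort: Cohort
    kb: KnowledgeBase
    exclusions: Optional[ExclusionReport]
    summary: CohortSummary
    graph: DrugGraph
    subgraph: DrugGraph
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_text_summary(path: Path, result: PipelineResult) -> None:
    s = result.summary
    gm = graph_metrics(result.graph)
    sm = graph_metrics(result.subgraph)
    lines = [
        "Drug-drug interaction analysis summary",
        "======================================",
        f"patients analysed: {s.n_patients}",
        f"total interactions: {s.total_interactions}",
        f"patients with >=1 interaction: {s.prevalence_any.successes} "
        f"({s.prevalence_any.pct:.1f}%; 95% CI {s.prevalence_any.ci_low:.1f}-"
        f"{s.prevalence_any.ci_high:.1f}%)",
        f"patients with >=1 major interaction: {s.prevalence_any_major.successes} "
        f"({s.prevalence_any_major.pct:.1f}%)",
        "severity distribution (events): "
        + ", ".join(
            f"{sev} {v['count']} ({v['pct']:.1f}%)"
            for sev, v in sorted(s.severity_distribution.items())
        ),
        "risk strata (patients): "
        + ", ".join(
            f"{cat} {v['count']} ({v['pct']:.1f}%)"
            for cat, v in s.risk_distribution.items()
        ),
        f"mean medications/patient: {s.per_patient['mean_medications']:.2f}",
        f"mean interactions/patient: {s.per_patient['mean_total']:.2f}",
        f"mean major interactions/patient: {s.per_patient['mean_major']:.2f}",
        "meds vs total interactions r: "
        + (f"{s.correlation_meds_vs_total.r:.3f}"
           if s.correlation_meds_vs_total.r is not None else "undefined"),
        "",
        f"network: {gm.n_nodes} nodes, {gm.n_edges} edges, "
        f"density {gm.density:.3f}, avg clustering {gm.avg_clustering:.3f}, "
        f"{gm.n_components} component(s)",
        f"top-{result.subgraph.n_nodes} hub subgraph: {sm.n_nodes} nodes, "
        f"{sm.n_edges} edges, density {sm.density:.3f}, "
        f"avg clustering {sm.avg_clustering:.3f}",
        "",
    ]
    path.write_text("\n".join(lines))


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to
    ``cfg.outdir``.  Stage failures propagate with the stage named."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "config": {
            "top_k": cfg.top_k,
            "strict": cfg.strict,
            "weighted_metrics": cfg.weighted_metrics,
            "include_isolated": cfg.include_isolated,
        },
    }

    exclusions: Optional[ExclusionReport] = None
    if cfg.generator is not None:
        logger.info("stage simulate: generating synthetic bundle")
        bundle = generate(cfg.generator)
        paths = write_bundle(bundle, outdir / "input")
        cohort, kb = bundle.cohort, bundle.kb
        manifest["config"]["generator"] = dataclasses.asdict(cfg.generator)
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
    else:
        logger.info("stage ingest: loading cohort and knowledge base")
        kb = load_knowledge_base(cfg.kb_path)
        cohort, exclusions = load_cohort(cfg.cohort_path, strict=cfg.strict)
        manifest["inputs"] = {
            "cohort": _sha256(Path(cfg.cohort_path)),
            "kb": _sha256(Path(cfg.kb_path)),
        }
        manifest["exclusions"] = {
            "n_input": exclusions.n_input,
            "n_accepted": exclusions.n_accepted,
            "excluded": [
                {"row": r, "patient_id": pid, "reason": reason}
                for r, pid, reason in exclusions.excluded
            ],
            "warnings": exclusions.warnings,
        }

    logger.info("stage profile: screening %d patients", len(cohort))
    profiles = profile_cohort(cohort, kb)
    profiles_to_frame(profiles).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    long = interactions_long_frame(profiles)
    long.to_csv(outdir / "interactions.tsv", sep="\t", index=False)

    logger.info("stage stats: %d interactions found", len(long))
    summary = summarize_cohort(profiles)
    (outdir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n")
    severity_distribution_frame(summary).to_csv(
        outdir / "severity_distribution.tsv", sep="\t", index=False)
    risk_distribution_frame(summary).to_csv(
        outdir / "risk_distribution.tsv", sep="\t", index=False)
    drug_frequency_table(long, cohort).to_csv(
        outdir / "drug_frequency.tsv", sep="\t", index=False)
    pair_frequency_table(long).to_csv(
        outdir / "pair_frequency.tsv", sep="\t", index=False)
    drug_severity_breakdown(long).to_csv(
        outdir / "drug_severity_breakdown.tsv", sep="\t", index=False)
    strata_dir = outdir / "strata"
    strata_dir.mkdir(exist_ok=True)
    for by in ("sex", "age_group"):
        strata = stratify(cohort, profiles, by=by)
        rows = []
        for label, s in strata.items():
            if s.severity_distribution:
                for sev, v in sorted(s.severity_distribution.items()):
                    rows.append({"stratum": label, "n_patients": s.n_patients,
                                 "total_interactions": s.total_interactions,
                                 "severity": sev, "count": v["count"],
                                 "pct": round(v["pct"], 1)})
            else:
                rows.append({"stratum": label, "n_patients": s.n_patients,
                             "total_interactions": 0, "severity": "",
                             "count": 0, "pct": 0.0})
        pd.DataFrame(rows).to_csv(strata_dir / f"{by}.tsv", sep="\t",
                                  index=False)

    logger.info("stage network: building interaction graph")
    all_drugs = {m for p in cohort for m in p.medications}
    graph = build_network(profiles, include_isolated=cfg.include_isolated,
                          all_drugs=all_drugs)
    edge_list_frame(graph).to_csv(outdir / "edge_list.tsv", sep="\t", index=False)
    write_graphml(graph, outdir / "network.graphml")

    logger.info("stage metrics: %d nodes, %d edges", graph.n_nodes, graph.n_edges)
    if graph.n_nodes:
        node_metrics_frame(graph, weighted=cfg.weighted_metrics).to_csv(
            outdir / "node_metrics.tsv", sep="\t", index=False)
        subgraph = top_k_subgraph(graph, min(cfg.top_k, max(graph.n_nodes, 1)))
        node_metrics_frame(subgraph, weighted=cfg.weighted_metrics).to_csv(
            outdir / "subgraph_node_metrics.tsv", sep="\t", index=False)
        edge_list_frame(subgraph).to_csv(
            outdir / "subgraph_edge_list.tsv", sep="\t", index=False)
    else:
        subgraph = DrugGraph()
    (outdir / "graph_metrics.json").write_text(json.dumps(
        {
            "full": graph_metrics(graph).to_dict(),
            "top_k": graph_metrics(subgraph).to_dict(),
        }, indent=2) + "\n")

    result = PipelineResult(
        cohort=cohort, kb=kb, exclusions=exclusions, summary=summary,
        graph=graph, subgraph=subgraph, outdir=outdir)
    _write_text_summary(outdir / "summary.txt", result)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: outputs in %s", outdir)
    return result
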