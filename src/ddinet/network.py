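"""Cohort-aggregated, severity-weighted drug-interaction graph.

Nodes are medications, undirected edges are documented interactions
between drug pairs.  An edge carries the pair's (single) knowledge-base
severity, the number of patients exhibiting the pair, and the summed
severity weight (occurrences x severity weight, with major=3,
moderate=2, minor=1, unknown=0.5).  The graph is simple: no self-loops,
no parallel edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional
from xml.etree import ElementTree as ET

import pandas as pd

from .errors import ValidationError
from .knowledge import Severity, severity_weight
from .profiles import PatientProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeData",
    "DrugGraph",
    "build_network",
    "top_k_subgraph",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]


@dataclass
class EdgeData:
    """Aggregated attributes of one interacting drug pair."""

    severity: Severity
    occurrence_count: int
    summed_weight: float

    def __post_init__(self) -> None:
        if self.occurrence_count < 1:
            raise ValidationError("edge occurrence count must be >= 1")


@dataclass
class DrugGraph:
    """Simple undirected graph with severity-annotated edges."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], EdgeData] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        """Node -> neighbour-set map (isolated nodes map to empty sets)."""
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self) -> dict[str, int]:
        adj = self.adjacency()
        return {v: len(nbrs) for v, nbrs in adj.items()}

    def add_edge(self, a: str, b: str, data: EdgeData) -> None:
        if a == b:
            raise ValidationError(f"self-loop on '{a}'")
        key = (a, b) if a < b else (b, a)
        self.nodes.update(key)
        self.edges[key] = data


def build_network(profiles: Iterable[PatientProfile],
                  include_isolated: bool = False,
                  all_drugs: Optional[Iterable[str]] = None) -> DrugGraph:
    """Aggregate patient-level interactions into the cohort graph.

    When the same pair occurs in several patients its severity weights
    are summed and occurrences counted.  By default only drugs appearing
    in at least one interaction become nodes; pass
    ``include_isolated=True`` with *all_drugs* (e.g. the union of
    medication lists) to retain never-interacting drugs as isolated
    nodes.
    """
    g = DrugGraph()
    for profile in profiles:
        for pair, sev in profile.interactions:
            existing = g.edges.get(pair)
            if existing is None:
                g.add_edge(*pair, EdgeData(
                    severity=sev, occurrence_count=1,
                    summed_weight=severity_weight(sev)))
            else:
                if existing.severity is not sev:
                    raise ValidationError(
                        f"pair {pair} observed with two severities "
                        f"({existing.severity.value}, {sev.value}); "
                        "profiles must come from a single knowledge base"
                    )
                existing.occurrence_count += 1
                existing.summed_weight += severity_weight(sev)
    if include_isolated and all_drugs is not None:
        g.nodes.update(all_drugs)
    logger.info("built network: %d nodes, %d edges", g.n_nodes, g.n_edges)
    return g


def top_k_subgraph(g: DrugGraph, k: int) -> DrugGraph:
    """Induced subgraph on the k nodes of highest raw degree.

    Ties are broken lexicographically; all edges among the selected
    nodes are retained.  ``k`` larger than the node count returns the
    whole graph with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.n_nodes:
        warnings.warn(
            f"k={k} exceeds node count {g.n_nodes}; returning full graph",
            stacklevel=2,
        )
        k = g.n_nodes
    deg = g.degree()
    ranked = sorted(deg, key=lambda v: (-deg[v], v))
    keep = set(ranked[:k])
    sub = DrugGraph(nodes=set(keep))
    for (a, b), data in g.edges.items():
        if a in keep and b in keep:
            sub.edges[(a, b)] = EdgeData(data.severity, data.occurrence_count,
                                         data.summed_weight)
    return sub


def edge_list_frame(g: DrugGraph) -> pd.DataFrame:
    """Loss-less tabular edge list (sorted by canonical pair)."""
    rows = [
        {
            "drug_a": a,
            "drug_b": b,
            "severity": data.severity.value,
            "occurrence_count": data.occurrence_count,
            "summed_weight": data.summed_weight,
        }
        for (a, b), data in sorted(g.edges.items())
    ]
    return pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "severity", "occurrence_count",
                       "summed_weight"])


def write_edge_list(g: DrugGraph, path: str | Path) -> None:
    edge_list_frame(g).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> DrugGraph:
    """Rebuild a graph from :func:`write_edge_list` output (round-trip
    inverse for graphs without isolated nodes)."""
    table = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    g = DrugGraph()
    for row in table.itertuples(index=False):
        g.add_edge(row.drug_a, row.drug_b, EdgeData(
            severity=Severity(row.severity),
            occurrence_count=int(row.occurrence_count),
            summed_weight=float(row.summed_weight)))
    return g


def write_graphml(g: DrugGraph, path: str | Path) -> None:
    """Write the graph as GraphML with all edge attributes preserved."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    keys = [
        ("severity", "string"), ("occurrence_count", "int"),
        ("summed_weight", "double"),
    ]
    for name, typ in keys:
        key = ET.SubElement(root, f"{{{ns}}}key")
        key.set("id", name)
        key.set("for", "edge")
        key.set("attr.name", name)
        key.set("attr.type", typ)
    graph = ET.SubElement(root, f"{{{ns}}}graph")
    graph.set("edgedefault", "undirected")
    for node in sorted(g.nodes):
        el = ET.SubElement(graph, f"{{{ns}}}node")
        el.set("id", node)
    for (a, b), data in sorted(g.edges.items()):
        el = ET.SubElement(graph, f"{{{ns}}}edge")
        el.set("source", a)
        el.set("target", b)
        for name, value in (
            ("severity", data.severity.value),
            ("occurrence_count", data.occurrence_count),
            ("summed_weight", data.summed_weight),
        ):
            d = ET.SubElement(el, f"{{{ns}}}data")
            d.set("key", name)
            d.text = str(value)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")
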