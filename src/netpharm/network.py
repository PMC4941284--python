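"""Assembly of the tripartite herb – putative-target – disease-target network.

Nodes carry one of four roles: ``herb``, ``putative_target``,
``known_disease_target``, or ``both`` (a gene that is simultaneously a
putative target of the formula and a known disease gene).  Edges are
typed: ``herb_target`` links a herb to one of its putative targets;
``ppi`` links two genes that interact directly.  Known disease genes
with no direct interaction inside the network (and no putative status)
are pruned, since the network is built on direct interactions only.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .scoring import HerbPutativeTargets
from .symbols import normalize_symbol

logger = logging.getLogger(__name__)

ROLES = ("herb", "putative_target", "known_disease_target", "both")
GENE_ROLES = ("putative_target", "known_disease_target", "both")


@dataclass(frozen=True)
class TripartiteNetwork:
    """Typed herb/target/disease graph with pruning bookkeeping."""

    graph: nx.Graph
    dropped_known: tuple[str, ...] = field(default=())

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def nodes_with_role(self, *roles: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data="role") if d in roles)

    def edges_with_type(self, edge_type: str) -> list[tuple[str, str]]:
        return sorted(
            (min(u, v), max(u, v))
            for u, v, t in self.graph.edges(data="edge_type")
            if t == edge_type
        )

    def untyped_graph(self) -> nx.Graph:
        """Plain undirected view used for centrality computation."""
        return self.graph

    # -- serialization -------------------------------------------------

    def to_files(self, edge_path: str | Path, node_path: str | Path) -> None:
        edge_rows = sorted(
            (min(u, v), max(u, v), t) for u, v, t in self.graph.edges(data="edge_type")
        )
        pd.DataFrame(edge_rows, columns=["source", "target", "edge_type"]).to_csv(
            edge_path, sep="\t", index=False
        )
        node_rows = sorted((n, r) for n, r in self.graph.nodes(data="role"))
        pd.DataFrame(node_rows, columns=["node", "role"]).to_csv(
            node_path, sep="\t", index=False
        )

    @classmethod
    def from_files(cls, edge_path: str | Path, node_path: str | Path) -> "TripartiteNetwork":
        nodes = pd.read_csv(node_path, sep="\t")
        edges = pd.read_csv(edge_path, sep="\t")
        graph = nx.Graph()
        for node, role in zip(nodes["node"], nodes["role"]):
            if role not in ROLES:
                raise ValueError(f"unknown node role {role!r}")
            graph.add_node(str(node), role=str(role))
        for u, v, t in zip(edges["source"], edges["target"], edges["edge_type"]):
            graph.add_edge(str(u), str(v), edge_type=str(t))
        return cls(graph=graph)

    def to_sif(self, path: str | Path) -> None:
        lines = [
            f"{min(u, v)}\t{'ht' if t == 'herb_target' else 'pp'}\t{max(u, v)}"
            for u, v, t in sorted(
                (min(u, v), max(u, v), t)
                for u, v, t in self.graph.edges(data="edge_type")
            )
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def assemble(
    herb_targets: HerbPutativeTargets | Mapping[str, Iterable[str]],
    known_disease: Iterable[str],
    ppi: nx.Graph,
) -> TripartiteNetwork:
    """Build the tripartite network from herb→target links and PPI edges.

    The node set is herbs ∪ putative targets ∪ surviving known disease
    genes; PPI edges are kept when both endpoints are in-network genes;
    known-only genes without any such edge are dropped (logged).
    """
    if isinstance(herb_targets, HerbPutativeTargets):
        per_herb = {h: set(t) for h, t in herb_targets.targets.items()}
    else:
        per_herb = {h: {normalize_symbol(g) for g in t} for h, t in herb_targets.items()}
    if not per_herb or not any(per_herb.values()):
        raise ValueError("no herb putative targets provided")
    putative = set().union(*per_herb.values())

    known_norm = {normalize_symbol(g) for g in known_disease}
    if not known_norm:
        raise ValueError("known disease-gene list is empty")
    known_in = known_norm & set(ppi.nodes())
    if not known_in:
        raise ValueError("no known disease gene is present in the gene universe")

    gene_pool = putative | known_in
    ppi_edges = [
        (u, v) for u, v in ppi.edges() if u in gene_pool and v in gene_pool and u != v
    ]
    touched = {u for e in ppi_edges for u in e}
    dropped = sorted(g for g in known_in - putative if g not in touched)
    if dropped:
        logger.info(
            "dropped %d isolated known disease genes with no direct interaction",
            len(dropped),
        )
    kept_known = known_in - set(dropped)

    graph = nx.Graph()
    for herb in sorted(per_herb):
        graph.add_node(herb, role="herb")
    for g in sorted(putative | kept_known):
        if g in putative and g in kept_known:
            role = "both"
        elif g in putative:
            role = "putative_target"
        else:
            role = "known_disease_target"
        graph.add_node(g, role=role)
    for herb in sorted(per_herb):
        for g in sorted(per_herb[herb]):
            graph.add_edge(herb, g, edge_type="herb_target")
    for u, v in ppi_edges:
        graph.add_edge(u, v, edge_type="ppi")
    return TripartiteNetwork(graph=graph, dropped_known=tuple(dropped))


def summarize(network: TripartiteNetwork) -> dict:
    """Composition record: node counts per role, edge counts per type.

    ``putative_targets_total`` / ``known_disease_targets_total`` count
    overlap ("both") genes in both categories, mirroring the additive
    accounting used when such networks are reported as
    "herbs + putative targets + known targets" sums.
    """
    graph = network.graph
    roles = pd.Series(dict(graph.nodes(data="role")))
    counts = {role: int((roles == role).sum()) for role in ROLES}
    edge_types = [t for _, _, t in graph.edges(data="edge_type")]
    overlap = counts["both"]
    return {
        "nodes_total": graph.number_of_nodes(),
        "herbs": counts["herb"],
        "putative_targets": counts["putative_target"],
        "known_disease_targets": counts["known_disease_target"],
        "overlap": overlap,
        "putative_targets_total": counts["putative_target"] + overlap,
        "known_disease_targets_total": counts["known_disease_target"] + overlap,
        "herb_target_edges": edge_types.count("herb_target"),
        "ppi_edges": edge_types.count("ppi"),
        "edges_total": graph.number_of_edges(),
        "dropped_known": list(network.dropped_known),
    }
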