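"""Four node-topology measures and the all-above-median "major node" rule.

Per node of the (untyped, undirected, unweighted) network:

* **degree** — incident edge count;
* **betweenness** — unnormalized shortest-path betweenness, each
  unordered pair (s, t) counted once;
* **closeness** — harmonic centrality ``sum_{u != v} 1/d(v, u)`` by
  default (finite on disconnected graphs; two classic inverse-farness
  variants are selectable);
* **k_core** — coreness: the largest k such that the node survives
  iterative removal of nodes with degree < k.

A *major node* is one whose four values are all strictly greater than
the corresponding column medians.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import GENE_ROLES, TripartiteNetwork
from .scoring import _to_igraph

CLOSENESS_VARIANTS = ("harmonic", "classic_inverse_farness", "classic_times_n_minus_1")


def _classic_closeness(graph, nodes: list, scale_by_n_minus_1: bool) -> np.ndarray:
    """Inverse farness over reachable nodes; 0 for isolated nodes."""
    dist = np.asarray(graph.distances(), dtype=float)
    np.fill_diagonal(dist, np.inf)
    finite = np.isfinite(dist)
    farness = np.where(finite, dist, 0.0).sum(axis=1)
    out = np.zeros(len(nodes))
    mask = farness > 0
    num = (len(nodes) - 1) if scale_by_n_minus_1 else 1.0
    out[mask] = num / farness[mask]
    return out


def compute_topology(
    network: TripartiteNetwork | nx.Graph,
    closeness_variant: str = "harmonic",
    betweenness_normalized: bool = False,
) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, and coreness.

    Measures are computed on the untyped undirected simple graph — all
    edges and all nodes, herbs included.  Returns a DataFrame indexed by
    node with columns ``role, degree, betweenness, closeness, k_core``.
    """
    if closeness_variant not in CLOSENESS_VARIANTS:
        raise ValueError(
            f"closeness_variant must be one of {CLOSENESS_VARIANTS}, got {closeness_variant!r}"
        )
    if isinstance(network, TripartiteNetwork):
        graph = network.untyped_graph()
        roles = [graph.nodes[n]["role"] for n in graph.nodes()]
    else:
        graph = network
        roles = [graph.nodes[n].get("role", "node") for n in graph.nodes()]
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    ig_graph, nodes = _to_igraph(graph)
    n = len(nodes)

    betweenness = np.asarray(ig_graph.betweenness(directed=False), dtype=float)
    if betweenness_normalized and n > 2:
        betweenness = betweenness / ((n - 1) * (n - 2) / 2)
    if closeness_variant == "harmonic":
        closeness = np.asarray(
            ig_graph.harmonic_centrality(normalized=False), dtype=float
        )
    else:
        closeness = _classic_closeness(
            ig_graph, nodes, closeness_variant == "classic_times_n_minus_1"
        )
    table = pd.DataFrame(
        {
            "role": roles,
            "degree": np.asarray(ig_graph.degree(), dtype=np.int64),
            "betweenness": betweenness,
            "closeness": closeness,
            "k_core": np.asarray(ig_graph.coreness(), dtype=np.int64),
        },
        index=pd.Index(nodes, name="node"),
    )
    return table


MEASURES = ("degree", "betweenness", "closeness", "k_core")


@dataclass(frozen=True)
class MedianThresholds:
    """Sample medians of the four topology columns."""

    degree: float
    betweenness: float
    closeness: float
    k_core: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def median_thresholds(table: pd.DataFrame) -> MedianThresholds:
    """Column medians (even n: mean of the two central order statistics)."""
    if len(table) == 0:
        raise ValueError("topology table is empty")
    return MedianThresholds(
        **{m: float(np.median(table[m].to_numpy(dtype=float))) for m in MEASURES}
    )


def select_major_nodes(
    table: pd.DataFrame,
    thresholds: MedianThresholds,
    eligible_roles: Iterable[str] = GENE_ROLES,
) -> list[str]:
    """Nodes of an eligible role strictly above all four thresholds.

    Herb nodes participate in the medians but are excluded from
    eligibility by default: hub-like formula nodes are structural, not
    candidate targets.
    """
    roles = frozenset(eligible_roles)
    if not roles:
        raise ValueError("eligible_roles must not be empty")
    mask = table["role"].isin(roles)
    for measure in MEASURES:
        mask &= table[measure] > getattr(thresholds, measure)
    return sorted(table.index[mask])


def major_node_report(
    table: pd.DataFrame,
    thresholds: MedianThresholds,
    eligible_roles: Iterable[str] = GENE_ROLES,
) -> dict:
    """Major-node selection with counts split by role.

    ``putative_total`` / ``known_total`` count overlap ("both") nodes in
    both categories, so the headline count equals the sum of its parts.
    """
    major = select_major_nodes(table, thresholds, eligible_roles)
    roles = table.loc[major, "role"]
    by_role = {role: int((roles == role).sum()) for role in sorted(set(table["role"]))}
    overlap = by_role.get("both", 0)
    return {
        "major_nodes": major,
        "n_major": len(major),
        "by_role": by_role,
        "putative_total": by_role.get("putative_target", 0) + overlap,
        "known_total": by_role.get("known_disease_target", 0) + overlap,
        "thresholds": thresholds.as_dict(),
    }


def write_topology(
    table: pd.DataFrame,
    thresholds: MedianThresholds,
    major: Iterable[str],
    path: str | Path,
) -> None:
    out = table.copy()
    out["is_major"] = out.index.isin(set(major))
    out.sort_index().to_csv(path, sep="\t", float_format="%.10g")
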