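"""Readers and writers for the pipeline's plain-text exchange formats.

All tables are TSV; networks additionally export the SIF dialect
(``A pp B``) for external graph viewers.  Every gene symbol passes
through :func:`netpharm.symbols.normalize_symbol` on the way in.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import pandas as pd

from .symbols import normalize_symbol


def write_ppi_edgelist(graph: nx.Graph, path: str | Path) -> None:
    lines = ["gene_a\tgene_b"]
    lines += [f"{min(u, v)}\t{max(u, v)}" for u, v in sorted(map(sorted, graph.edges()))]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ppi_edgelist(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        a, b = line.split("\t")[:2]
        if i == 0 and a.lower() in ("gene_a", "source", "node_a"):
            continue
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a != b:
            graph.add_edge(a, b)
    return graph


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    lines = [f"{min(u, v)}\t{relation}\t{max(u, v)}" for u, v in sorted(map(sorted, graph.edges()))]
    Path(path).write_text("\n".join(lines) + "\n")


def write_similarity(sim: pd.DataFrame, path: str | Path) -> None:
    sim.to_csv(path, sep="\t", index_label="compound", float_format="%.10g")


def read_similarity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"similarity matrix {path} contains missing values")
    df.index.name = None
    df.columns.name = None
    return df


def write_drug_targets(drug_targets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = ["drug\ttarget"]
    for drug in sorted(drug_targets):
        lines += [f"{drug}\t{t}" for t in sorted(drug_targets[drug])]
    Path(path).write_text("\n".join(lines) + "\n")


def read_drug_targets(path: str | Path) -> dict[str, frozenset]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set] = {}
    for drug, target in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(drug), set()).add(normalize_symbol(str(target)))
    return {d: frozenset(t) for d, t in out.items()}


def write_herb_compounds(herb_compounds: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = ["herb\tcompound"]
    for herb in sorted(herb_compounds):
        lines += [f"{herb}\t{c}" for c in herb_compounds[herb]]
    Path(path).write_text("\n".join(lines) + "\n")


def read_herb_compounds(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for herb, compound in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(herb), []).append(str(compound))
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        normalize_symbol(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
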