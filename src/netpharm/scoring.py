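"""Concordance-based compound→target scoring ("putative target profiles").

The scoring model follows the drugCIPHER-CS idea: a compound's chemical
similarity to a panel of reference drugs is one channel; a candidate
gene's network closeness to each reference drug's known targets is the
other.  A gene is a plausible target of the compound when the two
channels agree, i.e. when the Pearson correlation across reference drugs
between

* ``sim(compound, drug)``      (chemical similarity, given as input) and
* ``closeness(gene, drug)``    (sum of a distance kernel over the drug's
  targets in the protein-interaction network)

is high.  Ranking all candidate genes by this concordance score yields
the compound's putative target profile; a herb's putative targets are
the union of its compounds' top-``k`` genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .symbols import normalize_symbol

logger = logging.getLogger(__name__)

KernelFn = Callable[[np.ndarray], np.ndarray]


def gaussian_kernel(d: np.ndarray) -> np.ndarray:
    """Default distance kernel ``exp(-d**2)``; maps ``inf`` (unreachable) to 0."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-np.square(d))


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list]:
    """Convert a networkx graph to igraph, preserving node order."""
    nodes = list(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    return ig.Graph(n=len(nodes), edges=edges, directed=False), nodes


def _clean_drug_targets(
    ppi: nx.Graph, drug_targets: Mapping[str, Iterable[str]]
) -> dict[str, frozenset]:
    """Normalize symbols and drop targets absent from the network (logged)."""
    nodes = set(ppi.nodes())
    cleaned: dict[str, frozenset] = {}
    n_dropped = 0
    for drug, targets in drug_targets.items():
        kept = frozenset(
            t for t in (normalize_symbol(g) for g in targets) if t in nodes
        )
        n_dropped += len(set(targets)) - len(kept)
        cleaned[drug] = kept
    if n_dropped:
        logger.info("dropped %d drug targets absent from the PPI network", n_dropped)
    return cleaned


def gene_drug_closeness(
    gene: str,
    drug: str,
    ppi: nx.Graph,
    drug_targets: Mapping[str, Iterable[str]],
    kernel: KernelFn = gaussian_kernel,
) -> float:
    """Network closeness of ``gene`` to ``drug``'s known targets.

    Sum over the drug's targets *t* of ``kernel(d(gene, t))`` where *d*
    is the unweighted shortest-path length; unreachable targets
    contribute 0 and ``d(g, g) = 0``.
    """
    gene = normalize_symbol(gene)
    if gene not in ppi:
        raise KeyError(f"gene {gene!r} is not a node of the PPI network")
    targets = _clean_drug_targets(ppi, {drug: drug_targets[drug]})[drug]
    if not targets:
        raise ValueError(f"drug {drug!r} has no mapped targets in the network")
    dist = nx.single_source_shortest_path_length(ppi, gene)
    return float(sum(kernel(np.array([dist[t]]))[0] for t in targets if t in dist))


def closeness_matrix(
    ppi: nx.Graph,
    drug_targets: Mapping[str, Iterable[str]],
    drugs: Sequence[str] | None = None,
    kernel: KernelFn = gaussian_kernel,
) -> pd.DataFrame:
    """Gene × drug matrix of kernel-summed network closeness.

    One BFS per distinct target node (via igraph's C core), then each
    drug's column is the kernel sum over its own targets.
    """
    cleaned = _clean_drug_targets(ppi, drug_targets)
    if drugs is None:
        drugs = sorted(cleaned)
    for d in drugs:
        if not cleaned.get(d):
            raise ValueError(f"drug {d!r} has no mapped targets in the network")
    graph, nodes = _to_igraph(ppi)
    node_index = {v: i for i, v in enumerate(nodes)}
    all_targets = sorted({t for d in drugs for t in cleaned[d]})
    dist = np.asarray(
        graph.distances(source=[node_index[t] for t in all_targets]), dtype=float
    )
    ker = kernel(dist)  # (targets, genes)
    row_of = {t: i for i, t in enumerate(all_targets)}
    cols = np.column_stack(
        [ker[[row_of[t] for t in cleaned[d]], :].sum(axis=0) for d in drugs]
    )
    return pd.DataFrame(cols, index=nodes, columns=list(drugs))


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise population z-score; zero-variance rows become all-zero."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    np.divide(values - mean, sd, out=out, where=sd > 0)
    return out


def score_matrix(sim: pd.DataFrame, closeness: pd.DataFrame) -> pd.DataFrame:
    """Compound × gene concordance scores (Pearson across reference drugs).

    Zero-variance rows in either channel score 0 by convention: a
    constant channel carries no evidence either way.
    """
    drugs = list(sim.columns)
    if len(drugs) < 3:
        raise ValueError(
            f"concordance needs >= 3 reference drugs, got {len(drugs)}"
        )
    clo = closeness.loc[:, drugs]
    zs = _zscore_rows(sim.to_numpy(dtype=float))
    zc = _zscore_rows(clo.to_numpy(dtype=float))
    scores = (zs @ zc.T) / len(drugs)
    return pd.DataFrame(scores, index=sim.index, columns=closeness.index)


def concordance_score(
    compound: str,
    gene: str,
    sim: pd.DataFrame,
    ppi: nx.Graph,
    drug_targets: Mapping[str, Iterable[str]],
    kernel: KernelFn = gaussian_kernel,
) -> float:
    """Concordance score for a single (compound, gene) pair, in [-1, 1]."""
    gene = normalize_symbol(gene)
    drugs = list(sim.columns)
    if len(drugs) < 3:
        raise ValueError(
            f"concordance needs >= 3 reference drugs, got {len(drugs)}"
        )
    x = sim.loc[compound, drugs].to_numpy(dtype=float)
    y = np.array(
        [gene_drug_closeness(gene, d, ppi, drug_targets, kernel) for d in drugs]
    )
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _rank_rows(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-row ranks 1..n: score descending, ties by gene symbol ascending."""
    ordered = scores.loc[:, sorted(scores.columns)]
    vals = ordered.to_numpy(dtype=float)
    ranks = np.empty_like(vals, dtype=np.int64)
    positions = np.arange(1, vals.shape[1] + 1)
    for i in range(vals.shape[0]):
        order = np.argsort(-vals[i], kind="stable")  # stable keeps symbol order
        ranks[i, order] = positions
    return pd.DataFrame(ranks, index=ordered.index, columns=ordered.columns)


@dataclass(frozen=True)
class CompoundTargetScoreMatrix:
    """Per-compound concordance scores and ranks over candidate genes."""

    scores: pd.DataFrame  # compounds x genes
    ranks: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ranks is None:
            object.__setattr__(self, "ranks", _rank_rows(self.scores))

    @classmethod
    def compute(
        cls,
        sim: pd.DataFrame,
        ppi: nx.Graph,
        drug_targets: Mapping[str, Iterable[str]],
        candidate_genes: Iterable[str],
        kernel: KernelFn = gaussian_kernel,
    ) -> "CompoundTargetScoreMatrix":
        candidates = sorted({normalize_symbol(g) for g in candidate_genes})
        if not candidates:
            raise ValueError("candidate gene set is empty")
        missing = [g for g in candidates if g not in ppi]
        if missing:
            raise KeyError(f"candidate genes not in the PPI network: {missing[:5]}")
        clo = closeness_matrix(ppi, drug_targets, drugs=list(sim.columns), kernel=kernel)
        return cls(scores=score_matrix(sim, clo.loc[candidates]))

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "CompoundTargetScoreMatrix":
        """Rebuild from the long-form (compound, gene, score, rank) table."""
        scores = table.pivot(index="compound", columns="gene", values="score")
        if scores.isna().any().any():
            raise ValueError("long-form profile table is not complete")
        scores.index.name = None
        scores.columns.name = None
        return cls(scores=scores)

    @property
    def compounds(self) -> list:
        return list(self.scores.index)

    def top_genes(self, compound: str, k: int) -> list[str]:
        """The ``k`` best-ranked genes for a compound, in rank order."""
        row = self.ranks.loc[compound]
        top = row[row <= k].sort_values()
        return list(top.index)

    def profile(self, compound: str) -> pd.DataFrame:
        """Full ranked profile (gene, score, rank) for one compound."""
        df = pd.DataFrame(
            {
                "gene": self.scores.columns,
                "score": self.scores.loc[compound].to_numpy(),
                "rank": self.ranks.loc[compound].reindex(self.scores.columns).to_numpy(),
            }
        )
        return df.sort_values("rank", ignore_index=True)

    def to_long(self) -> pd.DataFrame:
        """Long-form table (compound, gene, score, rank) for serialization."""
        frames = []
        for c in self.compounds:
            df = self.profile(c)
            df.insert(0, "compound", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def build_target_profile(
    compound: str,
    sim: pd.DataFrame,
    ppi: nx.Graph,
    drug_targets: Mapping[str, Iterable[str]],
    candidate_genes: Iterable[str],
    kernel: KernelFn = gaussian_kernel,
) -> pd.DataFrame:
    """Ranked putative-target profile of one compound over the candidates."""
    matrix = CompoundTargetScoreMatrix.compute(
        sim.loc[[compound]], ppi, drug_targets, candidate_genes, kernel
    )
    return matrix.profile(compound)


@dataclass(frozen=True)
class HerbPutativeTargets:
    """Per-herb putative target sets with per-gene hit counts."""

    targets: dict[str, frozenset]
    hits: dict[str, dict[str, int]]

    def all_targets(self) -> frozenset:
        out: set = set()
        for t in self.targets.values():
            out |= t
        return frozenset(out)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"herb": h, "gene": g, "hit_times": n}
            for h in sorted(self.hits)
            for g, n in sorted(self.hits[h].items())
        ]
        return pd.DataFrame(rows, columns=["herb", "gene", "hit_times"])


def call_putative_targets(
    herb: str,
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> tuple[frozenset, dict[str, int]]:
    """Union of the herb's compounds' top-``k`` genes, with hit counts.

    A gene's hit count is the number of the herb's compounds whose
    top-``k`` list contains it.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if herb not in herb_compounds:
        raise KeyError(f"unknown herb {herb!r}")
    compounds = herb_compounds[herb]
    if not compounds:
        raise ValueError(f"herb {herb!r} has no compounds")
    counter: Counter = Counter()
    for c in compounds:
        counter.update(profiles.top_genes(c, top_k))
    return frozenset(counter), dict(counter)


def call_all_putative_targets(
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> HerbPutativeTargets:
    """Putative-target calling for every herb."""
    targets, hits = {}, {}
    for herb in sorted(herb_compounds):
        t, h = call_putative_targets(herb, profiles, herb_compounds, top_k)
        targets[herb], hits[herb] = t, h
    return HerbPutativeTargets(targets=targets, hits=hits)
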