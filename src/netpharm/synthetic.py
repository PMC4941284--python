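"""Synthetic inputs with planted ground truth for the whole pipeline.

Real herb-formula studies rest on inputs that are rarely redistributable:
curated compound-drug chemical-similarity matrices, reference-drug target
maps, PPI snapshots, disease-gene lists and pathway collections.  This
module emulates all six inputs with controlled statistical structure:

* a PPI network (preferential-attachment or Erdős–Rényi);
* a reference pharmacopeia in which each compound's similarity row is
  built by mixing one planted target gene's network-closeness profile
  with noise, so the concordance between the two channels is tunable;
* a pathway collection with one *planted* pathway whose genes are the
  preferred planted targets of every herb's compounds;
* a disease-gene list overlapping the planted pathway at a set fraction.

Every quantity is a pure function of :class:`SyntheticConfig` (including
its seed), so downstream stages can be tested against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .scoring import closeness_matrix, _zscore_rows

_SALTS = {"ppi": 11, "gene_sets": 23, "pharmacopeia": 37, "disease": 53}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    ``signal_strength`` is the mixing weight between a planted target's
    standardized closeness profile and independent noise when building a
    compound's similarity row; at 1 (with ``noise_sd`` 0) the planted
    concordance is exactly 1, at 0 true pairs are indistinguishable from
    random pairs.  ``planted_target_fraction`` is the fraction of the
    planted pathway that compounds are anchored to;
    ``pathway_compound_fraction`` is the fraction of each herb's
    compounds anchored to planted-pathway genes (the rest get random
    off-pathway planted targets).
    """

    n_genes: int = 2000
    n_reference_drugs: int = 40
    n_herbs: int = 5
    compounds_per_herb: int = 12
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 25)
    ppi_model: str = "scale_free"
    ppi_mean_degree: float = 6.0
    planted_pathway_index: int = 0
    planted_target_fraction: float = 0.6
    pathway_compound_fraction: float = 0.8
    signal_strength: float = 0.9
    noise_sd: float = 0.1
    n_disease_genes: int = 31
    disease_overlap_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_reference_drugs": self.n_reference_drugs,
            "n_herbs": self.n_herbs,
            "compounds_per_herb": self.compounds_per_herb,
            "n_pathways": self.n_pathways,
            "n_disease_genes": self.n_disease_genes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError(
                f"pathway_size_range must satisfy 1 <= min <= max <= n_genes, got {self.pathway_size_range}"
            )
        if self.ppi_model not in ("scale_free", "erdos_renyi"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")
        if self.ppi_mean_degree <= 0:
            raise ValueError("ppi_mean_degree must be positive")
        if self.ppi_mean_degree > self.n_genes - 1:
            raise ValueError(
                "ppi_mean_degree exceeds n_genes - 1: graph would be degenerate"
            )
        if not 0 <= self.planted_pathway_index < self.n_pathways:
            raise ValueError("planted_pathway_index out of range")
        for name in ("planted_target_fraction", "disease_overlap_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.pathway_compound_fraction <= 1:
            raise ValueError("pathway_compound_fraction must be in [0, 1]")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _SALTS[stage]])
        )

    def int_seed(self, stage: str) -> int:
        return int(self.rng(stage).integers(0, 2**31 - 1))


def gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_ppi(config: SyntheticConfig) -> nx.Graph:
    """Undirected simple PPI-like graph over synthetic gene symbols."""
    n, md = config.n_genes, config.ppi_mean_degree
    seed = config.int_seed("ppi")
    if config.ppi_model == "scale_free":
        m = min(max(1, round(md / 2)), n - 1)
        graph = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        p = min(1.0, md / (n - 1)) if n > 1 else 0.0
        graph = nx.gnp_random_graph(n, p, seed=seed)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    mapping = dict(zip(range(n), gene_symbols(n)))
    return nx.relabel_nodes(graph, mapping)


def generate_gene_sets(config: SyntheticConfig, ppi: nx.Graph) -> GeneSetCollection:
    """Pathway collection with sizes uniform in ``pathway_size_range``."""
    rng = config.rng("gene_sets")
    genes = np.array(sorted(ppi.nodes()))
    lo, hi = config.pathway_size_range
    width = max(2, len(str(config.n_pathways)))
    sets = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"PW{i + 1:0{width}d}"] = frozenset(members.tolist())
    return GeneSetCollection(sets=sets)


def planted_pathway_name(config: SyntheticConfig) -> str:
    width = max(2, len(str(config.n_pathways)))
    return f"PW{config.planted_pathway_index + 1:0{width}d}"


def _minmax_rows(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.full_like(values, 0.5, dtype=float)
    np.divide(values - lo, span, out=out, where=span > 0)
    return out


def generate_reference_pharmacopeia(
    config: SyntheticConfig, ppi: nx.Graph, gene_sets: GeneSetCollection
) -> tuple[dict[str, frozenset], pd.DataFrame, dict[str, list[str]], frozenset]:
    """Reference drugs, compound×drug similarity, herb membership, and truth.

    Returns ``(drug_targets, similarity, herb_compounds, true_pairs)``.
    Each compound carries exactly one planted target; its similarity row
    is ``signal_strength * z(closeness of the target) +
    sqrt(1 - signal_strength**2) * eta + noise_sd * eps`` (``eta``,
    ``eps`` i.i.d. standard normal per drug), min-max rescaled into
    [0, 1] — a positive affine map, so planted Pearson concordance is
    preserved.
    """
    rng = config.rng("pharmacopeia")
    genes = sorted(ppi.nodes())
    gene_arr = np.array(genes)

    drugs = [f"D{i + 1:03d}" for i in range(config.n_reference_drugs)]
    drug_targets: dict[str, frozenset] = {}
    for d in drugs:
        size = int(rng.integers(1, 6))
        drug_targets[d] = frozenset(rng.choice(gene_arr, size=size, replace=False).tolist())

    clo = closeness_matrix(ppi, drug_targets, drugs=drugs)
    z = _zscore_rows(clo.to_numpy(dtype=float))
    zrow = dict(zip(clo.index, z))
    informative = {g for g, row in zrow.items() if row.any()}

    pathway = sorted(gene_sets.sets[planted_pathway_name(config)])
    pathway_pool = [g for g in pathway if g in informative] or pathway
    n_path_slots = round(config.pathway_compound_fraction * config.compounds_per_herb)
    # Every planted target is anchored once by every herb ("common targets"
    # of the formula), which caps the planted set at the per-herb slot count.
    n_true = min(
        len(pathway_pool),
        max(1, round(config.planted_target_fraction * len(pathway))),
        max(1, n_path_slots),
    )
    # Planted targets are the best-connected pathway members: druggable,
    # well-studied targets sit on well-connected proteins, and a target
    # with no interactions cannot look topologically important.
    by_degree = sorted(pathway_pool, key=lambda g: (-ppi.degree(g), g))
    true_genes = sorted(by_degree[:n_true])
    off_pathway = [g for g in genes if g not in set(pathway) and g in informative]

    herbs = [f"HERB{i + 1}" for i in range(config.n_herbs)]
    herb_compounds: dict[str, list[str]] = {}
    anchors: dict[str, str] = {}
    n_drugs = len(drugs)
    idx = 0
    sim_rows, compounds = [], []
    for h, herb in enumerate(herbs):
        herb_compounds[herb] = []
        for j in range(config.compounds_per_herb):
            idx += 1
            compound = f"CMP{idx:04d}"
            herb_compounds[herb].append(compound)
            if j < n_path_slots:
                # per-herb offset so the whole planted set is anchored even
                # when it is larger than one herb's slot count
                anchor = true_genes[(j + h * n_path_slots) % n_true]
            else:
                anchor = str(rng.choice(np.array(off_pathway)))
            anchors[compound] = anchor
            s = config.signal_strength
            raw = (
                s * zrow[anchor]
                + np.sqrt(max(0.0, 1.0 - s * s)) * rng.standard_normal(n_drugs)
                + config.noise_sd * rng.standard_normal(n_drugs)
            )
            sim_rows.append(raw)
            compounds.append(compound)
    sim = pd.DataFrame(
        _minmax_rows(np.asarray(sim_rows)), index=compounds, columns=drugs
    )
    true_pairs = frozenset(anchors.items())
    return drug_targets, sim, herb_compounds, true_pairs


def generate_disease_genes(
    config: SyntheticConfig, ppi: nx.Graph, gene_sets: GeneSetCollection
) -> list[str]:
    """Known disease genes, a set fraction drawn from the planted pathway."""
    rng = config.rng("disease")
    pathway = sorted(gene_sets.sets[planted_pathway_name(config)])
    n_overlap = min(
        len(pathway),
        config.n_disease_genes,
        round(config.disease_overlap_fraction * config.n_disease_genes),
    )
    picked = set(rng.choice(np.array(pathway), size=n_overlap, replace=False).tolist())
    others = np.array([g for g in sorted(ppi.nodes()) if g not in set(pathway)])
    n_rest = config.n_disease_genes - n_overlap
    picked |= set(rng.choice(others, size=n_rest, replace=False).tolist())
    return sorted(picked)


@dataclass(frozen=True)
class SyntheticBundle:
    """All six pipeline inputs plus the planted ground truth."""

    config: SyntheticConfig
    ppi: nx.Graph
    gene_sets: GeneSetCollection
    drug_targets: dict[str, frozenset]
    similarity: pd.DataFrame
    herb_compounds: dict[str, list[str]]
    disease_genes: list[str]
    true_pairs: frozenset = field(repr=False)

    @property
    def planted_pathway(self) -> str:
        return planted_pathway_name(self.config)

    @property
    def true_genes(self) -> frozenset:
        return frozenset(g for _, g in self.true_pairs)

    def truth_record(self) -> dict:
        return {
            "planted_pathway": self.planted_pathway,
            "true_pairs": sorted(self.true_pairs),
            "true_genes": sorted(self.true_genes),
            "disease_genes": self.disease_genes,
        }


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full input bundle deterministically from the config."""
    ppi = generate_ppi(config)
    gene_sets = generate_gene_sets(config, ppi)
    drug_targets, sim, herb_compounds, true_pairs = generate_reference_pharmacopeia(
        config, ppi, gene_sets
    )
    disease = generate_disease_genes(config, ppi, gene_sets)
    return SyntheticBundle(
        config=config,
        ppi=ppi,
        gene_sets=gene_sets,
        drug_targets=drug_targets,
        similarity=sim,
        herb_compounds=herb_compounds,
        disease_genes=disease,
        true_pairs=true_pairs,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize the six inputs (plus truth) to plain-text files."""
    from . import io as npio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi_edges.tsv",
        "ppi_sif": outdir / "ppi.sif",
        "similarity": outdir / "similarity.tsv",
        "drug_targets": outdir / "drug_targets.tsv",
        "herb_compounds": outdir / "herb_compounds.tsv",
        "disease_genes": outdir / "disease_genes.txt",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    npio.write_ppi_edgelist(bundle.ppi, paths["ppi"])
    npio.write_sif(bundle.ppi, paths["ppi_sif"])
    npio.write_similarity(bundle.similarity, paths["similarity"])
    npio.write_drug_targets(bundle.drug_targets, paths["drug_targets"])
    npio.write_herb_compounds(bundle.herb_compounds, paths["herb_compounds"])
    npio.write_gene_list(bundle.disease_genes, paths["disease_genes"])
    bundle.gene_sets.to_gmt(paths["gene_sets"])
    paths["truth"].write_text(
        json.dumps(bundle.truth_record(), indent=2, sort_keys=True) + "\n"
    )
    config_path = outdir / "synthetic_config.json"
    config_path.write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=2, sort_keys=True) + "\n"
    )
    paths["config"] = config_path
    return paths
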