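"""End-to-end orchestration: inputs → scoring → network → topology →
enrichment → reliability, with a deterministic JSON run report.

The pipeline consumes either a :class:`~netpharm.synthetic.SyntheticConfig`
(inputs are generated and written alongside the results) or a directory
of user-supplied input files in the formats written by
:mod:`netpharm.io`.  Every stage writes its artifact so that downstream
stages can be re-run from serialized intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io as npio
from .enrichment import GeneSetCollection, enrich
from .network import GENE_ROLES, TripartiteNetwork, assemble, summarize
from .reliability import reliability_table, write_reliability
from .scoring import CompoundTargetScoreMatrix, call_all_putative_targets
from .synthetic import SyntheticConfig, generate_bundle, write_bundle
from .topology import (
    CLOSENESS_VARIANTS,
    compute_topology,
    major_node_report,
    median_thresholds,
    write_topology,
)

logger = logging.getLogger(__name__)

INPUT_FILES = {
    "ppi": "ppi_edges.tsv",
    "similarity": "similarity.tsv",
    "drug_targets": "drug_targets.tsv",
    "herb_compounds": "herb_compounds.tsv",
    "disease_genes": "disease_genes.txt",
    "gene_sets": "gene_sets.gmt",
}


@dataclass(frozen=True)
class PipelineInputs:
    """In-memory form of the six pipeline inputs (plus optional truth)."""

    ppi: nx.Graph
    gene_sets: GeneSetCollection
    drug_targets: dict[str, frozenset]
    similarity: pd.DataFrame
    herb_compounds: dict[str, list[str]]
    disease_genes: list[str]
    truth: dict | None = None


def load_inputs(input_dir: str | Path) -> PipelineInputs:
    d = Path(input_dir)
    missing = [f for f in INPUT_FILES.values() if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"input directory {d} is missing {missing}")
    truth_path = d / "truth.json"
    return PipelineInputs(
        ppi=npio.read_ppi_edgelist(d / INPUT_FILES["ppi"]),
        gene_sets=GeneSetCollection.from_gmt(d / INPUT_FILES["gene_sets"]),
        drug_targets=npio.read_drug_targets(d / INPUT_FILES["drug_targets"]),
        similarity=npio.read_similarity(d / INPUT_FILES["similarity"]),
        herb_compounds=npio.read_herb_compounds(d / INPUT_FILES["herb_compounds"]),
        disease_genes=npio.read_gene_list(d / INPUT_FILES["disease_genes"]),
        truth=json.loads(truth_path.read_text()) if truth_path.exists() else None,
    )


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.  Exactly one of ``synthetic``/``input_dir``."""

    out_dir: str | Path
    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None
    top_k: int = 25
    closeness_variant: str = "harmonic"
    betweenness_normalized: bool = False
    eligible_roles: tuple[str, ...] = GENE_ROLES
    universe_mode: str = "collection"
    significance_alpha: float = 0.05
    n_reliability_targets: int = 6

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of synthetic config or input_dir")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.closeness_variant not in CLOSENESS_VARIANTS:
            raise ValueError(f"unknown closeness_variant {self.closeness_variant!r}")
        if self.universe_mode not in ("collection", "ppi"):
            raise ValueError("universe_mode must be 'collection' or 'ppi'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            synth = SyntheticConfig(**synth)
        if "eligible_roles" in raw:
            raw["eligible_roles"] = tuple(raw["eligible_roles"])
        raw.update(overrides)
        return cls(synthetic=synth, **raw)

    def echo(self) -> dict:
        """Config echo for the run report (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("input_dir")
        d["eligible_roles"] = sorted(self.eligible_roles)
        return d


def _bundle_inputs(config: RunConfig, out_dir: Path) -> PipelineInputs:
    if config.synthetic is not None:
        bundle = generate_bundle(config.synthetic)
        write_bundle(bundle, out_dir / "inputs")
        return PipelineInputs(
            ppi=bundle.ppi,
            gene_sets=bundle.gene_sets,
            drug_targets=bundle.drug_targets,
            similarity=bundle.similarity,
            herb_compounds=bundle.herb_compounds,
            disease_genes=bundle.disease_genes,
            truth=bundle.truth_record(),
        )
    return load_inputs(config.input_dir)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write all artifacts, return the run report.

    The report is also written to ``<out_dir>/report.json``; identical
    configuration (and seed, for synthetic inputs) yields byte-identical
    reports.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = _bundle_inputs(config, out_dir)

    # -- scoring -------------------------------------------------------
    candidates = sorted(inputs.ppi.nodes())
    profiles = CompoundTargetScoreMatrix.compute(
        inputs.similarity, inputs.ppi, inputs.drug_targets, candidates
    )
    profiles.to_long().to_csv(
        out_dir / "profiles.tsv", sep="\t", index=False, float_format="%.10g"
    )
    herb_targets = call_all_putative_targets(
        profiles, inputs.herb_compounds, config.top_k
    )
    herb_targets.to_table().to_csv(out_dir / "herb_targets.tsv", sep="\t", index=False)

    # -- network assembly ---------------------------------------------
    network = assemble(herb_targets, inputs.disease_genes, inputs.ppi)
    network.to_files(out_dir / "network_edges.tsv", out_dir / "network_nodes.tsv")
    network.to_sif(out_dir / "network.sif")
    composition = summarize(network)
    logger.info(
        "network: %d nodes (%d putative, %d known, %d overlap), %d dropped known genes",
        composition["nodes_total"],
        composition["putative_targets"],
        composition["known_disease_targets"],
        composition["overlap"],
        len(network.dropped_known),
    )

    # -- topology and major nodes -------------------------------------
    topo = compute_topology(
        network,
        closeness_variant=config.closeness_variant,
        betweenness_normalized=config.betweenness_normalized,
    )
    thresholds = median_thresholds(topo)
    major = major_node_report(topo, thresholds, config.eligible_roles)
    write_topology(topo, thresholds, major["major_nodes"], out_dir / "topology.tsv")
    (out_dir / "thresholds.json").write_text(
        json.dumps(thresholds.as_dict(), indent=2, sort_keys=True) + "\n"
    )

    # -- enrichment ----------------------------------------------------
    universe = sorted(inputs.ppi.nodes()) if config.universe_mode == "ppi" else None
    collection = (
        GeneSetCollection(sets=inputs.gene_sets.sets, universe=frozenset(universe))
        if universe is not None
        else inputs.gene_sets
    )
    enrichment = enrich(
        major["major_nodes"], collection, alpha=config.significance_alpha
    )
    enrichment.to_csv(
        out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # -- reliability of the top pathway's major genes ------------------
    reliability_targets: list[str] = []
    if len(enrichment):
        top_pathway = enrichment.iloc[0]["pathway"]
        members = collection.sets[top_pathway]
        reliability_targets = sorted(members & set(major["major_nodes"]))[
            : config.n_reliability_targets
        ]
    if reliability_targets:
        rel = reliability_table(
            reliability_targets, profiles, inputs.herb_compounds, config.top_k
        )
        write_reliability(
            rel, out_dir / "reliability.tsv", out_dir / "reliability_table.txt"
        )

    # -- report --------------------------------------------------------
    significant = enrichment[enrichment["significant"]]
    report = {
        "config": config.echo(),
        "composition": composition,
        "medians": thresholds.as_dict(),
        "major_nodes": {k: v for k, v in major.items() if k != "thresholds"},
        "enrichment": {
            "n_pathways_tested": len(inputs.gene_sets.sets),
            "n_with_overlap": int(len(enrichment)),
            "significant": [
                {
                    "pathway": r["pathway"],
                    "k": int(r["k"]),
                    "K": int(r["K"]),
                    "p_raw": float(r["p_raw"]),
                    "p_bonf": float(r["p_bonf"]),
                }
                for _, r in significant.iterrows()
            ],
        },
        "reliability_targets": reliability_targets,
    }
    if inputs.truth is not None:
        planted = inputs.truth["planted_pathway"]
        ranked = list(enrichment["pathway"])
        report["truth_check"] = {
            "planted_pathway": planted,
            "planted_rank": (ranked.index(planted) + 1) if planted in ranked else None,
            "planted_significant": bool(
                planted in set(significant["pathway"])
            ),
        }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
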