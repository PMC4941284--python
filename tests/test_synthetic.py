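"""Contracts of the synthetic input generator: determinism, graph shape,
similarity ranges, planted-signal behaviour, and disease-gene overlap."""

import networkx as nx
import numpy as np
import pytest

from netpharm import SyntheticConfig, generate_bundle
from netpharm.scoring import CompoundTargetScoreMatrix, closeness_matrix, score_matrix
from netpharm.synthetic import (
    generate_disease_genes,
    generate_gene_sets,
    generate_ppi,
    planted_pathway_name,
)


def small(**kw):
    base = dict(
        n_genes=150,
        n_reference_drugs=12,
        n_herbs=2,
        compounds_per_herb=4,
        n_pathways=5,
        pathway_size_range=(6, 10),
        ppi_mean_degree=4.0,
        n_disease_genes=10,
        seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 0},
            {"n_herbs": 0},
            {"pathway_size_range": (5, 200)},
            {"pathway_size_range": (8, 6)},
            {"ppi_model": "smallworld"},
            {"ppi_mean_degree": 0.0},
            {"ppi_mean_degree": 150.0},
            {"planted_pathway_index": 5},
            {"planted_target_fraction": 0.0},
            {"signal_strength": 1.5},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small(**kw)

    def test_mean_degree_equal_n_minus_1_is_complete_graph(self):
        cfg = SyntheticConfig(
            n_genes=4,
            ppi_model="erdos_renyi",
            ppi_mean_degree=3.0,
            n_pathways=1,
            pathway_size_range=(2, 3),
            n_disease_genes=2,
            seed=0,
        )
        g = generate_ppi(cfg)
        assert g.number_of_edges() <= 6
        assert nx.number_of_selfloops(g) == 0


class TestPPI:
    def test_simple_graph_and_giant_component(self):
        g = generate_ppi(small(n_genes=300, ppi_mean_degree=6.0))
        assert nx.number_of_selfloops(g) == 0
        giant = max(nx.connected_components(g), key=len)
        assert len(giant) >= 0.8 * g.number_of_nodes()

    def test_same_seed_identical_edges(self):
        g1 = generate_ppi(small())
        g2 = generate_ppi(small())
        assert sorted(map(sorted, g1.edges())) == sorted(map(sorted, g2.edges()))

    def test_scale_free_has_hubs(self):
        cfg = small(n_genes=200, ppi_model="scale_free", ppi_mean_degree=6.0, seed=7)
        g = generate_ppi(cfg)
        degrees = [d for _, d in g.degree()]
        assert max(degrees) > 3 * np.mean(degrees)

    def test_erdos_renyi_model_supported(self):
        g = generate_ppi(small(ppi_model="erdos_renyi"))
        assert g.number_of_nodes() == 150


class TestGeneSets:
    def test_sizes_and_universe_closure(self):
        cfg = small()
        ppi = generate_ppi(cfg)
        gs = generate_gene_sets(cfg, ppi)
        genes = set(ppi.nodes())
        lo, hi = cfg.pathway_size_range
        assert len(gs.sets) == cfg.n_pathways
        for members in gs.sets.values():
            assert lo <= len(members) <= hi
            assert members <= genes

    def test_single_pathway_exact_size(self):
        cfg = small(n_pathways=1, pathway_size_range=(5, 5))
        gs = generate_gene_sets(cfg, generate_ppi(cfg))
        (members,) = gs.sets.values()
        assert len(members) == 5

    def test_seed_determinism_and_variation(self):
        cfg1, cfg2 = small(seed=1), small(seed=2)
        ppi1, ppi2 = generate_ppi(cfg1), generate_ppi(cfg2)
        assert generate_gene_sets(cfg1, ppi1).sets == generate_gene_sets(cfg1, ppi1).sets
        assert generate_gene_sets(cfg1, ppi1).sets != generate_gene_sets(cfg2, ppi2).sets


class TestPharmacopeia:
    def test_similarity_in_unit_interval(self, small_bundle):
        values = small_bundle.similarity.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_each_drug_has_1_to_5_targets(self, small_bundle):
        for targets in small_bundle.drug_targets.values():
            assert 1 <= len(targets) <= 5

    def test_bundle_determinism(self, small_config, small_bundle):
        other = generate_bundle(small_config)
        assert other.true_pairs == small_bundle.true_pairs
        assert other.similarity.equals(small_bundle.similarity)
        assert other.disease_genes == small_bundle.disease_genes
        assert sorted(map(sorted, other.ppi.edges())) == sorted(
            map(sorted, small_bundle.ppi.edges())
        )

    def test_perfect_signal_gives_unit_concordance(self):
        bundle = generate_bundle(small(signal_strength=1.0, noise_sd=0.0))
        profiles = CompoundTargetScoreMatrix.compute(
            bundle.similarity, bundle.ppi, bundle.drug_targets, sorted(bundle.ppi.nodes())
        )
        for compound, gene in bundle.true_pairs:
            assert profiles.scores.loc[compound, gene] == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_true_pairs_look_random(self):
        """At signal_strength 0 the planted pairs score like random pairs."""
        rng = np.random.default_rng(0)
        deltas = []
        for seed in range(50):
            bundle = generate_bundle(small(signal_strength=0.0, seed=seed))
            clo = closeness_matrix(bundle.ppi, bundle.drug_targets)
            scores = score_matrix(bundle.similarity, clo)
            true_mean = np.mean(
                [scores.loc[c, g] for c, g in bundle.true_pairs]
            )
            rand_mean = np.mean(
                [
                    scores.iloc[
                        rng.integers(scores.shape[0]), rng.integers(scores.shape[1])
                    ]
                    for _ in range(len(bundle.true_pairs))
                ]
            )
            deltas.append(true_mean - rand_mean)
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 2 * se

    def test_mean_true_concordance_monotone_in_signal(self):
        means = []
        for s in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in range(20):
                bundle = generate_bundle(small(signal_strength=s, seed=seed))
                clo = closeness_matrix(bundle.ppi, bundle.drug_targets)
                scores = score_matrix(bundle.similarity, clo)
                vals += [scores.loc[c, g] for c, g in bundle.true_pairs]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestDiseaseGenes:
    def test_overlap_fraction_respected(self):
        cfg = small(n_disease_genes=10, disease_overlap_fraction=0.4)
        ppi = generate_ppi(cfg)
        gs = generate_gene_sets(cfg, ppi)
        disease = generate_disease_genes(cfg, ppi, gs)
        pathway = gs.sets[planted_pathway_name(cfg)]
        overlap = len(set(disease) & pathway)
        assert len(disease) == 10
        assert abs(overlap - round(0.4 * 10)) <= 1
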