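"""Concordance scoring: closeness kernel, Pearson correctness and its
invariances, profile ranking, and top-k putative-target calling."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.scoring import (
    CompoundTargetScoreMatrix,
    build_target_profile,
    call_putative_targets,
    closeness_matrix,
    concordance_score,
    gene_drug_closeness,
    score_matrix,
)
from oracles import pearson_oracle


def sim_frame(rows: dict, drugs: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=drugs, dtype=float)


class TestGeneDrugCloseness:
    def test_sole_target_gene_scores_one(self, path_graph):
        assert gene_drug_closeness("A", "d1", path_graph, {"d1": {"A"}}) == 1.0

    def test_path_distance_two(self, path_graph):
        value = gene_drug_closeness("A", "d1", path_graph, {"d1": {"C"}})
        assert value == pytest.approx(math.exp(-4), rel=1e-12)

    def test_disconnected_component_scores_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_edge("X", "Y")
        assert gene_drug_closeness("A", "d1", g, {"d1": {"X"}}) == 0.0

    def test_multiple_targets_sum(self, path_graph):
        value = gene_drug_closeness("B", "d1", path_graph, {"d1": {"A", "C"}})
        assert value == pytest.approx(2 * math.exp(-1), rel=1e-12)

    def test_drug_without_network_targets_raises(self, path_graph):
        with pytest.raises(ValueError, match="d1"):
            gene_drug_closeness("A", "d1", path_graph, {"d1": {"ZZZ"}})

    def test_matrix_matches_scalar_path(self, small_bundle):
        clo = closeness_matrix(small_bundle.ppi, small_bundle.drug_targets)
        drug = clo.columns[0]
        for gene in list(clo.index)[:10]:
            scalar = gene_drug_closeness(
                gene, drug, small_bundle.ppi, small_bundle.drug_targets
            )
            assert clo.loc[gene, drug] == pytest.approx(scalar, rel=1e-12)


class TestConcordance:
    def setup_method(self):
        # 4-node path: distances from A are 0,1,2,3
        self.g = nx.path_graph(["A", "B", "C", "D"])

    def test_proportional_channels_score_one(self):
        drug_targets = {"d1": {"A"}, "d2": {"B"}, "d3": {"C"}}
        clo = closeness_matrix(self.g, drug_targets, drugs=["d1", "d2", "d3"])
        sim = sim_frame({"c": list(2.0 * clo.loc["A"] + 0.25)}, ["d1", "d2", "d3"])
        score = concordance_score("c", "A", sim, self.g, drug_targets)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_constant_closeness_scores_zero(self):
        # gene B is at distance 1 from both A and C: constant channel
        drug_targets = {"d1": {"A"}, "d2": {"C"}, "d3": {"A"}}
        sim = sim_frame({"c": [0.9, 0.1, 0.4]}, ["d1", "d2", "d3"])
        assert concordance_score("c", "B", sim, self.g, drug_targets) == 0.0

    def test_matches_textbook_oracle(self):
        drug_targets = {"d1": {"A"}, "d2": {"B"}, "d3": {"D"}}
        sim = sim_frame({"c": [0.9, 0.1, 0.5]}, ["d1", "d2", "d3"])
        y = [
            gene_drug_closeness("C", d, self.g, drug_targets)
            for d in ("d1", "d2", "d3")
        ]
        expected = pearson_oracle([0.9, 0.1, 0.5], y)
        score = concordance_score("c", "C", sim, self.g, drug_targets)
        assert score == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_drugs_rejected(self):
        sim = sim_frame({"c": [0.9, 0.1]}, ["d1", "d2"])
        with pytest.raises(ValueError, match="3 reference drugs"):
            concordance_score("c", "A", sim, self.g, {"d1": {"A"}, "d2": {"B"}})

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-10, max_value=10),
    )
    def test_invariant_under_positive_affine_transform(self, a, b):
        drug_targets = {"d1": {"A"}, "d2": {"B"}, "d3": {"D"}, "d4": {"C"}}
        drugs = ["d1", "d2", "d3", "d4"]
        base = [0.9, 0.1, 0.5, 0.3]
        sim0 = sim_frame({"c": base}, drugs)
        sim1 = sim_frame({"c": [a * x + b for x in base]}, drugs)
        s0 = concordance_score("c", "B", sim0, self.g, drug_targets)
        s1 = concordance_score("c", "B", sim1, self.g, drug_targets)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_vectorized_matrix_matches_scalar_scores(self, small_bundle):
        """Dual route: dense matrix equals the per-pair scalar computation."""
        clo = closeness_matrix(small_bundle.ppi, small_bundle.drug_targets)
        scores = score_matrix(small_bundle.similarity, clo)
        rng = np.random.default_rng(1)
        genes = list(scores.columns)
        for compound in list(scores.index)[:3]:
            for gene in rng.choice(genes, size=8, replace=False):
                scalar = concordance_score(
                    compound,
                    gene,
                    small_bundle.similarity,
                    small_bundle.ppi,
                    small_bundle.drug_targets,
                )
                assert scores.loc[compound, gene] == pytest.approx(scalar, abs=1e-12)


class TestProfiles:
    def make_profiles(self, score_rows: dict, genes: list[str]):
        scores = pd.DataFrame.from_dict(
            score_rows, orient="index", columns=genes, dtype=float
        )
        return CompoundTargetScoreMatrix(scores=scores)

    def test_ranks_are_descending_scores(self):
        p = self.make_profiles({"c": [0.3, 0.8]}, ["G001", "G002"])
        prof = p.profile("c")
        assert list(prof["gene"]) == ["G002", "G001"]
        assert list(prof["rank"]) == [1, 2]

    def test_ties_broken_by_symbol_ascending(self):
        p = self.make_profiles({"c": [0.5, 0.5]}, ["G002", "G001"])
        assert p.ranks.loc["c", "G001"] == 1
        assert p.ranks.loc["c", "G002"] == 2

    def test_ranks_are_a_permutation(self, small_profiles):
        for compound in small_profiles.compounds[:3]:
            ranks = sorted(small_profiles.ranks.loc[compound])
            assert ranks == list(range(1, len(ranks) + 1))

    def test_profile_covers_all_candidates(self, small_bundle):
        candidates = sorted(small_bundle.ppi.nodes())[:40]
        compound = small_bundle.similarity.index[0]
        prof = build_target_profile(
            compound,
            small_bundle.similarity,
            small_bundle.ppi,
            small_bundle.drug_targets,
            candidates,
        )
        assert len(prof) == len(candidates)

    def test_empty_candidates_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="empty"):
            build_target_profile(
                small_bundle.similarity.index[0],
                small_bundle.similarity,
                small_bundle.ppi,
                small_bundle.drug_targets,
                [],
            )

    def test_long_form_round_trip(self, small_profiles):
        rebuilt = CompoundTargetScoreMatrix.from_long(small_profiles.to_long())
        pd.testing.assert_frame_equal(
            rebuilt.ranks, small_profiles.ranks, check_like=True
        )


class TestTargetCalling:
    def make_profiles(self, score_rows, genes):
        scores = pd.DataFrame.from_dict(
            score_rows, orient="index", columns=genes, dtype=float
        )
        return CompoundTargetScoreMatrix(scores=scores)

    def test_single_compound_top2(self):
        p = self.make_profiles({"c1": [0.9, 0.5, 0.1]}, ["A", "B", "C"])
        targets, hits = call_putative_targets("h", p, {"h": ["c1"]}, top_k=2)
        assert targets == {"A", "B"}
        assert hits == {"A": 1, "B": 1}

    def test_shared_best_gene_hit_count(self):
        p = self.make_profiles(
            {"c1": [0.9, 0.1], "c2": [0.8, 0.2]}, ["G", "X"]
        )
        targets, hits = call_putative_targets("h", p, {"h": ["c1", "c2"]}, top_k=1)
        assert targets == {"G"}
        assert hits == {"G": 2}

    def test_unknown_herb_rejected(self, small_profiles, small_bundle):
        with pytest.raises(KeyError, match="nosuchherb"):
            call_putative_targets(
                "nosuchherb", small_profiles, small_bundle.herb_compounds, 5
            )

    def test_planted_targets_rank_high(self, small_bundle, small_profiles):
        n = small_profiles.ranks.shape[1]
        pcts = [
            small_profiles.ranks.loc[c, g] / n for c, g in small_bundle.true_pairs
        ]
        assert np.median(pcts) <= 0.10
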