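import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cofrac.network import (DegenerateDegreeError, build_network,
                            degree_powerlaw_fit, edge_type_counts,
                            enrichment_log2fc, genomic_distance,
                            neighborhood_query, roc_threshold,
                            simulate_scalefree_graph)
from cofrac.simulate import simulate_gene_annotation, simulate_virion_experiment


class TestDegreePowerlawFit:
    def test_exact_inverse_square_frequencies(self):
        # degrees {1,2,4,8} with counts 64,16,4,1: frequency exactly k^-2 * 64
        degs = [8] + [4] * 4 + [2] * 16 + [1] * 64
        g = nx.havel_hakimi_graph(degs)
        exponent, r2 = degree_powerlaw_fit(g)
        assert exponent == pytest.approx(2.0, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_star_graph_runs_with_small_support_warning(self):
        g = nx.star_graph(5)  # degrees {5: 1, 1: 5}
        with pytest.warns(UserWarning, match="fewer than 3"):
            exponent, r2 = degree_powerlaw_fit(g)
        assert exponent == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_complete_graph_is_degenerate(self):
        with pytest.raises(DegenerateDegreeError):
            degree_powerlaw_fit(nx.complete_graph(6))

    def test_recovers_planted_exponent_on_scalefree_graph(self):
        g = simulate_scalefree_graph(gamma=2.2, seed=0)
        exponent, r2 = degree_powerlaw_fit(g)
        assert exponent == pytest.approx(2.2, abs=0.3)
        assert r2 > 0.9


class TestGenomicDistance:
    def annotation(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"],
            "start": [1000, 5000, 40000],
            "end": [1900, 5900, 40900],
            "strand": ["+", "-", "+"],
            "genome_id": ["phage", "phage", "other"],
            "genome_length": [280000, 280000, 50000],
        })

    def test_start_to_start_distance_in_kb(self):
        pairs = pd.DataFrame({"protein_a": ["g1"], "protein_b": ["g2"]})
        out, skipped = genomic_distance(pairs, self.annotation())
        assert out["distance_kb"][0] == pytest.approx(4.0)
        assert skipped == 0

    def test_cross_genome_and_unannotated_pairs_skipped(self):
        pairs = pd.DataFrame({"protein_a": ["g1", "g1"], "protein_b": ["g3", "gX"]})
        with pytest.warns(UserWarning):
            out, skipped = genomic_distance(pairs, self.annotation())
        assert len(out) == 0
        assert skipped == 2

    def test_simulated_distances_match_hand_computation(self, default_bundle):
        truth = default_bundle["truth"]
        ann = simulate_gene_annotation(truth)
        phage = ann[ann["genome_id"] == "phage_genome"]["gene_id"].tolist()[:6]
        pairs = pd.DataFrame({"protein_a": phage[:3], "protein_b": phage[3:6]})
        out, _ = genomic_distance(pairs, ann)
        starts = ann.set_index("gene_id")["start"]
        expected = np.mean([abs(starts[a] - starts[b]) / 1000.0
                            for a, b in zip(phage[:3], phage[3:6])])
        assert out["distance_kb"].mean() == pytest.approx(expected, abs=1e-9)


class TestRocThreshold:
    def test_four_point_sweep_by_hand(self):
        result = roc_threshold([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert result.auc == pytest.approx(1.0)
        assert result.selected_threshold == pytest.approx(0.8)
        k = list(result.thresholds).index(0.8)
        assert result.tpr[k] == 1.0 and result.fpr[k] == 0.0

    def test_inverted_labels_give_zero_auc(self):
        result = roc_threshold([0.9, 0.8, 0.3, 0.2], [0, 0, 1, 1])
        assert result.auc == pytest.approx(0.0)

    def test_random_scores_chance_level(self):
        rng = np.random.default_rng(0)
        result = roc_threshold(rng.random(1000), rng.integers(0, 2, 1000))
        assert result.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        ours = roc_threshold(scores, labels).auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = roc_threshold(scores, labels).auc
        b = roc_threshold(np.exp(5 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([0.1, 0.2], [1, 1])

    def test_virion_enrichment_is_discriminative(self, default_bundle):
        vir = simulate_virion_experiment(default_bundle["truth"])
        result = roc_threshold(
            vir["enriched_intensity"] / vir["reference_intensity"], vir["is_virion"])
        assert result.auc > 0.8


class TestEnrichment:
    def test_equal_intensities_zero(self):
        e = pd.Series([10.0], index=["p"])
        assert enrichment_log2fc(e, e)["p"] == pytest.approx(0.0)

    def test_eightfold_enrichment(self):
        e = pd.Series([800.0, 100.0], index=["p", "q"])
        r = pd.Series([100.0, 100.0], index=["p", "q"])
        out = enrichment_log2fc(e, r)
        # pseudocount c = 50 shifts the pure ratio slightly
        assert out["p"] == pytest.approx(np.log2(850 / 150))

    def test_exact_threefold_without_pseudocount_distortion(self):
        e = pd.Series([8.0, 1e-9], index=["p", "tiny"])
        r = pd.Series([1.0, 1e-9], index=["p", "tiny"])
        out = enrichment_log2fc(e, r)
        assert out["p"] == pytest.approx(3.0, abs=1e-6)

    def test_protein_absent_in_reference_stays_finite(self):
        e = pd.Series([100.0, 4.0], index=["p", "q"])
        r = pd.Series([0.0, 4.0], index=["p", "q"])
        out = enrichment_log2fc(e, r)
        c = 2.0  # half the smallest nonzero intensity (4.0)
        assert out["p"] == pytest.approx(np.log2((100 + c) / c))
        assert np.isfinite(out["p"]) and out["p"] > 0


class TestNetworkStructure:
    def edges(self):
        return pd.DataFrame({
            "protein_a": ["h1", "h1", "v1", "h2"],
            "protein_b": ["h2", "v1", "v2", "v2"],
            "probability": [0.9, 0.8, 0.95, 0.6],
            "q_value": [0.0, 0.0, 0.0, 0.01],
        })

    def organism(self):
        return {"h1": "host", "h2": "host", "v1": "phage", "v2": "phage"}

    def test_edge_counts_partition_by_type(self):
        g = build_network(self.edges(), self.organism())
        counts = edge_type_counts(g)
        assert counts == {"host-host": 1, "host-phage": 2, "phage-phage": 1}
        assert sum(counts.values()) == g.number_of_edges()

    def test_self_loops_rejected(self):
        bad = pd.DataFrame({"protein_a": ["x"], "protein_b": ["x"],
                            "probability": [0.9], "q_value": [0.0]})
        with pytest.raises(ValueError):
            build_network(bad, {"x": "host"})

    def test_neighborhood_query_star(self):
        g = build_network(self.edges(), self.organism())
        star = neighborhood_query(g, "h1", min_probability=0.0)
        assert set(star.nodes) == {"h1", "h2", "v1"}
        assert star.number_of_edges() == 2

    def test_lower_probability_floor_expands_neighborhood(self):
        g = build_network(self.edges(), self.organism())
        strict = neighborhood_query(g, "v2", min_probability=0.75)
        loose = neighborhood_query(g, "v2", min_probability=0.5)
        assert set(strict.edges) <= set(loose.edges)
        assert loose.number_of_edges() > strict.number_of_edges()

    def test_unknown_protein_gives_empty_graph_with_warning(self):
        g = build_network(self.edges(), self.organism())
        with pytest.warns(UserWarning, match="nope"):
            star = neighborhood_query(g, "nope")
        assert star.number_of_nodes() == 0
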