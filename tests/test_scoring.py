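"""BC-ratio μ, permutation p_BC, seed-only scoring, correlations, ranking."""

import itertools

import numpy as np
import pytest

from netsuit import (
    DamageLabeling,
    betweenness,
    exact_permutation_p,
    metric_correlation,
    permutation_test,
    rank_genes,
    score_seed_only,
    suitability_ratio,
    summarize,
)
from netsuit.build import build_disease_network
from netsuit.centrality import CentralityVector
from netsuit.synth import make_graph, make_labeling

from conftest import labelled


def uniform_labeling(net, damaged):
    return DamageLabeling(
        {v: ("damaged" if v in damaged else "intact") for v in net.g},
        {v: ["fixture"] for v in damaged},
    )


class TestSuitabilityRatio:
    def test_central_damage_scores_one(self, star5):
        labelled(star5, {"G000"})
        assert suitability_ratio(betweenness(star5), star5.labels()) == 1.0

    def test_peripheral_damage_scores_zero(self, star5):
        labelled(star5, {"G001"})
        assert suitability_ratio(betweenness(star5), star5.labels()) == 0.0

    def test_all_damaged_scores_one_for_every_metric(self, path5):
        from netsuit.centrality import METRICS, compute

        labelled(path5, set(path5.nodes))
        for m in METRICS:
            assert suitability_ratio(compute(path5, m), path5.labels()) == pytest.approx(1.0)

    def test_path5_hand_computed_value(self, path5):
        # unnormalized betweenness of P5: 0, 3, 4, 3, 0
        labelled(path5, {"G001"})
        assert suitability_ratio(betweenness(path5), path5.labels()) == pytest.approx(0.3)

    def test_zero_total_mass_defined_as_zero(self):
        net = labelled(make_graph("path", 2), {"G000"})
        assert suitability_ratio(betweenness(net), net.labels()) == 0.0

    def test_unlabelled_node_is_an_error(self, star5):
        star5.g.nodes["G000"]["label"] = "damaged"
        with pytest.raises(ValueError, match="G001"):
            suitability_ratio(betweenness(star5), star5.labels())

    def test_invariant_to_rescaling(self, path5):
        labelled(path5, {"G001", "G002"})
        vec = betweenness(path5)
        scaled = CentralityVector(vec.metric, {v: 13.0 * x for v, x in vec.values.items()},
                                  vec.component_id, vec.normalized)
        assert suitability_ratio(scaled, path5.labels()) == pytest.approx(
            suitability_ratio(vec, path5.labels())
        )

    def test_label_flip_monotonicity_exhaustive_small(self):
        """Flipping intact→damaged never decreases μ (all labelings, n<=8)."""
        net = make_graph("erdos_renyi", 8, p=0.4, seed=2)
        vec = betweenness(net)
        nodes = sorted(net.g.nodes)
        for k in (1, 2):
            for damaged in itertools.combinations(nodes, k):
                labels = {v: ("damaged" if v in damaged else "intact") for v in nodes}
                mu = suitability_ratio(vec, labels)
                for v in nodes:
                    if labels[v] == "intact":
                        flipped = dict(labels, **{v: "damaged"})
                        assert suitability_ratio(vec, flipped) >= mu - 1e-12


class TestPermutationTest:
    def test_hub_damage_is_never_exceeded(self, star5):
        score = permutation_test(star5, uniform_labeling(star5, {"G000"}), n=1000, seed=7)
        assert score.mu == 1.0 and score.p_value == 0.0
        assert score.p_display == "<1/1000"
        assert score.p_conservative == pytest.approx(1 / 1001)

    def test_leaf_damage_p_near_one_fifth(self, star5):
        score = permutation_test(star5, uniform_labeling(star5, {"G001"}), n=10000, seed=3)
        assert score.mu == 0.0
        assert score.p_value == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / 10000))

    def test_matches_exact_enumeration(self):
        net = make_graph("erdos_renyi", 9, p=0.35, seed=5)
        lab = make_labeling(net, 3, mode="uniform", seed=11)
        exact = exact_permutation_p(net, lab)
        mc = permutation_test(net, lab, n=50_000, seed=13)
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / 50_000)
        assert mc.p_value == pytest.approx(exact, abs=max(3 * se, 1e-9))

    def test_constant_statistic_on_symmetric_graph(self):
        net = make_graph("cycle", 6)
        score = permutation_test(net, uniform_labeling(net, {"G000", "G003"}), n=500, seed=1)
        assert score.p_value == 0.0 and score.p_display == "<1/500"

    def test_degenerate_labeling_reports_p_one(self, star5):
        score = permutation_test(star5, uniform_labeling(star5, set(star5.nodes)), n=100, seed=1)
        assert score.mu == 1.0 and score.p_value == 1.0

    def test_reproducible_for_fixed_seed(self):
        net = make_graph("erdos_renyi", 20, p=0.2, seed=8)
        lab = make_labeling(net, 5, mode="uniform", seed=2)
        a = permutation_test(net, lab, n=2000, seed=99)
        b = permutation_test(net, lab, n=2000, seed=99)
        assert a == b

    def test_invalid_n_rejected(self, star5):
        with pytest.raises(ValueError):
            permutation_test(star5, uniform_labeling(star5, {"G000"}), n=0)

    def test_counts_respect_scope(self, two_components):
        labelled(two_components, {"A1", "B0"})
        score = permutation_test(two_components, None, metric="flow_betweenness", n=200, seed=4)
        assert score.scope == "largest_component"
        assert score.n_damaged + score.n_intact == 4  # the 4-path only

    def test_null_p_distribution_is_calibrated(self):
        """Exact p over random truth labelings is uniform on the achievable grid."""
        from scipy import stats

        net = make_graph("erdos_renyi", 12, p=0.3, seed=5)
        vec = betweenness(net)
        nodes = sorted(net.g.nodes)
        values = np.array([vec.values[v] for v in nodes])
        total = values.sum()
        k = 3
        sums = np.array([sum(values[list(c)]) for c in itertools.combinations(range(len(nodes)), k)])
        pop_p = np.array([(sums > s + 1e-15).mean() for s in sums])

        rng = np.random.default_rng(0)
        reps = rng.integers(0, len(sums), size=200)
        observed_p = pop_p[reps]

        edges = np.quantile(pop_p, np.linspace(0, 1, 6))
        edges[0], edges[-1] = -np.inf, np.inf
        obs_counts, _ = np.histogram(observed_p, bins=edges)
        exp_counts = np.array(
            [((pop_p > edges[i]) & (pop_p <= edges[i + 1])).mean() for i in range(5)]
        ) * 200
        gof = stats.chisquare(obs_counts, exp_counts * obs_counts.sum() / exp_counts.sum())
        assert gof.pvalue > 0.01


class TestSeedOnly:
    def test_all_seed_network_scores_one(self):
        bg = make_graph("erdos_renyi", 15, p=0.3, seed=1)
        net = build_disease_network(bg, sorted(bg.nodes), name="all")
        assert score_seed_only(net, n=50, seed=1).mu == pytest.approx(1.0)

    def test_two_node_expansion_has_zero_ratio(self):
        import networkx as nx
        from netsuit import PPINetwork

        g = nx.Graph([("a", "b"), ("b", "c")])
        nx.set_edge_attributes(g, 1.0, "confidence")
        bg = PPINetwork(g)
        net = build_disease_network(bg, ["a"])
        assert set(net.nodes) == {"a", "b"}
        assert score_seed_only(net, n=10, seed=1).mu == 0.0

    def test_missing_origins_rejected(self, star5):
        with pytest.raises(ValueError, match="origin"):
            score_seed_only(star5)


class TestMetricCorrelation:
    def test_unit_diagonal_and_symmetry(self):
        nets = [make_graph("erdos_renyi", 15, p=0.3, seed=s) for s in (1, 2)]
        table = metric_correlation(nets)
        assert np.allclose(np.diag(table.values), 1.0)
        assert np.allclose(table.values, table.values.T, equal_nan=True)

    def test_betweenness_flow_agree_exactly_on_trees(self):
        nets = [make_graph("tree", 20, seed=s) for s in range(3)]
        table = metric_correlation(nets)
        assert table.loc["betweenness", "flow_betweenness"] == pytest.approx(1.0, abs=1e-8)

    def test_constant_vector_excluded_with_warning(self, caplog):
        # cycle: every metric constant -> all off-diagonal pairs excluded
        table = metric_correlation([make_graph("cycle", 6)])
        assert np.isnan(table.loc["degree", "betweenness"])

    def test_spearman_flag(self):
        nets = [make_graph("barabasi_albert", 20, m=2, seed=3)]
        table = metric_correlation(nets, method="spearman")
        assert -1.0 <= table.loc["degree", "closeness"] <= 1.0


class TestRankGenes:
    def test_star_hub_ranks_first_everywhere(self, star5):
        df = rank_genes(star5)
        hub = df[df.gene == "G000"].iloc[0]
        assert all(hub[f"rank_{m}"] == 1 for m in
                   ("betweenness", "degree", "closeness", "flow_betweenness"))

    def test_path_middle_tops_both_betweenness_metrics(self, path5):
        df = rank_genes(path5)
        mid = df[df.gene == "G002"].iloc[0]
        assert mid.rank_betweenness == 1 and mid.rank_flow_betweenness == 1

    def test_ties_break_lexicographically(self, star5):
        df = rank_genes(star5)
        leaves = df[df.gene != "G000"].sort_values("rank_degree")
        assert list(leaves.gene) == sorted(leaves.gene)

    def test_top_k_truncates(self, path5):
        assert len(rank_genes(path5, top=3)) == 3


class TestSummarize:
    def test_connected_network_is_unflagged(self, star5):
        labelled(star5, {"G000"})
        df = summarize([star5], [None], n_permutations=100, seed=1)
        assert df.iloc[0].flow_bc_scope_flag == ""
        assert df.iloc[0].nodes_damaged == 1 and df.iloc[0].nodes_intact == 4

    def test_disconnected_network_flags_flow_scope(self, two_components):
        labelled(two_components, {"A1"})
        df = summarize([two_components], [None], n_permutations=100, seed=1)
        assert df.iloc[0].flow_bc_scope_flag == "*"

    def test_columns_round_trip_through_tsv(self, tmp_path, star5):
        import pandas as pd

        from netsuit.scoring import SUMMARY_COLUMNS

        labelled(star5, {"G000"})
        df = summarize([star5], [None], n_permutations=100, seed=1)
        f = tmp_path / "summary.tsv"
        df.to_csv(f, sep="\t", index=False)
        back = pd.read_csv(f, sep="\t")
        assert list(back.columns) == SUMMARY_COLUMNS
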