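"""Fold enrichment, function-prediction metrics, topology and trait density."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from coexnet import evalnet
from coexnet.evalnet import (
    EnrichmentInput,
    PredictionRecord,
    cafa_metrics,
    density_fold,
    enrichment_curve,
    fold_enrichment,
    guide_subnetwork,
    is_true_positive,
    neighborhood_enrichment,
    propagate_scores,
    topology_stats,
    trait_link_density,
)
from coexnet.goldstd import OntologyDAG
from coexnet.network import ScoredNetwork


class TestFoldEnrichment:
    def test_cell_cycle_motif_counts(self):
        # 33 of 1093 motif genes are among 180 cell-cycle genes of 55986
        fold = fold_enrichment(EnrichmentInput(33, 1093, 180, 55986))
        assert round(fold, 1) == 9.4

    def test_stress_motif_counts(self):
        fold = fold_enrichment(EnrichmentInput(88, 1329, 996, 55986))
        assert round(fold, 2) == 3.72

    def test_no_enrichment_is_one(self):
        assert fold_enrichment(EnrichmentInput(10, 100, 100, 1000)) == pytest.approx(1.0)

    def test_identity_relation(self):
        e = EnrichmentInput(7, 31, 55, 1234)
        assert fold_enrichment(e) * (e.M / e.N) == pytest.approx(e.n_k / e.m_k)

    def test_zero_selection_undefined(self):
        with pytest.raises(ValueError):
            fold_enrichment(EnrichmentInput(0, 0, 5, 10))


def ranked_net(scored_pairs):
    uni = {g for p, _ in scored_pairs for g in p}
    return ScoredNetwork(edges=dict(scored_pairs), node_universe=uni)


class TestEnrichmentCurve:
    def test_gold_everything_gives_fold_one(self):
        net = ranked_net([(("a", "b"), 3.0), (("a", "c"), 2.0), (("b", "c"), 1.0)])
        gold = {("a", "b"), ("a", "c"), ("b", "c")}
        curve = enrichment_curve(net, gold, M=3, N=3, cutoffs=[1, 2, 3])
        assert all(f == pytest.approx(1.0) for _, f in curve)

    def test_all_gold_top_edges_give_maximal_fold(self):
        net = ranked_net([(("a", "b"), 3.0), (("c", "d"), 2.0)])
        gold = {("a", "b"), ("c", "d")}
        (_, fold), *_ = enrichment_curve(net, gold, M=10, N=1000, cutoffs=[2])
        assert fold == pytest.approx(1000 / 10)

    def test_matches_brute_force_counting(self, rng):
        genes = [f"g{i}" for i in range(15)]
        pairs = sorted({tuple(sorted(p)) for p in rng.choice(genes, (60, 2)) if p[0] != p[1]})
        net = ranked_net([(p, float(rng.uniform())) for p in pairs])
        gold = set(map(tuple, rng.permutation(pairs)[: len(pairs) // 3]))
        M, N = len(gold), 15 * 14 // 2
        cutoffs = [1, 5, 10, len(pairs)]
        curve = enrichment_curve(net, gold, M, N, cutoffs)
        ordered = sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0]))
        for (c, fold) in curve:
            top = ordered[: int(c)]
            n_k = sum(p in gold for p, _ in top)
            assert fold == pytest.approx((n_k / len(top)) / (M / N))


@pytest.fixture(scope="module")
def pred_dag():
    parents = {
        "root": set(),
        "A": {"root"},
        "B": {"root"},
        "A1": {"A"},
        "A2": {"A"},
        "B1": {"B"},
    }
    annotations = {
        **{f"a{i}": {"A1"} for i in range(6)},
        **{f"c{i}": {"A2"} for i in range(6)},
        **{f"b{i}": {"B1"} for i in range(8)},
    }
    return OntologyDAG(parents=parents, annotations=annotations)


class TestNeighborhoodEnrichment:
    def test_pure_term_neighborhood_ranks_that_term_first(self, pred_dag):
        edges = {("a0", f"a{i}"): 1.0 for i in range(1, 6)}
        net = ScoredNetwork(edges=dict(edges), node_universe=set(pred_dag.annotations))
        rec = neighborhood_enrichment(net, "a0", pred_dag)
        assert "A1" in rec.predicted
        assert rec.predicted["A1"] == max(rec.predicted.values())

    def test_balanced_neighborhood_predicts_nothing(self):
        # neighborhood annotation frequencies exactly match the genome's
        genes = [f"g{i:02d}" for i in range(60)]
        parents = {"root": set(), "T": {"root"}, "U": {"root"}}
        ann = {g: {"T" if i % 2 else "U"} for i, g in enumerate(genes)}
        dag = OntologyDAG(parents=parents, annotations=ann)
        nbrs = genes[1:11]  # five T, five U -> same 50/50 split as the genome
        edges = {tuple(sorted(("g00", n))): 1.0 for n in nbrs}
        net = ScoredNetwork(edges=edges, node_universe=set(genes))
        rec = neighborhood_enrichment(net, "g00", dag)
        assert rec.predicted == {}

    def test_fisher_p_equals_hypergeometric_tail(self, pred_dag):
        # fixed table: 10 of 20 neighbors annotated; 50 of 1000 genes genome-wide
        p_impl = stats.hypergeom.sf(10 - 1, 1000, 50, 20)
        p_oracle = sum(
            math.comb(50, k) * math.comb(950, 20 - k) / math.comb(1000, 20)
            for k in range(10, 21)
        )
        assert p_impl == pytest.approx(p_oracle, rel=1e-10)
        _, p_fisher = stats.fisher_exact(
            [[10, 10], [40, 940]], alternative="greater"
        )
        assert p_fisher == pytest.approx(p_oracle, rel=1e-9)

    def test_isolated_gene_gives_empty_prediction(self, pred_dag):
        net = ScoredNetwork(edges={}, node_universe=set(pred_dag.annotations))
        rec = neighborhood_enrichment(net, "a0", pred_dag)
        assert rec.predicted == {}


class TestTruePositiveRule:
    def test_equal_term_is_true(self, pred_dag):
        assert is_true_positive("A1", {"A1"}, pred_dag)

    def test_less_specific_prediction_is_false(self, pred_dag):
        assert not is_true_positive("A", {"A1"}, pred_dag)

    def test_descendant_prediction_is_true(self, pred_dag):
        assert is_true_positive("A1", {"root"}, pred_dag)
        assert is_true_positive("A2", {"A"}, pred_dag)

    def test_unknown_term_errors(self, pred_dag):
        with pytest.raises(KeyError):
            is_true_positive("nope", {"A"}, pred_dag)


class TestPropagateScores:
    def test_single_leaf_fills_ancestors(self, pred_dag):
        out = propagate_scores(pred_dag, {"A1": 2.5})
        assert out == {"A1": 2.5, "A": 2.5, "root": 2.5}

    def test_parent_takes_highest_child(self, pred_dag):
        out = propagate_scores(pred_dag, {"A1": 2.0, "A2": 3.0})
        assert out["A"] == 3.0 and out["root"] == 3.0

    def test_matches_descendant_max_oracle_and_idempotent(self, pred_dag, rng):
        scores = {t: float(rng.uniform(0, 5)) for t in ["A1", "A2", "B1", "B"]}
        out = propagate_scores(pred_dag, scores)
        for t in pred_dag.terms:
            descendants = [
                u for u in scores if t in pred_dag.ancestors(u)
            ]
            want = max((scores[u] for u in descendants), default=None)
            if want is None:
                assert t not in out
            else:
                assert out[t] == pytest.approx(want)
        assert propagate_scores(pred_dag, out) == out


class TestCafaMetrics:
    def test_perfect_predictions_reach_fmax_one(self, pred_dag):
        records = []
        for g in ["a0", "b0", "c0"]:
            known = pred_dag.gene_terms(g)
            records.append(
                PredictionRecord(gene=g, predicted={t: 1.0 for t in known}, known=known)
            )
        res = cafa_metrics(records, pred_dag)
        assert res.f_max == pytest.approx(1.0)

    def test_empty_predictions_have_zero_recall(self, pred_dag):
        records = [
            PredictionRecord(gene="a0", predicted={}, known=pred_dag.gene_terms("a0"))
        ]
        res = cafa_metrics(records, pred_dag)
        assert all(r == 0.0 for _, r in res.roc_points)
        assert res.f_max == 0.0

    def test_three_gene_fixture_matches_hand_computation(self, pred_dag):
        records = [
            # gene 1: predicts its known leaf (score 2) and a wrong branch (1)
            PredictionRecord("a0", {"A1": 2.0, "A": 2.0, "B1": 1.0, "B": 1.0},
                             pred_dag.gene_terms("a0")),
            # gene 2: predicts only the wrong branch
            PredictionRecord("b0", {"A2": 1.0, "A": 1.0}, pred_dag.gene_terms("b0")),
            # gene 3: no predictions
            PredictionRecord("c0", {}, pred_dag.gene_terms("c0")),
        ]
        res = cafa_metrics(records, pred_dag, n_thresholds=2)
        # known sets exclude the root: a0 {A1, A}, b0 {B1, B}, c0 {A2, A}
        # tau = 1: a0 pred {A1,A,B1,B} -> P 2/4, R 2/2; b0 pred {A2,A} -> P 0/2, R 0
        #          c0 none. precision mean over predicting genes = (0.5 + 0)/2
        #          recall mean over all three genes = (1 + 0 + 0)/3
        by_tau = dict(zip(res.thresholds, zip(res.pr_points, res.roc_points)))
        (r1, p1), _ = by_tau[1.0]
        assert p1 == pytest.approx((0.5 + 0.0) / 2)
        assert r1 == pytest.approx(1.0 / 3)
        # tau = 2: only a0 predicts {A1, A} -> P 1, R 1; recall mean = 1/3
        (r2, p2), _ = by_tau[2.0]
        assert p2 == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0 / 3)
        # F at tau=2: 2*1*(1/3)/(1+1/3) = 0.5
        assert res.f_max == pytest.approx(0.5)

    def test_recall_never_increases_with_threshold(self, pred_dag, rng):
        records = []
        for g in list(pred_dag.annotations)[:8]:
            preds = {
                t: float(rng.uniform(0, 3))
                for t in rng.choice(sorted(pred_dag.terms), size=3, replace=False)
            }
            records.append(PredictionRecord(g, preds, pred_dag.gene_terms(g)))
        res = cafa_metrics(records, pred_dag)
        recalls = [r for _, r in res.roc_points]
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))
        assert all(0 <= p <= 1 and 0 <= r <= 1 for r, p in res.pr_points)

    def test_eligibility_prefilter(self, pred_dag):
        keep = PredictionRecord("a0", {"A1": 1.0, "A": 1.0, "root": 1.0},
                                frozenset({"A1", "A", "root"}))
        few_known = PredictionRecord("b0", {"A1": 1.0, "A": 1.0, "root": 1.0},
                                     frozenset({"B1"}))
        # 9 predicted vs 3 known: CV of the counts |9-3|/sqrt(2)/6 = 0.71 > 0.5
        unbalanced = PredictionRecord(
            "c0", {f"t{i}": 1.0 for i in range(9)}, frozenset({"A2", "A", "root"})
        )
        out = evalnet.eligible_records([keep, few_known, unbalanced])
        assert [r.gene for r in out] == ["a0"]


class TestTopology:
    def test_triangle(self):
        net = ScoredNetwork(
            edges={("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0},
            node_universe={"a", "b", "c"},
        )
        ts = topology_stats(net)
        assert ts.mean_clustering == pytest.approx(1.0)
        assert ts.avg_path_length == pytest.approx(1.0)
        assert ts.degree_histogram == {2: 3}

    def test_path_graph(self):
        net = ScoredNetwork(
            edges={("a", "b"): 1.0, ("b", "c"): 1.0}, node_universe={"a", "b", "c"}
        )
        assert topology_stats(net).avg_path_length == pytest.approx((1 + 1 + 2) / 3)

    def test_matches_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(50, 0.08, seed=7)
        edges = {tuple(sorted((f"n{a}", f"n{b}"))): 1.0 for a, b in g.edges}
        net = ScoredNetwork(edges=edges, node_universe={f"n{i}" for i in range(50)})
        ts = topology_stats(net)
        giant = g.subgraph(max(nx.connected_components(g), key=len))
        dists = []
        for s in giant.nodes:
            layers = {s: 0}
            frontier = [s]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for u in frontier:
                    for v in giant.neighbors(u):
                        if v not in layers:
                            layers[v] = d
                            nxt.append(v)
                frontier = nxt
            dists.extend(v for k, v in layers.items() if k != s)
        assert ts.avg_path_length == pytest.approx(np.mean(dists))


class TestGuideSubnetwork:
    def chain(self):
        return ScoredNetwork(
            edges={("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "d"): 1.0},
            node_universe={"a", "b", "c", "d"},
        )

    def test_two_layers_from_chain_end(self):
        sub = guide_subnetwork(self.chain(), {"a"}, layers=2)
        assert sub.node_universe == {"a", "b", "c"}
        assert sub.pairs == {("a", "b"), ("b", "c")}

    def test_zero_layers_is_induced_subgraph_on_guides(self):
        sub = guide_subnetwork(self.chain(), {"a", "b"}, layers=0)
        assert sub.node_universe == {"a", "b"}
        assert sub.pairs == {("a", "b")}

    def test_missing_guides_error(self):
        with pytest.raises(ValueError):
            guide_subnetwork(self.chain(), {"zzz"})

    def test_matches_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        edges = {tuple(sorted((f"n{a}", f"n{b}"))): 1.0 for a, b in g.edges}
        net = ScoredNetwork(edges=edges, node_universe={f"n{i}" for i in range(40)})
        guides = {"n0", "n7"}
        sub = guide_subnetwork(net, guides, layers=2)
        want = set()
        for s in (0, 7):
            want |= {f"n{v}" for v, d in nx.single_source_shortest_path_length(g, s, 2).items()}
        assert sub.node_universe == want


class TestTraitLinkDensity:
    def test_reported_counts_give_eleven_fold(self):
        fold = density_fold(262, 88041, 252, 982302)
        assert fold == pytest.approx(11.60, abs=0.01)
        assert fold >= 11

    def test_identical_densities_give_fold_one(self):
        assert density_fold(10, 100, 50, 500) == pytest.approx(1.0)

    def test_toy_fixture_matches_brute_force(self):
        traits = {"t1": {"a", "b", "c"}, "t2": {"c", "d"}, "t3": {"e", "f"}}
        edges = {("a", "b"): 1.0, ("c", "d"): 1.0, ("a", "e"): 1.0, ("e", "f"): 1.0}
        net = ScoredNetwork(edges=edges, node_universe={"a", "b", "c", "d", "e", "f"})
        res = trait_link_density(net, traits, n_perm=50, seed=0)
        # within pairs: ab, ac, bc, cd, ef ; links among them: ab, cd, ef
        assert (res.within_links, res.within_possible) == (3, 5)
        # between pairs: all remaining of 15 possible = 10 ; links: ae
        assert (res.between_links, res.between_possible) == (1, 10)
        assert res.fold == pytest.approx((3 / 5) / (1 / 10))
        assert 0 < res.p_value <= 1

    def test_zero_between_links_reported_as_undefined(self):
        traits = {"t1": {"a", "b"}, "t2": {"c", "d"}}
        net = ScoredNetwork(edges={("a", "b"): 1.0}, node_universe={"a", "b", "c", "d"})
        res = trait_link_density(net, traits)
        assert res.fold is None
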