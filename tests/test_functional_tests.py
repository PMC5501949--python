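"""Functional tests and downsampled convergence: oracles and calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convergetrend.functional_tests import (
    FunctionalProperty,
    connectivity_test,
    downsample_convergence,
    enrichment_test,
    filter_annotation_sets_by_size,
    score_test,
)
from convergetrend.genesets import GeneUniverse
from convergetrend.networks import WeightedGeneNetwork


@pytest.fixture
def universe10():
    return GeneUniverse(frozenset(f"g{i}" for i in range(10)))


class TestEnrichment:
    def test_disjoint_p_one(self, universe10):
        assert enrichment_test({"g0"}, {"g1"}, universe10) == pytest.approx(1.0)

    def test_enumeration_value(self, universe10):
        p = enrichment_test({"g0", "g1"}, {f"g{i}" for i in range(5)}, universe10)
        assert p == pytest.approx(10 / 45, rel=1e-12)

    def test_matches_enumeration_all_overlaps(self, universe10):
        """Closed-form tail equals counting over all candidate draws."""
        genes = sorted(universe10.genes)
        prop = set(genes[:5])
        for cand_size in (2, 3):
            for draw in itertools.combinations(genes, cand_size):
                ov = len(set(draw) & prop)
                hits = sum(
                    1
                    for other in itertools.combinations(genes, cand_size)
                    if len(set(other) & prop) >= ov
                )
                expected = hits / math.comb(10, cand_size)
                assert enrichment_test(set(draw), prop, universe10) == pytest.approx(
                    expected, rel=1e-9
                )

    def test_monotone_in_overlap(self, universe10):
        prop = {f"g{i}" for i in range(5)}
        ps = [
            enrichment_test(
                {f"g{i}" for i in range(k)} | {f"g{9-i}" for i in range(2 - k)}
                if k < 2 else {f"g{i}" for i in range(2)},
                prop,
                universe10,
            )
            for k in (0, 1, 2)
        ]
        assert ps[0] >= ps[1] >= ps[2]

    def test_relabeling_invariance(self, universe10):
        mapping = {f"g{i}": f"x{i}" for i in range(10)}
        relabeled = GeneUniverse(frozenset(mapping.values()))
        p1 = enrichment_test({"g0", "g1", "g2"}, {"g1", "g2", "g5"}, universe10)
        p2 = enrichment_test({"x0", "x1", "x2"}, {"x1", "x2", "x5"}, relabeled)
        assert p1 == pytest.approx(p2)


class TestScoreTest:
    def test_exact_extreme_p(self):
        scores = pd.Series(
            {"a": 10.0, "b": 9.0, "c": 8.0, "x": 1.0, "y": 2.0, "z": 3.0}
        )
        p = score_test({"a", "b", "c"}, scores, alternative="greater")
        assert p == pytest.approx(1 / math.comb(6, 3), rel=1e-9)

    def test_exact_matches_enumeration(self, rng):
        """Exact rank-sum p equals enumeration over all group assignments."""
        values = rng.normal(size=7)
        genes = [f"g{i}" for i in range(7)]
        scores = pd.Series(values, index=genes)
        cand = {"g0", "g1", "g2"}
        p = score_test(cand, scores, alternative="greater")
        cand_sum = sum(stats.rankdata(values)[:3])
        total = 0
        at_least = 0
        for combo in itertools.combinations(range(7), 3):
            total += 1
            if sum(stats.rankdata(values)[list(combo)]) >= cand_sum:
                at_least += 1
        assert p == pytest.approx(at_least / total, rel=1e-9)

    def test_uniform_under_null(self, rng):
        """p is uniform when the candidate is an exchangeable random subset."""
        genes = [f"g{i}" for i in range(60)]
        ps = []
        for _ in range(400):
            scores = pd.Series(rng.normal(size=60), index=genes)
            cand = set(rng.choice(genes, 12, replace=False))
            ps.append(score_test(cand, scores, alternative="greater"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_scores_degenerate(self):
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        assert score_test({"g0", "g1"}, scores) == 1.0

    def test_direction_flip(self, rng):
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(np.arange(40, dtype=float), index=genes)
        top = set(genes[-5:])
        assert score_test(top, scores, alternative="greater") < 0.01
        assert score_test(top, scores, alternative="less") > 0.95


def _uniform_complete_network(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return WeightedGeneNetwork(tuple(f"g{i}" for i in range(n)), w)


def _planted_clique_network(rng, n=500, clique=10, strong=5.0, weak=0.05):
    w = rng.random((n, n)) * weak
    w = (w + w.T) / 2
    w[:clique, :clique] = strong
    np.fill_diagonal(w, 0.0)
    return WeightedGeneNetwork(tuple(f"g{i}" for i in range(n)), w)


class TestConnectivity:
    def test_complete_graph_no_signal(self):
        net = _uniform_complete_network(60)
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            p = connectivity_test(
                {f"g{i}" for i in range(8)}, net, n_null_sets=100, rng=rng
            )
            rejections += p < 0.05
        assert rejections <= 6  # ~95% of runs should not reject

    def test_planted_clique_detected(self, rng):
        net = _planted_clique_network(rng)
        p = connectivity_test(
            {f"g{i}" for i in range(10)}, net, n_null_sets=300, rng=rng
        )
        assert p < 0.001

    def test_scaling_invariance(self, rng):
        net = _planted_clique_network(rng, n=120, clique=8)
        scaled = WeightedGeneNetwork(net.nodes, net.weights * 7.5)
        cand = {f"g{i}" for i in range(8)}
        p1 = connectivity_test(cand, net, n_null_sets=100,
                               rng=np.random.default_rng(9))
        p2 = connectivity_test(cand, scaled, n_null_sets=100,
                               rng=np.random.default_rng(9))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_random_candidates_symmetric_with_bounded_tails(self):
        """Random candidates give a symmetric p distribution; tails are
        over-dispersed (not uniform) because residuals of a gene set are
        positively correlated through shared within-set edges — the trend
        stage, being rank-based with a permutation null, absorbs this."""
        rng = np.random.default_rng(3)
        net = WeightedGeneNetwork(
            tuple(f"g{i}" for i in range(150)),
            (lambda m: (m + m.T) / 2)(rng.random((150, 150))),
            validate=False,
        )
        ps = np.array([
            connectivity_test(
                {f"g{i}" for i in rng.choice(150, 10, replace=False)},
                net, n_null_sets=100, rng=rng,
            )
            for _ in range(200)
        ])
        assert abs(np.median(ps) - 0.5) < 0.1
        assert (ps < 0.05).mean() < 0.2
        assert abs((ps < 0.05).mean() - (ps > 0.95).mean()) < 0.1

    def test_too_small_candidate_rejected(self, rng):
        net = _uniform_complete_network(10)
        with pytest.raises(ValueError, match="at least 3"):
            connectivity_test({"g0", "g1"}, net, n_null_sets=100, rng=rng)


class TestDownsampling:
    def test_full_size_subsample_equals_raw(self, universe10, rng):
        prop = {f"g{i}" for i in range(5)}
        cand = {"g0", "g1", "g2", "g5"}
        res = downsample_convergence(
            lambda s: enrichment_test(s, prop, universe10), cand,
            k=len(cand), iters=17, rng=rng,
        )
        assert res.convergence_p == pytest.approx(res.raw_p, rel=1e-12)

    def test_geometric_mean_closed_form(self):
        ps = iter([0.01, 0.0001, 0.5])  # raw + two iterations
        res = downsample_convergence(
            lambda s: next(ps), {"a", "b", "c", "d"}, k=3, iters=2,
            rng=np.random.default_rng(0),
        )
        assert res.convergence_p == pytest.approx(
            math.sqrt(0.0001 * 0.5), rel=1e-12
        )

    def test_reproducible_given_seed(self, universe10):
        prop = {f"g{i}" for i in range(5)}
        cand = {f"g{i}" for i in range(8)}
        runs = [
            downsample_convergence(
                lambda s: enrichment_test(s, prop, universe10), cand,
                k=4, iters=50, rng=np.random.default_rng(11),
            ).convergence_p
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_k_larger_than_set_rejected(self, universe10, rng):
        with pytest.raises(ValueError, match="subsample size"):
            downsample_convergence(
                lambda s: 0.5, {"g0", "g1", "g2"}, k=4, iters=5, rng=rng
            )

    def test_null_not_smaller_than_planted(self, universe10, rng):
        """Null convergence is stochastically no smaller than planted."""
        genes = sorted(universe10.genes)
        big_uni = GeneUniverse(frozenset(f"h{i}" for i in range(200)))
        prop = {f"h{i}" for i in range(40)}
        planted_cand = {f"h{i}" for i in range(20, 50)}  # 20 genes overlap
        null_cand = {f"h{i}" for i in range(150, 180)}
        conv = {
            name: downsample_convergence(
                lambda s: enrichment_test(s, prop, big_uni), cand,
                k=10, iters=100, rng=np.random.default_rng(4),
            ).convergence_p
            for name, cand in (("planted", planted_cand), ("null", null_cand))
        }
        assert conv["null"] > conv["planted"]

    def test_convergence_stabilizes_with_iterations(self, universe10):
        """Std error of log p at 1000 iters is < 5% of its magnitude."""
        big_uni = GeneUniverse(frozenset(f"h{i}" for i in range(400)))
        prop = {f"h{i}" for i in range(80)}
        cand = {f"h{i}" for i in range(40, 140)}
        reps = [
            math.log(
                downsample_convergence(
                    lambda s: enrichment_test(s, prop, big_uni), cand,
                    k=20, iters=1000, rng=np.random.default_rng(seed),
                ).convergence_p
            )
            for seed in range(6)
        ]
        assert np.std(reps) < 0.05 * abs(np.mean(reps))


class TestPropertyContainer:
    def test_kind_payload_mismatch(self):
        with pytest.raises(TypeError):
            FunctionalProperty("x", "network", {"a", "b"})

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FunctionalProperty("x", "annotation_set", set())

    def test_size_filter(self):
        props = [
            FunctionalProperty("small", "annotation_set", {"a"}),
            FunctionalProperty("ok", "annotation_set", {f"g{i}" for i in range(30)}),
            FunctionalProperty("score", "gene_score", pd.Series({"a": 1.0})),
        ]
        kept = filter_annotation_sets_by_size(props, min_size=20, max_size=1000)
        assert [p.id for p in kept] == ["ok", "score"]
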