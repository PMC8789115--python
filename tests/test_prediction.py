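"""Cross-validation folds, candidate scoring, and driver ranking."""

import numpy as np
import pytest

from gec import (
    Network,
    graphlet_eigencentrality,
    make_folds,
    rank_cancer_candidates,
    score_participation_global,
    score_participation_local,
)


def clique_net(members, extras=()):
    edges = [(u, v) for i, u in enumerate(members) for v in members[i + 1:]]
    edges += list(extras)
    return Network(edges=edges)


CLIQUE10 = [f"c{i}" for i in range(10)]


class TestMakeFolds:
    def test_balanced_partition_of_ten_genes(self):
        net = clique_net(CLIQUE10)
        folds = make_folds(net, CLIQUE10, iterations=1, k=5, seed=1)
        assert len(folds) == 5
        held = [f.held_out for f in folds]
        assert all(len(h) == 2 for h in held)
        assert set().union(*held) == set(CLIQUE10)
        for f in folds:
            assert f.train_genes | f.held_out == set(CLIQUE10)
            assert not f.train_genes & f.held_out
            assert not f.negatives & (f.train_genes | f.held_out)

    def test_isolated_clique_has_no_negatives(self):
        net = clique_net(CLIQUE10, extras=[("x", "y")])
        folds = make_folds(net, CLIQUE10, iterations=2, k=5, seed=3)
        assert all(f.negatives == frozenset() for f in folds)

    def test_neighbors_of_training_genes_are_negatives(self):
        net = clique_net(CLIQUE10, extras=[("c0", "out1"), ("out1", "out2")])
        folds = make_folds(net, CLIQUE10, iterations=1, k=5, seed=0)
        for f in folds:
            if "c0" in f.train_genes:
                assert f.negatives == {"out1"}  # out2 is not adjacent

    def test_seeded_determinism(self):
        net = clique_net(CLIQUE10)
        a = make_folds(net, CLIQUE10, iterations=3, k=5, seed=9)
        b = make_folds(net, CLIQUE10, iterations=3, k=5, seed=9)
        c = make_folds(net, CLIQUE10, iterations=3, k=5, seed=10)
        assert a == b
        assert a != c

    def test_too_few_genes_names_the_pathway(self):
        net = clique_net(["a", "b", "c"])
        with pytest.raises(ValueError, match="tiny"):
            make_folds(net, ["a", "b", "c"], k=5, pathway="tiny")

    def test_uneven_sizes_differ_by_at_most_one(self):
        members = [f"m{i}" for i in range(13)]
        net = clique_net(members)
        folds = make_folds(net, members, iterations=1, k=5, seed=2)
        sizes = sorted(len(f.held_out) for f in folds)
        assert sizes == [2, 2, 3, 3, 3]


class TestLocalScoring:
    def test_held_out_clique_member_scores_like_the_rest(self):
        net = clique_net(CLIQUE10, extras=[("c0", "neg")])
        folds = make_folds(net, CLIQUE10, iterations=1, k=5, seed=1)
        fold = folds[0]
        ts = score_participation_local(net, fold, 0)
        member = sorted(fold.held_out)[0]
        # the augmented graph is the 8 training genes plus the candidate
        # attached to all of them, i.e. a 9-clique -> uniform scores
        assert ts.scores[member] == pytest.approx(1 / 3, abs=1e-9)
        assert ts.labels[member] == 1

    def test_single_edge_candidate_closes_no_4_clique(self):
        net = clique_net(CLIQUE10, extras=[("c0", "neg")])
        folds = [
            f for f in make_folds(net, CLIQUE10, iterations=1, k=5, seed=1)
            if "c0" in f.train_genes
        ]
        ts = score_participation_local(net, folds[0], 8)
        assert ts.scores["neg"] == 0.0
        assert any(ts.scores[m] > 0 for m in folds[0].held_out)

    def test_disconnected_candidate_scores_zero(self):
        from gec import FoldSpec

        net = clique_net(CLIQUE10, extras=[("far", "c9"), ("far", "away")])
        folds = [
            f for f in make_folds(net, CLIQUE10, iterations=1, k=5, seed=4)
            if "c9" in f.train_genes
        ]
        ts = score_participation_local(net, folds[0], 0)
        # 'far' touches training gene c9, so it is a scored negative ...
        assert ts.scores["far"] > 0 and ts.labels["far"] == 0
        # ... while 'away' touches no training gene and is never scored
        assert "away" not in ts.scores
        # a manually specified candidate with no edge into the training
        # set has empty support in its augmented subgraph: score 0
        custom = FoldSpec(
            pathway="pw", iteration=1, fold=1,
            train_genes=folds[0].train_genes,
            held_out=folds[0].held_out,
            negatives=frozenset({"away"}),
        )
        ts2 = score_participation_local(net, custom, 0)
        assert ts2.scores["away"] == 0.0

    def test_edgeless_training_subgraph_is_degenerate(self):
        net = Network(edges=[("a", "x"), ("b", "x"), ("c", "x"),
                             ("d", "x"), ("e", "x")])
        genes = ["a", "b", "c", "d", "e"]
        folds = make_folds(net, genes, iterations=1, k=5, seed=0)
        ts = score_participation_local(net, folds[0], 0)
        assert ts.degenerate
        assert set(ts.scores.values()) == {0.0}

    def test_batch_and_loop_routes_agree(self):
        rng = np.random.default_rng(17)
        import networkx as nx

        net = Network.from_networkx(nx.gnp_random_graph(40, 0.15, seed=21))
        genes = sorted(net.nodes[:12])
        for fold in make_folds(net, genes, iterations=1, k=4, seed=5)[:2]:
            a = score_participation_local(net, fold, 0, method="loop")
            b = score_participation_local(net, fold, 0, method="batch")
            assert a.scores.keys() == b.scores.keys()
            for t in a.scores:
                assert a.scores[t] == pytest.approx(b.scores[t], abs=1e-9)

    def test_batch_rejects_higher_graphlets(self):
        net = clique_net(CLIQUE10)
        fold = make_folds(net, CLIQUE10, iterations=1, k=5, seed=1)[0]
        with pytest.raises(ValueError, match="G0 only"):
            score_participation_local(net, fold, 6, method="batch")

    def test_scoring_ignores_edges_among_test_genes(self):
        # candidate augmentation is per-candidate: edges between two
        # negatives must not influence anyone's score
        extras = [("c0", "n1"), ("c1", "n2")]
        net_plain = clique_net(CLIQUE10, extras=extras)
        net_linked = clique_net(CLIQUE10, extras=extras + [("n1", "n2")])
        folds_p = make_folds(net_plain, CLIQUE10, iterations=1, k=5, seed=2)
        folds_l = make_folds(net_linked, CLIQUE10, iterations=1, k=5, seed=2)
        for fp, fl in zip(folds_p, folds_l):
            assert fp.held_out == fl.held_out
            a = score_participation_local(net_plain, fp, 0)
            b = score_participation_local(net_linked, fl, 0)
            assert a.scores == b.scores

    def test_label_bookkeeping(self):
        net = clique_net(CLIQUE10, extras=[("c0", "n1"), ("c3", "n2")])
        for fold in make_folds(net, CLIQUE10, iterations=2, k=5, seed=6):
            ts = score_participation_local(net, fold, 0)
            assert ts.scores.keys() == ts.labels.keys()
            n_pos = sum(ts.labels.values())
            assert n_pos == len(fold.held_out)
            assert len(ts.scores) == n_pos + len(fold.negatives)


class TestGlobalScoring:
    def test_scores_are_cache_restriction(self, claw):
        net = clique_net(CLIQUE10, extras=[("c0", "n1")])
        cache = graphlet_eigencentrality(net, 0)
        fold = make_folds(net, CLIQUE10, iterations=1, k=5, seed=1)[0]
        ts = score_participation_global(net, fold, 0, cache)
        for t, s in ts.scores.items():
            assert s == cache[t]

    def test_star_center_outranks_leaf_negatives(self):
        # pathway = center + 4 leaves; hold the center out and the
        # remaining leaves' neighbour set pulls in nothing new
        leaves = [f"l{i}" for i in range(5)]
        net = Network(edges=[("hub", x) for x in leaves]
                      + [(u, v) for i, u in enumerate(leaves[:4])
                         for v in leaves[i + 1:4]])
        genes = ["hub"] + leaves[:4]
        cache = graphlet_eigencentrality(net, 0)
        folds = [
            f for f in make_folds(net, genes, iterations=1, k=5, seed=0)
            if f.held_out == {"hub"}
        ]
        ts = score_participation_global(net, folds[0], 0, cache)
        assert all(ts.scores["hub"] > ts.scores[t]
                   for t in ts.scores if t != "hub")


class TestDriverRanking:
    def test_bridged_modules_give_full_rankings(self):
        m1 = ["a1", "a2", "a3", "a4"]
        m2 = ["b1", "b2", "b3", "b4"]
        edges = [(u, v) for i, u in enumerate(m1) for v in m1[i + 1:]]
        edges += [(u, v) for i, u in enumerate(m2) for v in m2[i + 1:]]
        edges += [("hub", m1[0]), ("hub", m2[0])]
        net = Network(edges=edges)
        genes = set(net.nodes)
        for g in (0, 6):
            res = rank_cancer_candidates(net, genes, g, "local", pathway="pw")
            assert set(res.scores) == genes
            assert not res.degenerate

    def test_global_mode_equals_cache_slice(self, k4):
        cache = graphlet_eigencentrality(k4, 0)
        res = rank_cancer_candidates(k4, {"a", "b"}, 0, "global", cache=cache)
        assert res.scores == {"a": cache["a"], "b": cache["b"]}

    def test_global_mode_requires_cache(self, k4):
        with pytest.raises(ValueError, match="requires the cached"):
            rank_cancer_candidates(k4, {"a"}, 0, "global")

    def test_unknown_mode_rejected(self, k4):
        with pytest.raises(ValueError, match="mode"):
            rank_cancer_candidates(k4, {"a"}, 0, "sideways")
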