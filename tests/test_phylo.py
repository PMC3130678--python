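"""Tree bookkeeping, contrasts, ancestral states and regime painting."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import peakshift as pk
from peakshift.errors import MissingDataError, NewickParseError
from peakshift.phylo import _er_transition


class TestNewick:
    def test_two_tip_parse(self):
        t = pk.read_newick("(A:1,B:1):0;")
        assert t.n_tips == 2
        assert np.allclose(t.tip_depths(), 1.0)

    def test_three_tip_ultrametric(self, three_tip_tree):
        assert np.allclose(three_tip_tree.tip_depths(), 2.0)
        assert three_tip_tree.is_ultrametric()

    def test_roundtrip_preserves_patristic(self):
        tree = pk.simulate_tree(49, 30, 5)
        back = pk.read_newick(tree.to_newick())
        d1 = pk.patristic_distances(tree)
        d2 = pk.patristic_distances(back)
        assert np.allclose(d1.loc[d2.index, d2.columns], d2, atol=1e-9)

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            pk.read_newick("((A:1,B:1):1")


class TestPatristic:
    def test_closed_form(self, three_tip_tree):
        d = pk.patristic_distances(three_tip_tree)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(d), 0)

    def test_outgroup_equidistant(self):
        tree = pk.simulate_tree(12, 10, 3)
        d = pk.patristic_distances(tree)
        assert np.allclose(d, d.T)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_graph_shortest_paths(self, seed):
        tree = pk.simulate_tree(10, 20, seed)
        g = nx.Graph()
        for v in range(tree.n_nodes):
            if v != tree.root:
                g.add_edge(v, int(tree.parent[v]), weight=float(tree.length[v]))
        d = pk.patristic_distances(tree).to_numpy()
        for i in range(tree.n_tips):
            for j in range(i + 1, tree.n_tips):
                sp = nx.shortest_path_length(g, i, j, weight="weight")
                assert d[i, j] == pytest.approx(sp, abs=1e-10)

    def test_triangle_inequality(self):
        tree = pk.simulate_tree(15, 25, 9)
        d = pk.patristic_distances(tree).to_numpy()
        n = tree.n_tips
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestContrasts:
    def test_two_tip_closed_form(self):
        tree = pk.read_newick("(A:1,B:1):0;")
        traits = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        C, rate = pk.independent_contrasts(tree, traits)
        assert abs(C.iloc[0, 0]) == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_zero_rate(self, three_tip_tree):
        traits = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=["A", "B", "C"])
        C, rate = pk.independent_contrasts(three_tip_tree, traits)
        assert np.allclose(C, 0)
        assert rate[0, 0] == pytest.approx(0.0)

    def test_rate_recovery_on_bm(self):
        from peakshift.disparity import simulate_bm

        true = np.array([[2.0, 0.5], [0.5, 1.0]])
        ests = []
        for rep in range(20):
            tree = pk.simulate_tree(128, 30, 700 + rep)
            X = simulate_bm(tree, true, 1, np.random.default_rng(800 + rep))[0]
            _, rate = pk.independent_contrasts(
                tree, pd.DataFrame(X, index=tree.tip_labels)
            )
            ests.append(rate)
        mean_rate = np.mean(ests, axis=0)
        assert np.abs(mean_rate / true - 1).max() < 0.1

    def test_missing_data_raises(self, three_tip_tree):
        traits = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        with pytest.raises(MissingDataError):
            pk.independent_contrasts(three_tip_tree, traits)


class TestAncestralContinuous:
    def test_two_tip_symmetry(self):
        tree = pk.read_newick("(A:1,B:1):0;")
        est = pk.ancestral_continuous_ml(tree, pd.Series([0.0, 2.0], index=["A", "B"]))
        assert est.root_value[0] == pytest.approx(1.0)

    def test_star_like_mean(self):
        # caterpillar of near-zero internal branches approximates a star
        tree = pk.read_newick("(((A:1,B:1):1e-8,C:1):1e-8,D:1):0;")
        vals = pd.Series([1.0, 2.0, 3.0, 6.0], index=list("ABCD"))
        est = pk.ancestral_continuous_ml(tree, vals)
        assert est.root_value[0] == pytest.approx(vals.mean(), rel=1e-4)

    def test_matches_brute_force(self, three_tip_tree):
        vals = pd.Series([0.0, 2.0, 3.0], index=["A", "B", "C"])
        est = pk.ancestral_continuous_ml(three_tip_tree, vals)

        def ss(z):
            anc, root = z
            return (
                (0 - anc) ** 2 / 1
                + (2 - anc) ** 2 / 1
                + (anc - root) ** 2 / 1
                + (3 - root) ** 2 / 2
            )

        res = minimize(ss, [0, 0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(np.sort(est.node_values.ravel()), np.sort(res.x), atol=1e-3)

    def test_root_equals_gls_mean(self):
        tree = pk.simulate_tree(25, 30, 11)
        rng = np.random.default_rng(12)
        vals = pd.Series(rng.standard_normal(25), index=tree.tip_labels)
        est = pk.ancestral_continuous_ml(tree, vals)
        C = tree.shared_times()
        Ci = np.linalg.inv(C)
        one = np.ones(25)
        x = vals[tree.tip_labels].to_numpy()
        gls = one @ Ci @ x / (one @ Ci @ one)
        assert est.root_value[0] == pytest.approx(gls, abs=1e-8)


def _enumerate_marginals(tree, tip_idx, k, rate):
    """Exhaustive joint-state summation oracle for small trees."""
    n = tree.n_tips
    internals = list(range(n, tree.n_nodes))
    marg = np.zeros((tree.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(internals)):
        full = np.concatenate([tip_idx, np.array(assign, dtype=int)])
        lik = 1.0 / k
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p_same, p_diff = _er_transition(k, rate, tree.length[v])
            lik *= p_same if full[v] == full[tree.parent[v]] else p_diff
        for v in internals:
            marg[v, full[v]] += lik
    marg[n:] /= marg[n:].sum(axis=1, keepdims=True)
    return marg


class TestAncestralDiscrete:
    def test_uniform_tips(self, three_tip_tree):
        est = pk.ancestral_discrete_ml(
            three_tip_tree, pd.Series(["x", "x", "x"], index=["A", "B", "C"]),
            labels=["x", "y"],
        )
        assert est.node_state_probabilities[three_tip_tree.root, 0] > 0.99
        assert est.rate == 0.0

    def test_two_tip_symmetry(self):
        tree = pk.read_newick("(A:1,B:1):0;")
        est = pk.ancestral_discrete_ml(tree, pd.Series(["x", "y"], index=["A", "B"]))
        assert est.node_state_probabilities[tree.root] == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize(
        "newick,states,k",
        [
            ("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3):0;", "xxyyx", 2),
            ("((A:1,(B:0.5,C:0.5):0.5):1,(D:1.5,E:1.5):0.5):0;", "xyzzy", 3),
            ("(((A:1,B:2):1,(C:1,D:1):2):1,(E:2,F:1):2):0;", "xyxyxy", 2),
        ],
    )
    def test_matches_exhaustive_enumeration(self, newick, states, k):
        tree = pk.read_newick(newick)
        labels = sorted(set(states))
        sr = pd.Series(list(states), index=[l for l in "ABCDEF"[: tree.n_tips]])
        est = pk.ancestral_discrete_ml(tree, sr, labels=labels)
        tip_idx = np.array([labels.index(s) for s in sr[tree.tip_labels]])
        oracle = _enumerate_marginals(tree, tip_idx, k, est.rate)
        assert np.abs(
            oracle[tree.n_tips :] - est.node_state_probabilities[tree.n_tips :]
        ).max() < 1e-6

    def test_probabilities_sum_to_one(self):
        tree = pk.simulate_tree(12, 20, 3)
        paint = pk.simulate_regime_history(tree, 3, 0.1, 4)
        est = pk.ancestral_discrete_ml(tree, paint.tip_states)
        assert np.allclose(est.node_state_probabilities.sum(axis=1), 1.0, atol=1e-9)


class TestPaintRegimes:
    def test_uniform_diet(self, three_tip_tree):
        est = pk.ancestral_discrete_ml(
            three_tip_tree, pd.Series(["x", "x", "x"], index=["A", "B", "C"]),
            labels=["x", "y"],
        )
        paint = pk.paint_regimes(three_tip_tree, est)
        assert all(paint.branch_regime(v) == "x" for v in range(three_tip_tree.n_nodes))

    def test_recovery_at_low_switch_rate(self):
        rates = []
        for rep in range(5):
            tree = pk.simulate_tree(49, 30, 100 + rep)
            truth = pk.simulate_regime_history(tree, 5, 0.02, 200 + rep)
            est = pk.ancestral_discrete_ml(
                tree, truth.tip_states, labels=truth.regime_labels
            )
            rec = pk.paint_regimes(tree, est, tip_states=truth.tip_states)
            rates.append(np.mean(rec.node_regime == truth.node_regime))
        assert np.mean(rates) >= 0.90

    def test_tie_resolves_toward_parent(self, three_tip_tree):
        tree = three_tip_tree
        probs = np.zeros((tree.n_nodes, 2))
        probs[: tree.n_tips] = [[1, 0], [1, 0], [0, 1]]
        probs[tree.n_tips] = [0.5, 0.5]  # tied internal node
        probs[tree.root] = [0.1, 0.9]
        est = pk.AncestralEstimate(
            tree=tree, node_state_probabilities=probs, state_labels=["x", "y"]
        )
        paint = pk.paint_regimes(tree, est)
        assert paint.node_regime[tree.root] == 1
        assert paint.node_regime[tree.n_tips] == 1  # follows parent on tie


class TestRegimePaintingContainer:
    def test_merge_relabels(self):
        tree = pk.simulate_tree(10, 10, 1)
        paint = pk.simulate_regime_history(tree, 5, 0.1, 2)
        merged = paint.merge({"insectivory": "animalivory", "carnivory": "animalivory"})
        assert "animalivory" in merged.regime_labels
        assert len(merged.regime_labels) == 4

    def test_tip_segments_cover_path(self):
        tree = pk.simulate_tree(8, 12, 7)
        paint = pk.simulate_regime_history(tree, 3, 0.2, 8)
        for tip in range(tree.n_tips):
            segs = paint.tip_segments(tip)
            assert segs[0][0] == pytest.approx(0.0)
            assert segs[-1][1] == pytest.approx(tree.node_times[tip])
            for (a0, b0, _), (a1, b1, _) in zip(segs, segs[1:]):
                assert b0 == pytest.approx(a1)
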