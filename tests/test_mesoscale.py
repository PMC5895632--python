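import networkx as nx
import numpy as np
import pytest

from shapegraph.data_model import TaskDesign
from shapegraph.mapper import ShapeGraph
from shapegraph.mesoscale import (
    SASettings,
    UndefinedMetricError,
    annotate_nodes,
    core_profile,
    coreness_by_task,
    coreness_oracle,
    coreness_scores,
    modularity,
)
from tests.conftest import graph_from_networkx


def _design(labels, **kw):
    return TaskDesign.from_labels(list(labels), **kw)


class TestAnnotation:
    def test_proportions_and_majority(self):
        sg = ShapeGraph(nodes=[np.array([0, 1, 2])], edges=[], frame_count=3)
        ann = annotate_nodes(sg, _design(["Rest", "Rest", "Math"]))
        assert ann.proportions[0] == {"Rest": pytest.approx(2 / 3),
                                      "Math": pytest.approx(1 / 3)}
        assert ann.majority == ["Rest"]
        assert not ann.ties[0]

    def test_tie_broken_by_task_set_order_and_flagged(self):
        sg = ShapeGraph(nodes=[np.array([0, 1])], edges=[], frame_count=2)
        ann = annotate_nodes(sg, _design(["Math", "Rest"],
                                         task_set=["Rest", "Math"]))
        assert ann.majority == ["Rest"]
        assert ann.ties[0]

    def test_single_frame_node(self):
        sg = ShapeGraph(nodes=[np.array([1])], edges=[], frame_count=2)
        ann = annotate_nodes(sg, _design(["a", "b"]))
        assert ann.proportions[0] == {"b": 1.0}


class TestModularity:
    def test_single_community_gives_zero(self):
        g = nx.gnp_random_graph(8, 0.5, seed=4)
        sg = graph_from_networkx(g)
        ann = annotate_nodes(sg, _design(["x"] * 8))
        assert modularity(sg, ann).q_mod == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        sg = graph_from_networkx(g)
        ann = annotate_nodes(sg, _design(["a"] * 3 + ["b"] * 3))
        assert modularity(sg, ann).q_mod == pytest.approx(0.5)

    def test_complete_graph_split(self):
        sg = graph_from_networkx(nx.complete_graph(4))
        ann = annotate_nodes(sg, _design(["a", "a", "b", "b"]))
        assert modularity(sg, ann).q_mod == pytest.approx(-1 / 6)

    def test_matches_networkx_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            g = nx.gnp_random_graph(9, 0.45, seed=trial)
            if g.number_of_edges() == 0:
                continue
            labels = rng.choice(["a", "b", "c"], size=9)
            sg = graph_from_networkx(g)
            ann = annotate_nodes(sg, _design(labels))
            comms = [{i for i in range(9) if labels[i] == c}
                     for c in ("a", "b", "c")]
            expected = nx.community.modularity(g, [c for c in comms if c])
            assert modularity(sg, ann).q_mod == pytest.approx(expected,
                                                              abs=1e-12)

    def test_community_relabeling_invariance(self):
        g = nx.gnp_random_graph(8, 0.5, seed=9)
        sg = graph_from_networkx(g)
        labels = ["a", "a", "b", "b", "a", "c", "c", "b"]
        swapped = [{"a": "z", "b": "y", "c": "x"}[l] for l in labels]
        q1 = modularity(sg, annotate_nodes(sg, _design(labels))).q_mod
        q2 = modularity(sg, annotate_nodes(sg, _design(swapped))).q_mod
        assert q1 == pytest.approx(q2, abs=1e-14)

    def test_edgeless_graph_rejected(self):
        sg = graph_from_networkx(nx.empty_graph(3))
        ann = annotate_nodes(sg, _design(["a", "b", "c"]))
        with pytest.raises(UndefinedMetricError):
            modularity(sg, ann)


class TestCoreProfile:
    def test_sharp_transition_at_alpha_one(self):
        c = core_profile(10, alpha=1.0, beta=0.5)
        np.testing.assert_allclose(c[:5], 0.0)
        np.testing.assert_allclose(c[5:], 1.0)

    def test_monotone_in_rank(self):
        c = core_profile(12, alpha=0.3, beta=0.4)
        assert (np.diff(c) >= 0).all()
        assert c.min() >= 0 and c.max() <= 1


class TestCorenessOracle:
    @pytest.mark.parametrize("g", [nx.complete_graph(3), nx.complete_graph(5),
                                   nx.Graph([(0, 1)])])
    def test_symmetric_graphs_get_equal_scores(self, g):
        res = coreness_oracle(graph_from_networkx(g), grid_step=0.25)
        np.testing.assert_allclose(res.cs, 1.0, atol=1e-12)

    def test_star_hub_is_core(self):
        res = coreness_oracle(graph_from_networkx(nx.star_graph(5)),
                              grid_step=0.25)
        assert res.cs[0] == pytest.approx(1.0)
        leaves = res.cs[1:]
        np.testing.assert_allclose(leaves, leaves[0], atol=1e-12)
        assert leaves[0] < 1.0

    def test_path_interior_beats_endpoints(self):
        res = coreness_oracle(graph_from_networkx(nx.path_graph(5)),
                              grid_step=0.25)
        assert res.cs[2] > res.cs[0]
        assert res.cs[2] > res.cs[4]

    def test_too_many_nodes_rejected(self):
        with pytest.raises(ValueError, match="oracle"):
            coreness_oracle(graph_from_networkx(nx.path_graph(10)))


class TestCorenessSA:
    SA = SASettings(proposals=5000, restarts=2)

    def test_complete_graph_scores_equal(self):
        res = coreness_scores(graph_from_networkx(nx.complete_graph(5)),
                              grid_step=0.25, sa=self.SA, seed=0)
        np.testing.assert_allclose(res.cs, 1.0, atol=1e-12)

    def test_star_hub_core_leaves_equal(self):
        res = coreness_scores(graph_from_networkx(nx.star_graph(5)),
                              grid_step=0.25, sa=self.SA, seed=0)
        assert res.cs[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.cs[1:], res.cs[1], atol=1e-12)
        assert res.cs[1] < 1.0

    def test_path_interior_beats_endpoints(self):
        res = coreness_scores(graph_from_networkx(nx.path_graph(5)),
                              grid_step=0.25, sa=self.SA, seed=0)
        assert res.cs[2] > res.cs[0]
        assert res.cs[2] > res.cs[4]

    def test_reproducible_for_fixed_seed(self):
        sg = graph_from_networkx(nx.gnp_random_graph(12, 0.3, seed=2))
        a = coreness_scores(sg, grid_step=0.5, sa=self.SA, seed=3)
        b = coreness_scores(sg, grid_step=0.5, sa=self.SA, seed=3)
        np.testing.assert_array_equal(a.cs, b.cs)

    def test_max_score_is_one(self):
        sg = graph_from_networkx(nx.gnp_random_graph(10, 0.4, seed=5))
        res = coreness_scores(sg, grid_step=0.5, sa=self.SA, seed=1)
        assert res.cs.max() == pytest.approx(1.0)
        assert (res.cs >= 0).all()

    def test_weight_scale_invariance(self):
        # duplicated shared frames double every edge weight; rankings keep
        base = ShapeGraph(nodes=[np.array([0, 1]), np.array([1, 2]),
                                 np.array([2, 3])],
                          edges=[(0, 1), (1, 2)], frame_count=4)
        doubled = ShapeGraph(
            nodes=[np.array([0, 1, 4]), np.array([1, 2, 4, 5]),
                   np.array([2, 3, 5])],
            edges=[(0, 1), (1, 2)], frame_count=6)
        a = coreness_oracle(base, grid_step=0.5, weighted=True)
        b = coreness_oracle(doubled, grid_step=0.5, weighted=True)
        np.testing.assert_allclose(a.cs, b.cs, atol=1e-9)

    def test_single_node_degenerates_with_warning(self):
        sg = ShapeGraph(nodes=[np.array([0])], edges=[], frame_count=1)
        with pytest.warns(UserWarning, match="single-node"):
            res = coreness_scores(sg)
        np.testing.assert_array_equal(res.cs, [1.0])


class TestCorenessByTask:
    def _result(self, cs_values):
        from shapegraph.mesoscale import CorenessResult
        cs = np.asarray(cs_values, dtype=float)
        return CorenessResult(cs=cs, alphas=np.array([0.0]),
                              betas=np.array([0.0]),
                              r_grid=np.zeros((1, 1)),
                              c_grid=np.zeros((1, 1, len(cs))),
                              z=1.0, sa=None, seed=None)

    def test_mean_and_sd(self):
        sg = ShapeGraph(nodes=[np.array([0]), np.array([1])], edges=[],
                        frame_count=2)
        ann = annotate_nodes(sg, _design(["Rest", "Rest"]))
        table = coreness_by_task(self._result([0.2, 0.4]), ann)
        row = table.iloc[0]
        assert row["mean_cs"] == pytest.approx(0.3)
        assert row["sd_cs"] == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_single_node_task_sd_zero_and_missing_task_warns(self):
        sg = ShapeGraph(nodes=[np.array([0])], edges=[], frame_count=1)
        ann = annotate_nodes(sg, _design(["Math"],
                                         task_set=["Rest", "Math"]))
        with pytest.warns(UserWarning, match="Rest"):
            table = coreness_by_task(self._result([0.7]), ann)
        assert table.iloc[0]["sd_cs"] == 0.0
        assert set(table["task"]) == {"Math"}
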