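import numpy as np
import pytest

from shapegraph.data_model import TaskDesign
from shapegraph.mapper import (
    CoverageError,
    CoverBin,
    FilterEmbedding,
    MapperParams,
    SearchError,
    build_cover,
    build_mapper_graph,
    build_shape_graph,
    compute_filter,
    first_gap_threshold,
    parameter_search,
    partial_cluster,
)
from tests.conftest import single_voxel_series


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"resolution": 1}, {"gain": 0.5}, {"metric": "hyperbolic"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MapperParams(**kwargs)

    def test_metric_aliases(self):
        assert MapperParams(metric="L1").metric_name == "manhattan"
        assert MapperParams(metric="cityblock").metric_name == "manhattan"


class TestFilter:
    def test_shape_contract_and_registry(self, clustered_series):
        vs, _ = clustered_series
        for name in ("pca", "tsne"):
            emb = compute_filter(vs, MapperParams(filter_name=name, seed=0))
            assert emb.coords.shape == (vs.frame_count, 2)
        with pytest.raises(KeyError, match="unknown filter"):
            compute_filter(vs, MapperParams(filter_name="lens9000"))
        with pytest.raises(ValueError, match="at least 10"):
            compute_filter(vs.data[:5], MapperParams())

    def test_duplicate_frames_coincide(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(12, 6))
        data[7] = data[2]
        emb = compute_filter(data, MapperParams(filter_name="pca"))
        np.testing.assert_allclose(emb.coords[7], emb.coords[2], atol=1e-12)

    def test_clusters_stay_separated(self, clustered_series):
        vs, labels = clustered_series
        emb = compute_filter(vs, MapperParams(filter_name="tsne", seed=0))
        within, between = [], []
        for i in range(vs.frame_count):
            for j in range(i + 1, vs.frame_count):
                d = np.abs(emb.coords[i] - emb.coords[j]).sum()
                (within if labels[i] == labels[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_deterministic_for_fixed_seed(self, clustered_series):
        vs, _ = clustered_series
        p = MapperParams(filter_name="tsne", seed=11)
        a = compute_filter(vs, p)
        b = compute_filter(vs, p)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestCover:
    def test_two_bin_geometry(self):
        # one axis of range [0,1] with R=2, G=2: centers 0.25/0.75, width 1
        coords = np.column_stack([np.linspace(0, 1, 11), np.zeros(11)])
        emb = FilterEmbedding(coords=coords, ranges=[(0.0, 1.0), (0.0, 0.0)])
        bins = build_cover(emb, MapperParams(resolution=2, gain=2.0))
        x_intervals = sorted({b.intervals[0] for b in bins})
        assert x_intervals == [(-0.25, 0.75), (0.25, 1.25)]
        lo, hi = x_intervals[0], x_intervals[1]
        overlap = (lo[1] - hi[0]) / (lo[1] - lo[0])
        assert overlap == pytest.approx(0.5)

    def test_paper_grid_has_900_bins(self):
        rng = np.random.default_rng(0)
        emb = FilterEmbedding(coords=rng.uniform(size=(50, 2)),
                              ranges=[(0.0, 1.0), (0.0, 1.0)])
        bins = build_cover(emb, MapperParams(resolution=30, gain=3.0))
        assert len(bins) == 900

    def test_gain_one_is_a_partition(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(size=(200, 2))
        coords[0] = [0.5, 0.5]  # a boundary point with R=2
        emb = FilterEmbedding(coords=coords, ranges=[(0.0, 1.0), (0.0, 1.0)])
        bins = build_cover(emb, MapperParams(resolution=2, gain=1.0))
        counts = np.zeros(200, dtype=int)
        for b in bins:
            counts[b.members] += 1
        assert (counts == 1).all()

    def test_every_point_covered_and_multiplicity_bound(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(300, 2))
        emb = FilterEmbedding(coords=coords,
                              ranges=[(coords[:, 0].min(), coords[:, 0].max()),
                                      (coords[:, 1].min(), coords[:, 1].max())])
        bins = build_cover(emb, MapperParams(resolution=10, gain=2.0))
        counts = np.zeros(300, dtype=int)
        for b in bins:
            counts[b.members] += 1
        assert (counts >= 1).all()
        assert counts.max() <= 4  # G <= 2 in 2-D


class TestPartialCluster:
    def _bin(self, members):
        return CoverBin(index=(0, 0), intervals=[(0, 1), (0, 1)],
                        members=np.asarray(members))

    def test_separated_groups_split(self):
        vs = single_voxel_series([0.0, 0.1, 10.0, 10.1])
        clusters = partial_cluster(self._bin([0, 1, 2, 3]), vs, MapperParams())
        assert sorted(sorted(c.tolist()) for c in clusters) == [[0, 1], [2, 3]]

    def test_singleton_and_empty_bins(self):
        vs = single_voxel_series([0.0, 1.0])
        assert partial_cluster(self._bin([]), vs, MapperParams()) == []
        [c] = partial_cluster(self._bin([1]), vs, MapperParams())
        assert c.tolist() == [1]

    def test_equally_spaced_points_stay_together(self):
        vs = single_voxel_series([0.0, 1.0, 2.0, 3.0, 4.0])
        clusters = partial_cluster(self._bin([0, 1, 2, 3, 4]), vs,
                                   MapperParams())
        assert len(clusters) == 1

    def test_first_gap_threshold_by_hand(self):
        # distances 0.1,0.1,9.9: bins over [0.1,9.9]; first empty bin edge
        thr = first_gap_threshold(np.array([0.1, 0.1, 9.9]), nbins=10)
        assert 0.1 < thr < 9.9
        assert first_gap_threshold(np.array([1.0, 1.0, 1.0])) is None
        assert first_gap_threshold(np.array([])) is None


class TestGraphBuild:
    def test_shared_frame_makes_edge(self):
        sg = build_shape_graph([[np.array([1, 2])], [np.array([2, 3])],
                                [np.array([0])]], 4)
        assert sg.node_count == 3
        assert sg.edges == [(0, 1)]  # only the clusters sharing frame 2

    def test_disjoint_clusters_no_edge(self):
        sg = build_shape_graph([[np.array([0, 1])], [np.array([2, 3])]], 4)
        assert sg.node_count == 2
        assert sg.edges == []

    def test_one_node_per_cluster(self):
        clusters = [[np.array([i]) for i in range(5)]]
        sg = build_shape_graph(clusters, 5)
        assert sg.node_count == 5

    def test_uncovered_frame_raises(self):
        with pytest.raises(CoverageError):
            build_shape_graph([[np.array([0, 1])]], 3)

    def test_gain_monotonicity_of_cover_overlap(self, clustered_series):
        # growing G widens every bin on the same embedding, so the pool of
        # co-binned frame pairs (the only source of edges) can only grow
        vs, _ = clustered_series
        p = MapperParams(resolution=5, gain=1.0, filter_name="pca")
        emb = compute_filter(vs, p)
        pair_counts = []
        for g in (1.0, 1.5, 2.0, 3.0):
            bins = build_cover(emb, MapperParams(resolution=5, gain=g,
                                                 filter_name="pca"))
            pairs = set()
            for b in bins:
                pairs.update((int(i), int(j)) for k, i in enumerate(b.members)
                             for j in b.members[k + 1:])
            pair_counts.append(len(pairs))
        assert pair_counts == sorted(pair_counts)
        assert pair_counts[-1] > pair_counts[0]

    def test_export_determinism(self, clustered_series):
        vs, _ = clustered_series
        p = MapperParams(resolution=4, gain=2.0, filter_name="tsne", seed=5)
        a = build_mapper_graph(vs, p).to_json()
        b = build_mapper_graph(vs, p).to_json()
        assert a == b


class TestParameterSearch:
    def test_single_config_grid_returns_it(self, clustered_series):
        vs, labels = clustered_series
        design = TaskDesign.from_labels(labels)
        p = MapperParams(resolution=4, gain=2.0, filter_name="pca")
        assert parameter_search(vs, design, [p]) is p

    def test_task_separating_config_wins(self, clustered_series):
        vs, labels = clustered_series
        design = TaskDesign.from_labels(labels)
        # G=3 yields three task-pure components on this embedding; G=2
        # leaves clusters bridged through shared bins -> lower Q_mod
        good = MapperParams(resolution=2, gain=3.0, filter_name="pca")
        bad = MapperParams(resolution=2, gain=2.0, filter_name="pca")
        best, table = parameter_search(vs, design, [bad, good],
                                       return_table=True)
        assert best is good
        assert len(table) == 2
        scores = {r["gain"]: r["q_mod"] for r in table}
        assert scores[3.0] > scores[2.0]

    def test_empty_grid_rejected(self, clustered_series):
        vs, labels = clustered_series
        with pytest.raises(SearchError):
            parameter_search(vs, TaskDesign.from_labels(labels), [])
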