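"""The Mapper algorithm: from a frames × voxels matrix to a shape graph.

Mapper compresses a point cloud (here: one point per time frame, living in
voxel space) into a graph in five steps:

1. the matrix rows are the points;
2. a *filter* projects them to 2-D (default: a seeded t-SNE over the
   configured metric, Manhattan/L1 by default; a PCA fallback is registered
   for linear, fully deterministic projections);
3. the 2-D range is covered by ``R × R`` overlapping rectangular bins —
   per axis, base width ``range/R`` and bin width ``G × range/R``, so
   adjacent bins overlap by a fraction ``(G-1)/G``;
4. within each bin the member frames are condensed by single-linkage
   clustering *in the original voxel space*, cut at the first gap of the
   merge-distance histogram;
5. each cluster becomes a node; two nodes are joined by an edge iff they
   share at least one time frame.

Because bins overlap, a frame can sit in several nodes, and those shared
frames are what create edges: the graph's topology reflects how whole-brain
activity patterns recur and connect over the session.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)

__all__ = [
    "MapperParams",
    "FilterEmbedding",
    "CoverBin",
    "ShapeGraph",
    "compute_filter",
    "build_cover",
    "partial_cluster",
    "build_shape_graph",
    "build_mapper_graph",
    "parameter_search",
]

#: Accepted metric aliases -> scipy/sklearn metric names.
METRIC_ALIASES = {
    "l1": "manhattan",
    "manhattan": "manhattan",
    "cityblock": "manhattan",
    "l2": "euclidean",
    "euclidean": "euclidean",
    "correlation": "correlation",
    "cosine": "cosine",
}


class CoverageError(RuntimeError):
    """A frame ended up in no cluster — indicates a cover/cluster bug."""


class SearchError(RuntimeError):
    """No grid configuration produced a usable shape graph."""


@dataclass(frozen=True)
class MapperParams:
    """Mapper configuration.

    resolution
        Bins per filter axis (``R``); the 2-D cover has ``R**2`` bins.
    gain
        Overlap factor (``G``); per-axis bin width is ``G`` base widths,
        giving adjacent-bin overlap ``(G-1)/G``.
    metric
        Distance used both by the filter and by within-bin clustering
        (computed in the original voxel space). Default Manhattan (L1).
    filter_name
        Key into the filter registry (``tsne`` or ``pca``).
    seed
        Seed for the stochastic filter; recorded in every export.
    """

    resolution: int = 30
    gain: float = 3.0
    metric: str = "manhattan"
    filter_name: str = "tsne"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if self.metric.lower() not in METRIC_ALIASES:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def metric_name(self) -> str:
        return METRIC_ALIASES[self.metric.lower()]


@dataclass
class FilterEmbedding:
    """Frames × 2 filter coordinates plus the per-axis ranges."""

    coords: np.ndarray
    ranges: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must be frames x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")


@dataclass
class CoverBin:
    """One rectangular cover element with its member frame indices."""

    index: tuple[int, int]
    intervals: list[tuple[float, float]]
    members: np.ndarray


@dataclass
class ShapeGraph:
    """Mapper output: nodes are frame-index sets, edges mark shared frames."""

    nodes: list[np.ndarray]
    edges: list[tuple[int, int]]
    frame_count: int
    params: MapperParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def node_sizes(self) -> np.ndarray:
        return np.asarray([len(n) for n in self.nodes], dtype=int)

    def adjacency(self, weighted: bool = False) -> np.ndarray:
        """Symmetric adjacency; weights are shared-frame counts if requested."""
        a = np.zeros((self.node_count, self.node_count))
        for i, j in self.edges:
            w = 1.0
            if weighted:
                w = float(len(np.intersect1d(self.nodes[i], self.nodes[j])))
            a[i, j] = a[j, i] = w
        return a

    def frame_membership(self) -> list[list[int]]:
        """For each frame, the list of nodes containing it."""
        member: list[list[int]] = [[] for _ in range(self.frame_count)]
        for k, frames in enumerate(self.nodes):
            for f in frames:
                member[int(f)].append(k)
        return member

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, frames in enumerate(self.nodes):
            g.add_node(k, size=len(frames),
                       frames=",".join(str(int(f)) for f in frames))
        g.add_edges_from(self.edges)
        return g

    def to_json(self) -> str:
        doc = {
            "frame_count": self.frame_count,
            "nodes": [[int(f) for f in frames] for frames in self.nodes],
            "edges": [[int(i), int(j)] for i, j in self.edges],
            "params": None if self.params is None else {
                "resolution": self.params.resolution,
                "gain": self.params.gain,
                "metric": self.params.metric,
                "filter_name": self.params.filter_name,
                "seed": self.params.seed,
            },
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ShapeGraph":
        doc = json.loads(text)
        params = None
        if doc.get("params"):
            params = MapperParams(**doc["params"])
        return cls(
            nodes=[np.asarray(f, dtype=int) for f in doc["nodes"]],
            edges=[tuple(e) for e in doc["edges"]],
            frame_count=int(doc["frame_count"]),
            params=params,
            meta=doc.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Step 2: filter


def _filter_tsne(data: np.ndarray, params: MapperParams) -> np.ndarray:
    n = data.shape[0]
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        metric=params.metric_name,
        perplexity=perplexity,
        init="pca",
        random_state=params.seed,
    )
    return tsne.fit_transform(data)


def _filter_pca(data: np.ndarray, params: MapperParams) -> np.ndarray:
    return PCA(n_components=2, random_state=params.seed).fit_transform(data)


FILTER_REGISTRY = {"tsne": _filter_tsne, "pca": _filter_pca}


def compute_filter(vs, params: MapperParams) -> FilterEmbedding:
    """Project the frames × voxels matrix to 2-D filter coordinates.

    Deterministic for a fixed (input, params.seed). The default filter is a
    seeded t-SNE over the configured metric — a stochastic neighbor
    embedding that preserves local structure, standing in for proprietary
    nonlinear lenses; ``pca`` gives a linear principal-axes fallback.
    """
    data = np.asarray(vs.data if hasattr(vs, "data") else vs, dtype=np.float64)
    if data.shape[0] < 10:
        raise ValueError("need at least 10 frames to compute a filter")
    try:
        fn = FILTER_REGISTRY[params.filter_name]
    except KeyError:
        raise KeyError(
            f"unknown filter {params.filter_name!r}; "
            f"registered: {sorted(FILTER_REGISTRY)}"
        ) from None
    coords = np.asarray(fn(data, params), dtype=np.float64)
    ranges = [(float(coords[:, d].min()), float(coords[:, d].max()))
              for d in range(2)]
    return FilterEmbedding(coords=coords, ranges=ranges)


# ---------------------------------------------------------------------------
# Step 3: cover


def _axis_intervals(lo: float, hi: float, r: int, g: float):
    """Per-axis bin intervals: centers of the r base bins, width g*base."""
    if hi <= lo:  # degenerate axis: a single bin around the constant value
        logger.info("degenerate filter axis [%g, %g]; using one bin", lo, hi)
        return [(lo - 0.5, hi + 0.5)], True
    base = (hi - lo) / r
    half = g * base / 2.0
    centers = lo + (np.arange(r) + 0.5) * base
    return [(float(c - half), float(c + half)) for c in centers], False


def build_cover(emb: FilterEmbedding, params: MapperParams) -> list[CoverBin]:
    """Overlapping R × R rectangular cover of the embedding range.

    Intervals are closed; with ``G = 1`` (disjoint cover) a point on a
    shared boundary is assigned to the lower-index bin only, so the cover
    stays a partition.
    """
    r, g = params.resolution, params.gain
    axes = []
    for d in range(2):
        lo, hi = emb.ranges[d]
        intervals, degen = _axis_intervals(lo, hi, r, g)
        axes.append(intervals)
    x, y = emb.coords[:, 0], emb.coords[:, 1]

    def memberships(values, intervals):
        m = np.zeros((len(intervals), len(values)), dtype=bool)
        span = max(hi - lo for lo, hi in intervals)
        tol = 1e-9 * span  # guards extreme points against rounding
        for i, (lo, hi) in enumerate(intervals):
            m[i] = (values >= lo - tol) & (values <= hi + tol)
        if g == 1.0:  # boundary ties -> lower-index bin
            for i in range(1, len(intervals)):
                m[i] &= ~m[:i].any(axis=0)
        return m

    mx = memberships(x, axes[0])
    my = memberships(y, axes[1])
    bins: list[CoverBin] = []
    for ix, iy in itertools.product(range(len(axes[0])), range(len(axes[1]))):
        members = np.flatnonzero(mx[ix] & my[iy])
        bins.append(CoverBin(index=(ix, iy),
                             intervals=[axes[0][ix], axes[1][iy]],
                             members=members))
    covered = np.zeros(emb.coords.shape[0], dtype=bool)
    for b in bins:
        covered[b.members] = True
    if not covered.all():
        raise CoverageError("cover misses some embedded points")
    return bins


# ---------------------------------------------------------------------------
# Step 4: partial clustering


def first_gap_threshold(merge_distances: np.ndarray, nbins: int = 10) -> float | None:
    """Single-linkage cut threshold: left edge of the first empty histogram bin.

    Returns None when the histogram has no empty bin (no gap: keep one
    cluster), following the original Mapper convention.
    """
    d = np.asarray(merge_distances, dtype=float)
    if d.size == 0 or d.max() == d.min():
        return None
    counts, edges = np.histogram(d, bins=nbins,
                                 range=(float(d.min()), float(d.max())))
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return None
    return float(edges[empty[0]])


def partial_cluster(bin_: CoverBin, vs, params: MapperParams,
                    nbins: int = 10) -> list[np.ndarray]:
    """Single-linkage clustering of a bin's frames in original voxel space.

    The linkage is cut at the first gap in the merge-distance histogram
    (``nbins`` histogram bins); no gap means a single cluster. Distances use
    the configured metric on the raw frames-by-voxels rows, not on the 2-D
    embedding.
    """
    members = np.asarray(bin_.members, dtype=int)
    if members.size == 0:
        return []
    if members.size == 1:
        return [members.copy()]
    data = np.asarray(vs.data if hasattr(vs, "data") else vs)
    metric = "cityblock" if params.metric_name == "manhattan" else params.metric_name
    dists = pdist(data[members], metric=metric)
    z = linkage(dists, method="single")
    thr = first_gap_threshold(z[:, 2], nbins=nbins)
    if thr is None:
        return [members.copy()]
    assignment = fcluster(z, t=thr, criterion="distance")
    return [members[assignment == c] for c in np.unique(assignment)]


# ---------------------------------------------------------------------------
# Step 5: graph construction


def build_shape_graph(clusters_per_bin, frame_count: int,
                      params: MapperParams | None = None) -> ShapeGraph:
    """Nodes = clusters; edge iff two clusters share >= 1 time frame."""
    nodes: list[np.ndarray] = []
    for clusters in clusters_per_bin:
        for c in clusters:
            nodes.append(np.asarray(sorted(int(f) for f in c), dtype=int))
    covered = np.zeros(frame_count, dtype=bool)
    for c in nodes:
        covered[c] = True
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise CoverageError(f"{missing.size} frame(s) not covered, e.g. {missing[:5]}")
    # frames shared between nodes induce the edges
    frame_nodes: dict[int, list[int]] = {}
    for k, c in enumerate(nodes):
        for f in c:
            frame_nodes.setdefault(int(f), []).append(k)
    edge_set: set[tuple[int, int]] = set()
    for ks in frame_nodes.values():
        for a, b in itertools.combinations(ks, 2):
            edge_set.add((a, b) if a < b else (b, a))
    return ShapeGraph(nodes=nodes, edges=sorted(edge_set),
                      frame_count=frame_count, params=params)


def build_mapper_graph(vs, params: MapperParams,
                       emb: FilterEmbedding | None = None) -> ShapeGraph:
    """Run filter -> cover -> partial clustering -> graph in one call."""
    if emb is None:
        emb = compute_filter(vs, params)
    bins = build_cover(emb, params)
    clusters = [partial_cluster(b, vs, params) for b in bins]
    sg = build_shape_graph(clusters, emb.coords.shape[0], params=params)
    logger.info(
        "mapper: %d frames -> %d nodes, %d edges (R=%d, G=%g, %s/%s, seed=%d)",
        sg.frame_count, sg.node_count, len(sg.edges), params.resolution,
        params.gain, params.filter_name, params.metric, params.seed,
    )
    return sg


# ---------------------------------------------------------------------------
# Parameter search


def parameter_search(vs, design, grid, return_table: bool = False):
    """Pick the grid configuration whose graph best localizes the task.

    Each configuration is run end-to-end and scored by the task-community
    modularity of the annotated graph; the argmax is returned (first in grid
    order on ties). Embeddings are cached per (filter, metric, seed) since
    binning parameters do not affect the filter. Configurations yielding
    fewer than 2 nodes or no edges score ``-inf``.
    """
    from .mesoscale import annotate_nodes, modularity

    grid = list(grid)
    if not grid:
        raise SearchError("empty parameter grid")
    emb_cache: dict[tuple, FilterEmbedding] = {}
    rows = []
    best = None
    for params in grid:
        key = (params.filter_name, params.metric_name, params.seed)
        if key not in emb_cache:
            emb_cache[key] = compute_filter(vs, params)
        score = -np.inf
        n_nodes = n_edges = 0
        try:
            sg = build_mapper_graph(vs, params, emb=emb_cache[key])
            n_nodes, n_edges = sg.node_count, len(sg.edges)
            if n_nodes >= 2 and n_edges >= 1:
                ann = annotate_nodes(sg, design)
                score = modularity(sg, ann).q_mod
        except CoverageError:
            pass
        rows.append({"resolution": params.resolution, "gain": params.gain,
                     "metric": params.metric, "filter": params.filter_name,
                     "nodes": n_nodes, "edges": n_edges, "q_mod": score})
        logger.info("parameter_search: R=%d G=%g -> q_mod=%s",
                    params.resolution, params.gain, score)
        if best is None or score > best[0]:
            best = (score, params)
    if best is None or not np.isfinite(best[0]):
        raise SearchError("no grid configuration produced a scorable shape graph")
    return (best[1], rows) if return_table else best[1]
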