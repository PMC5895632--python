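"""Temporal projection of shape graphs and transition detection.

The shape graph lives over clusters of time frames; projecting it back onto
the time axis yields the *temporal connectivity matrix* (TCM): frames a and
b are connected iff they share a node, or sit in two nodes joined by an
edge. The per-frame normalized degree of the TCM, d_TCM in [0, 1], is high
when a frame resembles many others (evoked, stimulus-locked activity) and
low when it does not (intrinsic/rest activity), so task-block onsets and
offsets appear as mean shifts in the degree trace. Change points of that
trace recover task transitions at single-frame resolution.

Change-point detection is least-squares mean-shift binary segmentation:
recursively split the trace where the within-segment sum of squared errors
drops the most, either a fixed number of times (known count) or while the
drop exceeds a BIC-style penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import TaskDesign
from .mapper import CoverageError, ShapeGraph

__all__ = [
    "TCMatrix",
    "DegreeTrace",
    "TransitionSet",
    "build_tcm",
    "degree_trace",
    "detect_transitions",
    "single_split_oracle",
    "transition_lags",
    "block_fc_similarity",
]


@dataclass
class TCMatrix:
    """Binary symmetric frames × frames connectivity with zero diagonal."""

    matrix: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("TCM must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("TCM must be symmetric")
        np.fill_diagonal(m, False)
        self.matrix = m

    @property
    def frame_count(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DegreeTrace:
    """Per-frame normalized TCM degree, values in [0, 1]."""

    values: np.ndarray
    tr: float
    normalization: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class TransitionSet:
    """Detected change points (frame indices, strictly increasing)."""

    change_points: np.ndarray
    tr: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cp = np.asarray(self.change_points, dtype=int)
        if cp.size and (np.diff(cp) <= 0).any():
            raise ValueError("change points must be strictly increasing")
        self.change_points = cp

    @property
    def times_s(self) -> np.ndarray:
        return self.change_points * self.tr


def build_tcm(sg: ShapeGraph, frame_count: int | None = None,
              tr: float | None = None) -> TCMatrix:
    """Project a shape graph onto the time axis.

    ``T[a, b] = 1`` iff ``a != b`` and either some node contains both frames
    or some edge joins a node containing ``a`` to a node containing ``b``.
    With incidence B (frames × nodes) and node adjacency A this is
    ``B (A + I) B^T > 0`` off the diagonal.
    """
    t = sg.frame_count if frame_count is None else int(frame_count)
    b = np.zeros((t, sg.node_count), dtype=np.float64)
    for k, frames in enumerate(sg.nodes):
        if frames.size and frames.max() >= t:
            raise CoverageError("node refers to frames beyond frame_count")
        b[frames, k] = 1.0
    if not b.any(axis=1).all():
        raise CoverageError("some frames are not covered by any node")
    m = sg.adjacency() + np.eye(sg.node_count)
    tcm = (b @ m @ b.T) > 0
    np.fill_diagonal(tcm, False)
    return TCMatrix(matrix=tcm, tr=1.0 if tr is None else float(tr))


def degree_trace(tcm: TCMatrix) -> DegreeTrace:
    """d_TCM(t): row sum of the TCM divided by (frame_count - 1)."""
    t = tcm.frame_count
    if t < 2:
        raise ValueError("need at least 2 frames")
    d = tcm.matrix.sum(axis=1) / (t - 1)
    return DegreeTrace(values=d, tr=tcm.tr, normalization=t - 1)


# ---------------------------------------------------------------------------
# Change-point detection (mean shift, binary segmentation)


def _prefix_cost(y: np.ndarray):
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(a: int, b: int) -> float:
        """SSE of segment y[a:b] around its mean."""
        n = b - a
        if n <= 0:
            return 0.0
        s = s1[b] - s1[a]
        return float(s2[b] - s2[a] - s * s / n)

    return cost


def _optimal_segmentation(y: np.ndarray, n_splits: int,
                          min_size: int) -> list[int]:
    """Exact least-squares segmentation with a fixed number of splits.

    Dynamic programming over the same SSE cost as binary segmentation
    (optimal partitioning), so the result is the global optimum rather
    than the greedy approximation; for one split it coincides with the
    exhaustive single-split search.
    """
    t = y.size
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost_vec(starts: np.ndarray, end: int) -> np.ndarray:
        n = end - starts
        s = s1[end] - s1[starts]
        return s2[end] - s2[starts] - s * s / n

    inf = np.inf
    prev = np.full(t + 1, inf)
    for end in range(min_size, t + 1):
        prev[end] = s2[end] - s1[end] ** 2 / end
    back = np.zeros((n_splits, t + 1), dtype=int)
    for k in range(1, n_splits + 1):
        cur = np.full(t + 1, inf)
        for end in range((k + 1) * min_size, t + 1):
            starts = np.arange(k * min_size, end - min_size + 1)
            cand = prev[starts] + seg_cost_vec(starts, end)
            i = int(np.argmin(cand))
            cur[end] = cand[i]
            back[k - 1, end] = starts[i]
        prev = cur
    cps = []
    end = t
    for k in range(n_splits, 0, -1):
        end = int(back[k - 1, end])
        cps.append(end)
    return sorted(cps)


def _best_split(cost, a: int, b: int, min_size: int):
    """Split index s in (a, b) minimizing cost(a,s)+cost(s,b), and its gain."""
    best_s, best_c = None, np.inf
    for s in range(a + min_size, b - min_size + 1):
        c = cost(a, s) + cost(s, b)
        if c < best_c:
            best_s, best_c = s, c
    if best_s is None:
        return None, 0.0
    return best_s, cost(a, b) - best_c


def detect_transitions(trace: DegreeTrace, n_expected: int | None = None,
                       penalty: float | None = None,
                       min_size: int = 2) -> TransitionSet:
    """Least-squares mean-shift change points of the degree trace.

    With ``n_expected`` given, the exact optimum over segmentations with
    that many splits is found by dynamic programming (for one split this
    is the exhaustive single-split search). Otherwise greedy binary
    segmentation splits while the SSE reduction exceeds ``penalty``; the
    default penalty is BIC-style, ``2 * sigma^2 * log(T)`` with
    ``sigma^2`` estimated from first differences. Deterministic.
    """
    y = np.asarray(trace.values, dtype=np.float64)
    t = y.size
    if t < 10:
        raise ValueError("trace too short for change-point detection")
    if n_expected is not None:
        if n_expected >= t:
            raise ValueError("n_expected must be smaller than the trace "
                             "length")
        if (n_expected + 1) * min_size > t:
            raise ValueError("n_expected incompatible with min_size")
        cps = _optimal_segmentation(y, n_expected, min_size)
        return TransitionSet(change_points=np.asarray(cps, dtype=int),
                             tr=trace.tr,
                             meta={"n_expected": n_expected,
                                   "penalty": None, "min_size": min_size})
    if penalty is None:
        sigma2 = float(np.var(np.diff(y)) / 2.0)
        penalty = 2.0 * sigma2 * np.log(t)
    # numerical floor: prefix-sum costs carry ~1e-13 rounding noise
    penalty = max(penalty, 1e-9 * float(np.var(y)) * t, 1e-12)
    cost = _prefix_cost(y)
    segments = [(0, t)]
    cps: list[int] = []
    while True:
        best = None
        for (a, b) in segments:
            s, gain = _best_split(cost, a, b, min_size)
            if s is not None and (best is None or gain > best[0]):
                best = (gain, s, (a, b))
        if best is None or best[0] <= penalty:
            break
        gain, s, seg = best
        segments.remove(seg)
        segments.extend([(seg[0], s), (s, seg[1])])
        cps.append(s)
    return TransitionSet(change_points=np.sort(cps), tr=trace.tr,
                         meta={"n_expected": None, "penalty": penalty,
                               "min_size": min_size})


def single_split_oracle(trace: DegreeTrace, min_size: int = 2) -> int:
    """Exhaustive best single mean-shift split (reference for binseg)."""
    y = np.asarray(trace.values, dtype=np.float64)
    cost = _prefix_cost(y)
    s, _ = _best_split(cost, 0, y.size, min_size)
    if s is None:
        raise ValueError("trace too short to split")
    return s


# ---------------------------------------------------------------------------
# Evaluation against ground truth


def transition_lags(ts: TransitionSet, design: TaskDesign, tr: float,
                    kind: str = "both") -> pd.DataFrame:
    """Match each true task boundary to its nearest detected change point.

    Assignment is greedy by smallest |distance| without reusing detections;
    unmatched boundaries appear with NaN lag (misses). Lags are signed,
    ``(detected - true) * tr`` seconds. The frame ``mean_abs_lag_s`` /
    ``max_abs_lag_s`` summary lives in ``DataFrame.attrs``.
    """
    truths = design.boundaries(kind=kind)
    if truths.size == 0:
        raise ValueError("design declares no task boundaries")
    det = np.asarray(ts.change_points, dtype=int)
    rows = [{"boundary_frame": int(b), "detected_frame": np.nan, "lag_s": np.nan}
            for b in truths]
    if det.size == 0:
        warnings.warn("no detections to match against boundaries")
        out = pd.DataFrame(rows)
        out.attrs.update({"mean_abs_lag_s": np.nan, "max_abs_lag_s": np.nan,
                          "n_missed": len(rows)})
        return out
    pairs = sorted(
        ((abs(int(b) - int(d)), bi, di)
         for bi, b in enumerate(truths) for di, d in enumerate(det)),
        key=lambda x: (x[0], x[1], x[2]),
    )
    used_b: set[int] = set()
    used_d: set[int] = set()
    for _, bi, di in pairs:
        if bi in used_b or di in used_d:
            continue
        used_b.add(bi)
        used_d.add(di)
        rows[bi]["detected_frame"] = int(det[di])
        rows[bi]["lag_s"] = (int(det[di]) - int(truths[bi])) * tr
    out = pd.DataFrame(rows)
    lags = out["lag_s"].to_numpy(dtype=float)
    matched = lags[np.isfinite(lags)]
    out.attrs.update({
        "mean_abs_lag_s": float(np.abs(matched).mean()) if matched.size else np.nan,
        "max_abs_lag_s": float(np.abs(matched).max()) if matched.size else np.nan,
        "n_missed": int(np.isnan(lags).sum()),
    })
    return out


# ---------------------------------------------------------------------------
# Block-wise functional connectivity similarity


def block_fc_similarity(vs, design: TaskDesign, parcels: np.ndarray,
                        min_block_frames: int = 3):
    """Similarity of region-by-region FC across task blocks.

    Per block: region-mean time series -> Pearson FC -> Fisher z; block-pair
    similarity is the Pearson correlation of the vectorized upper triangles.
    Returns the block-pair similarity matrix (DataFrame indexed by
    ``label[block]``) and the participant mean over its upper triangle.
    Blocks shorter than ``min_block_frames`` are excluded with a warning.
    """
    parcels = np.asarray(parcels)
    if parcels.size != vs.voxel_count:
        raise ValueError("parcel labeling must cover every in-mask voxel")
    regions = np.unique(parcels)
    if regions.size < 2:
        raise ValueError("need at least 2 regions")
    blocks = design.task_blocks()
    kept, vectors = [], []
    for label, onset, offset in blocks:
        if offset - onset < min_block_frames:
            warnings.warn(f"block {(label, onset, offset)} shorter than "
                          f"{min_block_frames} frames; excluded")
            continue
        seg = vs.data[onset:offset]
        means = np.column_stack([seg[:, parcels == reg].mean(axis=1)
                                 for reg in regions])
        fc = np.corrcoef(means, rowvar=False)
        z = np.arctanh(np.clip(fc, -1 + 1e-15, 1 - 1e-15))
        iu = np.triu_indices(regions.size, k=1)
        vectors.append(z[iu])
        kept.append((label, onset, offset))
    if len(kept) < 2:
        raise ValueError("need at least 2 usable blocks")
    vecs = np.asarray(vectors)
    sim = np.corrcoef(vecs)
    names = [f"{label}[{onset}:{offset}]" for label, onset, offset in kept]
    df = pd.DataFrame(sim, index=names, columns=names)
    iu = np.triu_indices(len(kept), k=1)
    mean_sim = float(sim[iu].mean())
    return df, mean_sim
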