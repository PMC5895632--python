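"""Mesoscale structure of shape graphs: task communities and core-periphery.

Two complementary summaries of a task-annotated shape graph:

* **Modularity** ``Q_mod``: with each node assigned to the task supplying
  the majority of its time frames, how much more within-task connectivity
  is there than a degree-preserving random null expects?
  ``Q_mod = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] delta(g_i, g_j)``.
  High values mean distinct tasks occupy distinct graph neighborhoods.

* **Coreness score** ``CS``: a continuous [0, 1] core-periphery measure in
  the Borgatti-Everett tradition, computed with the Rombach generalization.
  For core-size parameter ``beta`` and transition sharpness ``alpha``, each
  node order induces local core values ``C_i`` (rank-based transition
  profile) and a quality ``R_(alpha,beta) = sum_ij A_ij C_i C_j``; the order
  is optimized by simulated annealing. CS aggregates ``C_i * R`` over a
  uniform (alpha, beta) grid on [0,1]^2 and is normalized so the deepest
  core node scores exactly 1.

Nodes with identical neighborhoods are interchangeable in any order without
changing ``R``; their aggregated scores are averaged so that symmetric
graphs (e.g. complete graphs, star leaves) receive symmetric scores instead
of arbitrary tie-breaks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .data_model import TaskDesign
from .mapper import ShapeGraph

__all__ = [
    "TaskAnnotation",
    "ModularityResult",
    "CorenessResult",
    "SASettings",
    "annotate_nodes",
    "modularity",
    "coreness_scores",
    "coreness_oracle",
    "coreness_by_task",
]


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for this graph (e.g. no edges)."""


# ---------------------------------------------------------------------------
# Task annotation


@dataclass
class TaskAnnotation:
    """Per-node majority task labels and label proportions."""

    majority: list[str]
    proportions: list[dict[str, float]]
    ties: np.ndarray
    label_order: list[str]

    @property
    def node_count(self) -> int:
        return len(self.majority)


def annotate_nodes(sg: ShapeGraph, design: TaskDesign) -> TaskAnnotation:
    """Label every node by the tasks of the frames it contains.

    The majority label is the most frequent frame label in the node; ties
    are broken by task_set order (then by other labels in order of first
    appearance) and flagged.
    """
    if design.frame_count < sg.frame_count:
        raise ValueError(
            f"design labels {design.frame_count} frames but graph covers "
            f"{sg.frame_count}"
        )
    label_order = list(design.task_set)
    for lab in design.labels:
        if lab not in label_order:
            label_order.append(str(lab))
    majority: list[str] = []
    proportions: list[dict[str, float]] = []
    ties = np.zeros(sg.node_count, dtype=bool)
    for k, frames in enumerate(sg.nodes):
        labs = [str(design.labels[int(f)]) for f in frames]
        counts = {lab: labs.count(lab) for lab in dict.fromkeys(labs)}
        total = len(labs)
        proportions.append({lab: c / total for lab, c in counts.items()})
        top = max(counts.values())
        winners = [lab for lab in label_order if counts.get(lab, 0) == top]
        majority.append(winners[0])
        ties[k] = len(winners) > 1
    return TaskAnnotation(majority=majority, proportions=proportions,
                          ties=ties, label_order=label_order)


# ---------------------------------------------------------------------------
# Modularity


@dataclass
class ModularityResult:
    q_mod: float
    unnormalized: float
    degrees: np.ndarray
    m: float
    p_null: np.ndarray


def modularity(sg: ShapeGraph, ann: TaskAnnotation,
               weighted: bool = False) -> ModularityResult:
    """Newman modularity of the majority-task partition.

    ``Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(g_i, g_j)`` with the
    configuration-model null ``P_ij = k_i k_j / 2m``. The raw (un-divided)
    sum is returned alongside.
    """
    a = sg.adjacency(weighted=weighted)
    k = a.sum(axis=1)
    two_m = a.sum()
    if two_m == 0:
        raise UndefinedMetricError("modularity is undefined for an edgeless graph")
    p = np.outer(k, k) / two_m
    g = np.asarray(ann.majority, dtype=object)
    delta = (g[:, None] == g[None, :])
    unnorm = float(((a - p) * delta).sum())
    return ModularityResult(q_mod=unnorm / two_m, unnormalized=unnorm,
                            degrees=k, m=two_m / 2.0, p_null=p)


# ---------------------------------------------------------------------------
# Coreness


@dataclass
class SASettings:
    """Simulated-annealing schedule for the order search."""

    proposals: int = 10_000
    restarts: int = 3
    t0: float = 1.0
    cooling: float = 0.9995


@dataclass
class CorenessResult:
    cs: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    r_grid: np.ndarray          # quality R at each (alpha, beta)
    c_grid: np.ndarray          # local core values, shape (n_alpha, n_beta, n_nodes)
    z: float
    sa: SASettings | None
    seed: int | None
    meta: dict = field(default_factory=dict)


def core_profile(n: int, alpha: float, beta: float) -> np.ndarray:
    """Rombach local core values by rank (1-based rank order).

    The first ``floor(beta*n)`` ranks form the periphery with values rising
    to ``(1-alpha)/2``; the remaining ranks form the core with values from
    ``(1+alpha)/2`` up to 1. ``alpha`` sets the size of the jump between
    the two segments, ``beta`` the boundary position.
    """
    bn = int(np.floor(beta * n))
    i = np.arange(1, n + 1, dtype=np.float64)
    c = np.empty(n, dtype=np.float64)
    if bn > 0:
        c[:bn] = i[:bn] * (1.0 - alpha) / (2.0 * bn)
    if bn < n:
        c[bn:] = (i[bn:] - bn) * (1.0 - alpha) / (2.0 * (n - bn)) + (1.0 + alpha) / 2.0
    return c


@njit(cache=True)
def _sa_order_search(indptr, indices, weights, corevec, proposals,
                     t0, cooling, seed):  # pragma: no cover - jitted
    n = corevec.size
    np.random.seed(seed)
    rank = np.random.permutation(n)
    c = np.empty(n)
    for i in range(n):
        c[i] = corevec[rank[i]]
    # R = sum_ij A_ij c_i c_j (ordered pairs)
    r = 0.0
    for u in range(n):
        s = 0.0
        for idx in range(indptr[u], indptr[u + 1]):
            s += weights[idx] * c[indices[idx]]
        r += c[u] * s
    best_r = r
    best_rank = rank.copy()
    t = t0
    for _ in range(proposals):
        u = np.random.randint(n)
        v = np.random.randint(n)
        if u == v:
            t *= cooling
            continue
        cu_new = corevec[rank[v]]
        cv_new = corevec[rank[u]]
        su = 0.0
        w_uv = 0.0
        for idx in range(indptr[u], indptr[u + 1]):
            j = indices[idx]
            if j == v:
                w_uv = weights[idx]
            else:
                su += weights[idx] * c[j]
        sv = 0.0
        for idx in range(indptr[v], indptr[v + 1]):
            j = indices[idx]
            if j != u:
                sv += weights[idx] * c[j]
        dr = 2.0 * ((cu_new - c[u]) * su + (cv_new - c[v]) * sv
                    + w_uv * (cu_new * cv_new - c[u] * c[v]))
        if dr > 0.0 or np.random.random() < np.exp(dr / t):
            tmp = rank[u]
            rank[u] = rank[v]
            rank[v] = tmp
            c[u] = cu_new
            c[v] = cv_new
            r += dr
            if r > best_r:
                best_r = r
                best_rank = rank.copy()
        t *= cooling
    return best_rank, best_r


def _quality(a: np.ndarray, c: np.ndarray) -> float:
    return float(c @ a @ c)


def _ab_grid(grid_step: float) -> np.ndarray:
    if not (0.0 < grid_step <= 1.0):
        raise ValueError("grid_step must be in (0, 1]")
    n = int(round(1.0 / grid_step))
    return np.linspace(0.0, 1.0, n + 1)


def _equivalence_classes(a: np.ndarray) -> list[np.ndarray]:
    """Groups of nodes with identical neighborhoods (ignoring each other)."""
    n = a.shape[0]
    deg = a.sum(axis=1)
    common = a @ a
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n):
        for v in range(u + 1, n):
            # rows differ at (deg_u + deg_v - 2 common_uv) positions; the two
            # positions u, v themselves differ iff A_uv != 0 (twice)
            mism = deg[u] + deg[v] - 2.0 * common[u, v] - 2.0 * (a[u, v] != 0)
            if mism == 0:
                parent[find(u)] = find(v)
    roots: dict[int, list[int]] = {}
    for u in range(n):
        roots.setdefault(find(u), []).append(u)
    return [np.asarray(v) for v in roots.values()]


def _aggregate(alphas, betas, r_grid, c_grid, a, symmetrize: bool):
    agg = np.tensordot(c_grid.reshape(-1, a.shape[0]).T,
                       r_grid.reshape(-1), axes=1)
    if symmetrize:
        for cls in _equivalence_classes(a):
            if cls.size > 1:
                agg[cls] = agg[cls].mean()
    top = agg.max()
    if top <= 0:
        warnings.warn("graph has no positive core quality; coreness degenerate")
        return np.ones_like(agg), 1.0
    return agg / top, 1.0 / top


def coreness_scores(sg: ShapeGraph, grid_step: float = 0.1,
                    sa: SASettings | None = None, seed: int = 0,
                    weighted: bool = False) -> CorenessResult:
    """Continuous coreness of every node via SA order optimization.

    For each (alpha, beta) on the grid, simulated annealing (with restarts,
    best kept) searches node orders maximizing
    ``R = sum_ij A_ij C_i C_j``; the aggregated score
    ``CS(i) = Z * sum_(alpha,beta) C_i(alpha,beta) * R(alpha,beta)`` is
    normalized by ``Z`` so the maximum is 1. Deterministic for fixed seed.
    """
    from scipy.sparse import csr_matrix

    sa = sa or SASettings()
    n = sg.node_count
    alphas = betas = _ab_grid(grid_step)
    if n == 1:
        warnings.warn("single-node graph: coreness degenerates to CS = 1")
        return CorenessResult(
            cs=np.ones(1), alphas=alphas, betas=betas,
            r_grid=np.zeros((alphas.size, betas.size)),
            c_grid=np.ones((alphas.size, betas.size, 1)),
            z=1.0, sa=sa, seed=seed,
        )
    a = sg.adjacency(weighted=weighted)
    csr = csr_matrix(a)
    indptr = csr.indptr.astype(np.int64)
    indices = csr.indices.astype(np.int64)
    weights = csr.data.astype(np.float64)

    r_grid = np.zeros((alphas.size, betas.size))
    c_grid = np.zeros((alphas.size, betas.size, n))
    for ia, alpha in enumerate(alphas):
        for ib, beta in enumerate(betas):
            corevec = core_profile(n, alpha, beta)
            runs = []
            for rep in range(sa.restarts):
                sub = (seed * 7919 + ia * 1009 + ib * 101 + rep) % (2**31 - 1)
                rank, _ = _sa_order_search(indptr, indices, weights, corevec,
                                           sa.proposals, sa.t0, sa.cooling, sub)
                c = corevec[rank]
                runs.append((_quality(a, c), c))  # exact recompute
            best_r = max(r for r, _ in runs)
            # average C over restarts that reached the optimum: tied optimal
            # orders (graph symmetries) then contribute symmetrically
            tol = 1e-9 * max(1.0, abs(best_r))
            tied = [c for r, c in runs if r >= best_r - tol]
            r_grid[ia, ib] = best_r
            c_grid[ia, ib] = np.mean(tied, axis=0)
    cs, z = _aggregate(alphas, betas, r_grid, c_grid, a, symmetrize=True)
    return CorenessResult(cs=cs, alphas=alphas, betas=betas, r_grid=r_grid,
                          c_grid=c_grid, z=z, sa=sa, seed=seed)


def coreness_oracle(sg: ShapeGraph, grid_step: float = 0.1,
                    weighted: bool = False, max_nodes: int = 9) -> CorenessResult:
    """Exhaustive-order reference for :func:`coreness_scores`.

    Enumerates every node order, takes the exact maximum of R per
    (alpha, beta) and averages local core values over *all* maximizing
    orders, so tied symmetric configurations contribute symmetrically.
    Only feasible for small graphs (<= 9 nodes).
    """
    n = sg.node_count
    if n > max_nodes:
        raise ValueError(f"oracle limited to {max_nodes} nodes, got {n}")
    alphas = betas = _ab_grid(grid_step)
    if n == 1:
        warnings.warn("single-node graph: coreness degenerates to CS = 1")
        return CorenessResult(
            cs=np.ones(1), alphas=alphas, betas=betas,
            r_grid=np.zeros((alphas.size, betas.size)),
            c_grid=np.ones((alphas.size, betas.size, 1)),
            z=1.0, sa=None, seed=None,
        )
    a = sg.adjacency(weighted=weighted)
    iu, jv = np.nonzero(np.triu(a, 1))
    w = a[iu, jv]
    # rank_mat[p, node] = 0-based rank of node in permutation p
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    rank_mat = np.empty_like(perms)
    np.put_along_axis(rank_mat, perms.astype(np.intp),
                      np.arange(n, dtype=np.int8)[None, :], axis=1)
    r_grid = np.zeros((alphas.size, betas.size))
    c_grid = np.zeros((alphas.size, betas.size, n))
    for ia, alpha in enumerate(alphas):
        for ib, beta in enumerate(betas):
            corevec = core_profile(n, alpha, beta)
            c_all = corevec[rank_mat]  # (n_perms, n)
            if iu.size:
                r_all = 2.0 * (w[None, :] * c_all[:, iu] * c_all[:, jv]).sum(axis=1)
            else:
                r_all = np.zeros(c_all.shape[0])
            rmax = r_all.max()
            tied = r_all >= rmax - 1e-12 * max(1.0, abs(rmax))
            r_grid[ia, ib] = rmax
            c_grid[ia, ib] = c_all[tied].mean(axis=0)
    cs, z = _aggregate(alphas, betas, r_grid, c_grid, a, symmetrize=False)
    return CorenessResult(cs=cs, alphas=alphas, betas=betas, r_grid=r_grid,
                          c_grid=c_grid, z=z, sa=None, seed=None)


def coreness_by_task(cs: CorenessResult, ann: TaskAnnotation) -> pd.DataFrame:
    """Mean and SD of CS per majority task label.

    Labels with a single node get SD 0; labels in the annotation order with
    zero nodes are omitted with a warning.
    """
    if len(cs.cs) != ann.node_count:
        raise ValueError("coreness and annotation cover different node sets")
    rows = []
    maj = np.asarray(ann.majority, dtype=object)
    for label in ann.label_order:
        vals = cs.cs[maj == label]
        if vals.size == 0:
            warnings.warn(f"no nodes with majority label {label!r}; omitted")
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({"task": label, "n_nodes": int(vals.size),
                     "mean_cs": float(vals.mean()), "sd_cs": sd})
    return pd.DataFrame(rows)
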