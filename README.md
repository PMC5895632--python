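# shapegraph

Topological data analysis of whole-brain fMRI dynamics at the single-frame
level. `shapegraph` turns a 4D scan (one point per acquired time frame, in
voxel space) into a **shape graph** via the Mapper algorithm, quantifies its
mesoscale organization, and recovers task transitions from the graph's
temporal projection — without averaging over space, time, or participants.

It is written for researchers studying ongoing cognition in multitask or
naturalistic fMRI who need single-session, single-frame summaries:

* **Mapper**: 2-D filter embedding (seeded t-SNE over Manhattan distance, or
  PCA) → overlapping `R × R` cover (resolution `R = 30`, gain `G = 3` by
  default) → within-bin single-linkage clustering in voxel space → nodes =
  clusters of frames, edges = shared frames.
* **Task-community modularity** of the annotated graph,
  `Q_mod = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(g_i, g_j)`.
* **Coreness scores** `CS(i) ∈ [0, 1]` (Borgatti–Everett/Rombach
  formulation): rank-profile core values `C_i(α, β)` optimized by simulated
  annealing to maximize `R_(α,β) = Σ_ij A_ij C_i C_j`, aggregated over a
  uniform `(α, β)` grid on `[0,1]²` and normalized to max 1. An
  exhaustive-order oracle validates the annealer on small graphs.
* **Temporal connectivity matrix (TCM)**: frames connected iff they share a
  node or their nodes share an edge; per-frame normalized degree `d_TCM`;
  task transitions as least-squares mean-shift change points (exact dynamic
  programming for a known count).
* **Null models**: a four-source noise simulator (Rician system noise,
  cardiac/respiratory sinusoids, AR temporal noise, Gaussian-random-field
  spatial noise, tissue-weighted) and Fourier phase randomization with
  per-voxel-random or constant phase sequences.
* **Synthetic session generator**: a continuous multitask block design
  (4 tasks × 2 × 3-min blocks, 12-s instruction periods, TR = 1.5 s,
  1017 frames) with HRF-convolved task patterns, so the entire pipeline is
  testable without any download.

## Worked example

```python
from shapegraph import (
    MapperParams, SASettings, annotate_nodes, build_mapper_graph, build_tcm,
    coreness_by_task, coreness_scores, degree_trace, detect_transitions,
    modularity, normalize_frames, simulate_cmp_session, transition_lags,
)

vs, design = simulate_cmp_session(seed=1, design_seed=0)  # 1017 x ~2100
vs = normalize_frames(vs)
sg = build_mapper_graph(vs, MapperParams(resolution=30, gain=3.0, seed=1))

ann = annotate_nodes(sg, design)
q = modularity(sg, ann)
cs = coreness_scores(sg, grid_step=0.25,
                     sa=SASettings(proposals=10_000, restarts=2), seed=1)
trace = degree_trace(build_tcm(sg, tr=vs.tr))
```

prints (via the obvious `print` statements):

```
shape graph: 3472 nodes, 20003 edges
task-community modularity Q_mod = 0.763
       task  n_nodes  mean_cs  sd_cs
       Rest      975    0.678  0.130
     Memory      788    0.741  0.117
       Math      751    0.692  0.127
      Video      615    0.765  0.122
instruction      343    0.659  0.118
mean d_TCM Rest: 0.029
mean d_TCM Memory: 0.142
mean d_TCM Math: 0.130
mean d_TCM Video: 0.072
```

Reading it: the session's frames compress into a graph whose node-level
task communities are strongly modular (`Q_mod = 0.76`); rest-labeled nodes
sit at the periphery (lowest mean CS) while evoked-task nodes occupy the
core; and rest frames are far less connected in time (`d_TCM = 0.03`) than
task frames (0.07–0.14) — evoked activity recurs, intrinsic activity
wanders. Change points of a *single* session's degree trace are noisy;
transition timing is evaluated on a group-mean trace over sessions sharing
one design (see below), where detected change points land within a few
frames (~2 s mean absolute lag) of the true evoked block boundaries.

A `shapegraph` CLI wraps the same library (`simulate`, `map`, `metrics`,
`transitions`, `run-all`, `split-half`, `perturb`); `run-all` consumes a
YAML config and writes a full artifact bundle (GraphML/JSON graph, node
table, metrics JSON, TCM, degree trace, transitions CSV), every artifact
stamped with the seed and config hash.

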