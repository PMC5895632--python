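# Methods

## Overview

`shapegraph` reconstructs the dynamical organization of whole-brain activity
from a single fMRI session without averaging over space or time. Each
acquired volume (time frame) is treated as one point in voxel space; the
Mapper algorithm from topological data analysis compresses the resulting
point cloud into a *shape graph*, whose mesoscale organization
(task communities, core–periphery structure) and temporal projection
(the temporal connectivity matrix, TCM) are then quantified.

The pipeline is: ingest/simulate → band-pass (optional) → per-voxel
normalization → 2-D filter embedding → overlapping cover → within-bin
single-linkage clustering → shape graph → task annotation → modularity
`Q_mod` + coreness `CS` → TCM → degree trace `d_TCM` → change-point
transitions.

## The Mapper construction

**Filter.** The frames × voxels matrix is projected to two dimensions with
a seeded t-SNE over the configured metric (Manhattan/L1 by default), which
preserves local neighborhood structure; a PCA filter is registered as a
linear, fully deterministic alternative and is used in many unit tests.
t-SNE is stochastic by nature; all runs fix `random_state` and use the
deterministic PCA initialization, so a given (input, seed) pair always
yields the same embedding on the same platform.

**Cover.** The embedding range is covered by `R × R` axis-aligned
rectangular bins: per axis, base width `range/R` with bin width
`G × range/R` centered on the base-bin centers, so adjacent bins overlap by
a fraction `(G−1)/G`. Defaults `R = 30`, `G = 3` (per-axis resolution; 900
bins in 2-D). With `G = 1` the cover is an exact partition; a point on a
shared boundary is assigned to the lower-index bin. Interval membership
uses a tolerance of 1e−9 of the bin width so extreme points are never lost
to rounding. A degenerate axis (zero range) collapses to a single bin and
is logged.

**Partial clustering.** Within each bin, members are clustered by single
linkage computed in the *original voxel space* (not the embedding) with the
same metric. The dendrogram is cut at the first empty bin of a 10-bin
histogram of the merge distances, taken over the observed distance range
`[min, max]`; no empty bin (or an all-equal set of distances) means one
cluster. The histogram spans the observed range rather than `[0, max]`
because pairwise distances between high-dimensional noisy frames
concentrate well away from zero — anchoring at zero would declare a gap
below the distance floor and shatter every bin into singletons.

**Graph.** Every cluster becomes a node (carrying its frame set); two
nodes are joined iff they share at least one frame. Edges are binary by
default — the sharing rule is existential — with shared-frame counts
available as optional weights.

**Parameter search.** `parameter_search` scores each configuration of a
grid end-to-end by the task-community modularity of the annotated graph and
returns the argmax (ties → first in grid order). Embeddings are cached per
(filter, metric, seed) since binning parameters do not affect the filter.
`perturbation_analysis` exposes the 7 × 7 grid `R ∈ {10..70}`,
`G ∈ {2..5}` (49 configurations) as a robustness report.

## Mesoscale metrics

**Modularity.** With each node assigned to the task contributing the
majority of its frames (ties broken by task-set order and flagged),

    Q_mod = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(g_i, g_j),

the standard Newman form with the configuration-model null. The
normalization by `1/2m` keeps `Q_mod` in [−1, 1]; the raw sum is also
reported. An edgeless graph has no defined modularity and raises.

**Coreness.** Core–periphery structure is scored with the continuous
(Borgatti–Everett-style) formulation: for parameters `(α, β)` a node order
induces local core values `C_i` via a rank profile — the first `⌊βN⌋` ranks
rise to `(1−α)/2`, the rest start at `(1+α)/2` and rise to 1, so `β` sets
the core size and `α` the sharpness of the boundary — and the order is
chosen to maximize `R_(α,β) = Σ_ij A_ij C_i C_j`. The aggregate score

    CS(i) = Z Σ_(α,β) C_i(α,β) · R(α,β)

sums over a uniform grid on `[0,1]²` (step 0.1 by default, 121 points) and
is normalized so `max_i CS(i) = 1`.

The order search is simulated annealing (numba-compiled): pairwise rank
swaps, geometric cooling (T₀ = 1, ratio 0.9995), 10⁴ proposals and 3
restarts by default, all seeded. Two degeneracy safeguards make symmetric
graphs score symmetrically: local core values are averaged across restarts
that reach the same optimum, and aggregated scores are averaged within
classes of structurally equivalent nodes (identical neighborhoods ignoring
each other). An exhaustive-order oracle (≤ 9 nodes) computes the exact
optimum per grid point and averages over *all* tied optimal orders; it is
the reference the SA path is validated against. Exactly tied optima are
also why the SA-vs-oracle comparison is summarized as a mean rank
correlation over many graphs rather than per graph: on a graph with
nontrivial ties the oracle's tie-average has no single-order counterpart.

## Temporal dynamics

**TCM.** Frames `a ≠ b` are connected iff they share a node or lie in two
adjacent nodes: with frame–node incidence `B` and node adjacency `A`,
`TCM = B (A + I) Bᵀ > 0` off the diagonal. The normalized degree
`d_TCM(t) = rowsum / (T − 1) ∈ [0, 1]` is high for frames resembling many
others (evoked activity) and low for idle frames.

**Transitions.** Task switches appear as mean shifts of the degree trace.
With a known change-point count the *exact* least-squares segmentation is
found by dynamic programming (optimal partitioning; for one split this is
the exhaustive single-split search); without a count, greedy binary
segmentation runs until the SSE gain drops below a BIC-style penalty
`2σ̂² log T` (σ̂² from first differences, with a small numerical floor so a
constant trace yields no detections). Minimum segment length is 2 frames.

**Lag evaluation.** True boundaries are matched to detections greedily by
smallest |distance| without reuse; unmatched boundaries are reported as
misses. Lags are signed, `(detected − true) × TR` seconds. The `evoked`
boundary kind evaluates only onsets/offsets of non-rest blocks: instruction
periods and rest are both idle states, so a rest↔instruction switch
produces no activity change and is undetectable in `d_TCM` by construction.
Because the BOLD response lags its stimulus by several seconds, detected
onsets trail true onsets by a few frames even in a perfect reconstruction.

**Block-FC similarity.** Per task block, region-mean time series → Pearson
FC → Fisher z; block-pair similarity is the Pearson correlation of the
vectorized upper triangles, and the participant mean averages the
upper triangle of the block-similarity matrix. Blocks shorter than 3 frames
are excluded.

## Null models

1. *Pure-noise simulation*: the sum of four independent, individually
   standardized sources — Rician system noise (magnitude of complex
   Gaussian, demeaned), cardiac (1.17 Hz) and respiratory (0.2 Hz)
   sinusoids with per-voxel phases, AR temporal noise (default AR(1),
   φ = 0.4), and per-frame Gaussian random fields smoothed to FWHM 4 mm —
   weighted (system 0.5, physio 0.5, AR 0.7, spatial 1.0) and scaled per
   tissue class (gray 1.0, white 0.6, CSF 1.3). At TR = 1.5 s the cardiac
   frequency lies above Nyquist and aliases; the aliased frequency is
   logged, mirroring real acquisitions.
2. *Phase randomization, per-voxel random phases*: every voxel's rFFT
   phases are rotated by independent uniform angles (DC and Nyquist bins
   untouched), preserving each amplitude spectrum exactly while destroying
   cross-voxel covariance and all nonstationary structure.
3. *Phase randomization, constant phase sequence*: one shared rotation
   vector for all voxels. Rotating (rather than replacing) phases preserves
   every cross-spectrum and hence the full covariance structure; only
   nonlinear/nonstationary structure is scrambled.

## The synthetic multitask session generator

The generator emulates a continuous multitask paradigm: four tasks
(Rest, Memory, Math, Video) × two blocks of 3 min, each block preceded by a
12-s instruction period, TR = 1.5 s, in a seeded random order with no task
immediately repeated. The full sequence (1024 frames) is truncated to the
default 1017-frame session. A `design_seed` can fix the block order
independently of the noise seed so a group of simulated participants shares
one experimental design, as a real study would.

Signal model, per voxel, on a synthetic three-shell spherical "brain"
(~2100 voxels, gray/white/CSF):

* the four-source noise above (σ_n = mean noise SD);
* *intrinsic wander*: 10 smooth spatial modes driven by slow AR(1)
  (φ = 0.9) time courses, amplitude 2.5 σ_n. During evoked blocks the
  wander gain drops (Memory 0.12, Math 0.18, Video 0.4) — task engagement
  stabilizes the brain state. This is the key geometric ingredient: rest
  frames drift widely through state space (mutually dissimilar →
  peripheral, low-degree), while evoked frames cluster tightly and
  reconnect across repeated blocks (core, high-degree), with per-task
  damping producing distinct `d_TCM` levels per task;
* *evoked responses*: per non-rest task a smooth gray-matter pattern
  (FWHM 6 mm, unit RMS) multiplied by the block boxcar convolved with a
  canonical double-gamma HRF (peak 6 s, undershoot 16 s), at amplitude
  `cnr × σ_n` for the strongest task (CNR = 1 by default, relative
  amplitudes Memory 1.0, Math 0.9, Video 0.6, Rest 0).

What this generator does *not* emulate: head motion, scanner drift,
physiologically realistic spatial covariance, individual anatomy,
task-correlated breathing, or the true dimensionality of cortical dynamics
(271k voxels in real scans vs ~2k here). Passing tests therefore show that
the pipeline recovers planted structure of the stated kind at realistic
noise levels — not that it would behave identically on any particular real
dataset. The real-data headline values (e.g. per-task CS means, ANOVA
statistics, behavioral correlations) depend on the original cohorts and are
out of scope.

## Numerical and design choices

* Band-pass: zero-phase forward–backward 2nd-order Butterworth; the
  simulated pipeline default leaves band-passing off because the block
  design's fundamental (~0.0026 Hz) lies below the conventional 0.009 Hz
  cutoff; it is available (and on by default) for real ingested data via
  config.
* Normalization: per-voxel demean + unit *sample* variance (n−1);
  zero-variance voxels are zeroed and logged, not an error. Idempotent.
* Voxel linearization: ascending (x, y, z) order of in-mask coordinates.
* Degree normalization: `T − 1` (the maximum possible TCM degree).
* Majority-label ties: task-set order, flagged for sensitivity analyses.
* Seeds: every stochastic component (filter, SA, simulation) takes an
  explicit seed recorded in all exported artifacts; the pipeline's config
  hash excludes only the output directory.
* Problem sizes in the validation suite (10 sessions of 1017 frames ×
  ~2100 voxels; coreness on a 0.25 grid with 10⁴ proposals × 2 restarts;
  50 random ≤ 8-node graphs for the SA-vs-oracle check) were chosen as the
  smallest group study at which the planted effects are comfortably
  resolved.

## Known limitations

* The proprietary nonlinear lens used in the original platform is
  unpublished; the seeded t-SNE filter is a documented equivalent, not a
  bit-compatible reimplementation, so node counts and layouts differ from
  the original tool even at identical (R, G).
* On iid-noise-dominated synthetic data the first-gap heuristic fragments
  sparsely populated bins into singletons, inflating node counts relative
  to real, spatially smooth data (~3900 nodes per 1017 frames at the
  default parameters). Contrasts (rest vs task CS, d_TCM) are unaffected.
* The SA coreness values on thousands-of-node graphs are partially
  optimized scores (the SA budget is far below the mixing time of the
  order chain); rankings and group contrasts are stable across seeds, but
  absolute CS values should not be compared across graphs of very
  different size.
* Phase-randomized surrogates retain each voxel's autocorrelation, so
  shape graphs built from them still contain temporally contiguous chains
  and nonzero task-labeled modularity; what vanishes is the rest-vs-task
  coreness and degree contrast, which is the property the null test uses.
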