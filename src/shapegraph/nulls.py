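"""Null models and a synthetic continuous-multitask (CMP) session generator.

Three null models make the pipeline testable without any real scan:

1. **Pure-noise simulation** — a 4D series that is only noise, built from
   four independent sources: Rician system noise, physiological sinusoids
   (cardiac ~1.17 Hz, respiratory ~0.2 Hz), autoregressive temporal noise,
   and spatially smooth Gaussian-random-field noise (FWHM-parameterized),
   each weighted per tissue class (gray/white/CSF).
2. **Phase randomization, per-voxel random phases** — preserves every
   voxel's amplitude spectrum while destroying cross-voxel covariance.
3. **Phase randomization, constant phase sequence** — rotates all voxels'
   spectra by one shared random phase vector, preserving both spectra and
   the full cross-covariance structure while scrambling nonlinear/task
   structure.

The evoked CMP generator is a synthetic stand-in for the real multitask
scans: four tasks x two 3-minute blocks, each preceded by a 12-second
instruction period, at TR = 1.5 s, with HRF-convolved task-specific spatial
patterns added to the four-source noise. Ongoing intrinsic activity is
modeled as a slow wander across smooth spatial modes; task engagement
partially stabilizes it (reduced wander gain during task blocks), which is
what gives rest frames their dispersed, peripheral geometry relative to the
tight task clusters the paper's method is designed to expose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .data_model import INSTRUCTION_LABEL, TaskDesign, VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseSpec",
    "EvokedSpec",
    "synthetic_brain_mask",
    "double_gamma_hrf",
    "simulate_null_fmri",
    "phase_randomize",
    "simulate_cmp_session",
    "math_trial_count",
]

GRAY, WHITE, CSF = 1, 2, 3


@dataclass
class NoiseSpec:
    """Parameters of the four noise sources.

    Amplitudes are relative weights of each source (each source is
    standardized to unit temporal variance before weighting); tissue
    weights scale the summed noise per tissue class.
    """

    system_amp: float = 0.5          # Rician system noise
    physio_amp: float = 0.5          # cardiac + respiratory sinusoids
    heart_hz: float = 1.17
    resp_hz: float = 0.2
    ar_amp: float = 0.7              # autoregressive temporal noise
    ar_coeffs: tuple[float, ...] = (0.4,)
    spatial_amp: float = 1.0         # Gaussian random field
    spatial_fwhm_mm: float = 4.0
    voxel_size_mm: float = 3.0
    tissue_weights: dict[int, float] = field(
        default_factory=lambda: {GRAY: 1.0, WHITE: 0.6, CSF: 1.3})

    def __post_init__(self) -> None:
        if self.spatial_fwhm_mm <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("FWHM and voxel size must be positive")
        for name in ("system_amp", "physio_amp", "ar_amp", "spatial_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.ar_coeffs)) >= 1:
            raise ValueError("AR coefficients must define a stationary process")


@dataclass
class EvokedSpec:
    """Task design and evoked-signal parameters of the CMP generator.

    ``task_amplitudes`` are relative evoked strengths (the rest task has no
    evoked response); ``cnr`` scales the strongest task's evoked amplitude
    relative to the mean noise standard deviation. ``rest_fluctuation``
    sets the intrinsic-wander amplitude on the same scale, and
    ``task_wander_gain`` is the factor by which task engagement suppresses
    that wander during task blocks.
    """

    task_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"Rest": 0.0, "Memory": 1.0,
                                 "Math": 0.9, "Video": 0.6})
    blocks_per_task: int = 2
    block_s: float = 180.0
    instruction_s: float = 12.0
    cnr: float = 1.0
    rest_fluctuation: float = 2.5
    task_wander_gain: dict[str, float] | float = field(
        default_factory=lambda: {"Memory": 0.12, "Math": 0.18, "Video": 0.4})
    n_wander_modes: int = 10
    wander_phi: float = 0.90
    pattern_fwhm_mm: float = 6.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0

    def __post_init__(self) -> None:
        if len(self.task_amplitudes) < 2:
            raise ValueError("need at least 2 tasks to build a block order")
        for amp in self.task_amplitudes.values():
            if amp < 0:
                raise ValueError("task amplitudes must be >= 0")


def synthetic_brain_mask(shape: tuple[int, int, int] = (18, 18, 18),
                         radius: float = 8.0):
    """A labeled spherical stand-in for a segmented brain (synthetic).

    Concentric shells: CSF core (~ventricles), white-matter shell, gray
    matter at the surface. Returns (mask, tissue) with tissue codes
    1=gray, 2=white, 3=CSF. Roughly 2100 in-mask voxels at the defaults.
    """
    center = (np.asarray(shape) - 1) / 2.0
    grid = np.indices(shape).astype(float)
    r = np.sqrt(((grid - center[:, None, None, None]) ** 2).sum(axis=0))
    mask = r <= radius
    tissue = np.zeros(shape, dtype=np.int8)
    tissue[r <= radius] = GRAY
    tissue[r <= radius * 0.65] = WHITE
    tissue[r <= radius * 0.3] = CSF
    return mask, tissue


def double_gamma_hrf(tr: float, duration_s: float = 32.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR.

    Positive gamma peaking at ``peak_s``, undershoot gamma at
    ``undershoot_s`` scaled by ``1/ratio``; normalized to peak 1.
    """
    t = np.arange(0.0, duration_s, tr)
    from scipy.stats import gamma as gamma_dist
    h = gamma_dist.pdf(t, peak_s, scale=1.0) - gamma_dist.pdf(
        t, undershoot_s, scale=1.0) / ratio
    return h / h.max()


def _standardize(x: np.ndarray) -> np.ndarray:
    """Scale a (frames x voxels) component to unit mean temporal variance."""
    s = x.std(axis=0).mean()
    return x if s == 0 else x / s


def _smooth_field(rng: np.random.Generator, mask: np.ndarray,
                  fwhm_mm: float, voxel_mm: float, n: int = 1) -> np.ndarray:
    """n spatially smooth zero-mean random maps over the mask, (n, V)."""
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_mm
    fields = rng.standard_normal((n,) + mask.shape)
    fields = ndimage.gaussian_filter(fields, sigma=(0,) * 1 + (sigma_vox,) * 3)
    flat = fields[:, mask]
    flat -= flat.mean(axis=1, keepdims=True)
    rms = np.sqrt((flat ** 2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return flat / rms


def simulate_null_fmri(mask: np.ndarray, frame_count: int, tr: float,
                       spec: NoiseSpec | None = None, seed: int = 0,
                       tissue: np.ndarray | None = None) -> VolumeSeries:
    """Four-source pure-noise 4D series (no task structure), seeded.

    Sources: (a) Rician system noise (magnitude of complex Gaussian,
    demeaned); (b) cardiac/respiratory sinusoids with per-voxel phases —
    frequencies at or above the TR Nyquist alias, which is logged;
    (c) AR temporal noise; (d) per-frame Gaussian random fields smoothed to
    the requested FWHM. Each source is standardized to unit mean temporal
    variance, weighted by its amplitude, summed and tissue-weighted.
    """
    spec = spec or NoiseSpec()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    if frame_count < 10:
        raise ValueError("need at least 10 frames")
    rng = np.random.default_rng(seed)
    v = int(mask.sum())
    t_s = np.arange(frame_count) * tr
    total = np.zeros((frame_count, v))

    if spec.system_amp > 0:
        re = rng.standard_normal((frame_count, v))
        im = rng.standard_normal((frame_count, v))
        ric = np.hypot(re, im)
        total += spec.system_amp * _standardize(ric - ric.mean(axis=0))

    if spec.physio_amp > 0:
        nyq = 1.0 / (2.0 * tr)
        physio = np.zeros((frame_count, v))
        for f in (spec.heart_hz, spec.resp_hz):
            if f >= nyq:
                alias = abs(f - round(f * tr) / tr)
                logger.info("physiological %.3f Hz aliases to %.3f Hz at "
                            "TR=%.3g s", f, alias, tr)
            phases = rng.uniform(0, 2 * np.pi, size=v)
            physio += np.sin(2 * np.pi * f * t_s[:, None] + phases[None, :])
        total += spec.physio_amp * _standardize(physio)

    if spec.ar_amp > 0:
        white = rng.standard_normal((frame_count + 50, v))
        coeffs = np.concatenate([[1.0], -np.asarray(spec.ar_coeffs)])
        ar = signal.lfilter([1.0], coeffs, white, axis=0)[50:]
        total += spec.ar_amp * _standardize(ar - ar.mean(axis=0))

    if spec.spatial_amp > 0:
        sigma_vox = (spec.spatial_fwhm_mm
                     / (2.0 * math.sqrt(2.0 * math.log(2.0)))
                     / spec.voxel_size_mm)
        fields = rng.standard_normal((frame_count,) + mask.shape)
        fields = ndimage.gaussian_filter(fields, sigma=(0, sigma_vox,
                                                        sigma_vox, sigma_vox))
        sp = fields[:, mask]
        total += spec.spatial_amp * _standardize(sp - sp.mean(axis=0))

    if tissue is not None:
        tissue = np.asarray(tissue)
        wvec = np.ones(v)
        labels = tissue[mask]
        for code, w in spec.tissue_weights.items():
            wvec[labels == code] = w
        total *= wvec[None, :]

    return VolumeSeries(data=total, tr=tr, mask=mask)


def phase_randomize(vs: VolumeSeries, mode: str = "random",
                    seed: int = 0) -> VolumeSeries:
    """Fourier phase-randomization surrogate of a volume series.

    Every voxel's amplitude spectrum is preserved exactly (the phases are
    *rotated* by random angles, DC and Nyquist bins untouched).
    ``mode="constant"`` applies one shared phase sequence to all voxels,
    preserving cross-covariance; ``mode="random"`` draws an independent
    sequence per voxel, destroying it.
    """
    if mode not in ("random", "constant"):
        raise ValueError(f"unknown mode {mode!r}; use 'random' or 'constant'")
    t, v = vs.data.shape
    if t < 4:
        raise ValueError("need at least 4 frames to phase-randomize")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(vs.data, axis=0)
    n_bins = spec.shape[0]
    # rotatable bins: exclude DC, and the Nyquist bin when t is even
    hi = n_bins - 1 if t % 2 == 0 else n_bins
    n_rot = hi - 1
    if mode == "constant":
        phases = np.repeat(rng.uniform(0, 2 * np.pi, size=(n_rot, 1)), v, axis=1)
    else:
        phases = rng.uniform(0, 2 * np.pi, size=(n_rot, v))
    rot = np.ones((n_bins, v), dtype=complex)
    rot[1:hi] = np.exp(1j * phases)
    surrogate = np.fft.irfft(spec * rot, n=t, axis=0)
    return replace(vs, data=surrogate)


def _block_order(tasks: list[str], blocks_per_task: int,
                 rng: np.random.Generator, max_tries: int = 10_000) -> list[str]:
    """Random block order where consecutive blocks are different tasks."""
    if len(tasks) < 2:
        raise ValueError("cannot avoid immediate repeats with a single task")
    pool = list(tasks) * blocks_per_task
    for _ in range(max_tries):
        order = list(rng.permutation(pool))
        if all(order[i] != order[i + 1] for i in range(len(order) - 1)):
            return [str(x) for x in order]
    raise RuntimeError("could not find a no-repeat block order")


def simulate_cmp_session(mask: np.ndarray | None = None,
                         spec: EvokedSpec | None = None,
                         noise: NoiseSpec | None = None,
                         tr: float = 1.5, seed: int = 0,
                         frame_count: int = 1017,
                         tissue: np.ndarray | None = None,
                         design_seed: int | None = None
                         ) -> tuple[VolumeSeries, TaskDesign]:
    """Simulate one continuous multitask session with ground-truth labels.

    Layout: ``blocks_per_task`` blocks per task in a seeded random order
    with no immediate task repeats, each block = instruction period then
    task period; the sequence is truncated to ``frame_count`` frames
    (default 1017, one 25.4-minute session at TR = 1.5 s). ``design_seed``
    fixes the block order independently of the noise seed, so a group of
    sessions can share one experimental design (as a multi-participant
    study would) while differing in noise; it defaults to ``seed``.

    Signal model per voxel: four-source noise + intrinsic wander (slow AR
    time courses on smooth spatial modes; gain reduced during task blocks)
    + HRF-convolved task-specific smooth gray-matter patterns whose
    amplitude is ``cnr`` x mean noise SD for the strongest task.
    """
    spec = spec or EvokedSpec()
    noise = noise or NoiseSpec()
    if mask is None:
        mask, tissue = synthetic_brain_mask()
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    design_rng = np.random.default_rng(seed if design_seed is None
                                       else design_seed)

    tasks = list(spec.task_amplitudes)
    order = _block_order(tasks, spec.blocks_per_task, design_rng)
    instr_f = int(round(spec.instruction_s / tr))
    block_f = int(round(spec.block_s / tr))
    labels: list[str] = []
    for task in order:
        labels.extend([INSTRUCTION_LABEL] * instr_f)
        labels.extend([task] * block_f)
    if len(labels) < frame_count:
        raise ValueError(
            f"design covers only {len(labels)} frames < {frame_count}")
    labels = labels[:frame_count]
    rest = next((t for t in tasks if spec.task_amplitudes[t] == 0), None)
    design = TaskDesign.from_labels(np.asarray(labels, dtype=object),
                                    task_set=tasks, rest_label=rest)

    base = simulate_null_fmri(mask, frame_count, tr, noise,
                              seed=int(rng.integers(2**31 - 1)),
                              tissue=tissue)
    sigma_n = base.data.std(axis=0).mean()
    data = base.data.copy()
    gray_flat = (np.asarray(tissue)[mask] == GRAY) if tissue is not None \
        else np.ones(int(mask.sum()), dtype=bool)

    # intrinsic wander: slow AR(1) time courses on smooth spatial modes,
    # damped while a task block is on
    if spec.rest_fluctuation > 0 and spec.n_wander_modes > 0:
        modes = _smooth_field(rng, mask, spec.pattern_fwhm_mm,
                              noise.voxel_size_mm, n=spec.n_wander_modes)
        white = rng.standard_normal((frame_count + 100, spec.n_wander_modes))
        courses = signal.lfilter([1.0], [1.0, -spec.wander_phi], white,
                                 axis=0)[100:]
        courses /= courses.std(axis=0, keepdims=True)
        wander = _standardize(courses @ modes)
        gain = np.ones(frame_count)
        if isinstance(spec.task_wander_gain, dict):
            gain_of = dict(spec.task_wander_gain)
        else:
            gain_of = {t: float(spec.task_wander_gain) for t in tasks}
        for i, lab in enumerate(design.labels):
            if lab in tasks and spec.task_amplitudes[lab] > 0:
                gain[i] = gain_of.get(lab, 0.2)
        data += spec.rest_fluctuation * sigma_n * gain[:, None] * wander

    # evoked responses: HRF-convolved boxcars x smooth task patterns
    hrf = double_gamma_hrf(tr, peak_s=spec.hrf_peak_s,
                           undershoot_s=spec.hrf_undershoot_s)
    max_amp = max(spec.task_amplitudes.values()) or 1.0
    for task in tasks:
        amp = spec.task_amplitudes[task]
        if amp == 0:
            continue
        boxcar = (design.labels == task).astype(float)
        reg = np.convolve(boxcar, hrf)[:frame_count]
        if reg.max() > 0:
            reg /= reg.max()
        pattern = np.zeros(int(mask.sum()))
        pat = _smooth_field(rng, mask, spec.pattern_fwhm_mm,
                            noise.voxel_size_mm)[0]
        pattern[gray_flat] = pat[gray_flat]
        rms = np.sqrt((pattern[gray_flat] ** 2).mean()) or 1.0
        pattern /= rms
        data += (spec.cnr * sigma_n * amp / max_amp) * reg[:, None] * pattern[None, :]

    vs = VolumeSeries(data=data, tr=tr, mask=mask)
    logger.info("simulated CMP session: %d frames x %d voxels, order %s",
                vs.frame_count, vs.voxel_count, "->".join(order))
    return vs, design


def math_trial_count(block_s: float, stim_s: float, gap_s: float) -> int:
    """Number of trials fitting in a block: floor(block / (stim + gap))."""
    period = stim_s + gap_s
    if period <= 0:
        raise ValueError("stimulus + gap duration must be positive")
    return int(math.floor(block_s / period))
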