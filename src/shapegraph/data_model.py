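"""Volumetric time-series ingestion and preprocessing.

A 4D fMRI scan is flattened into a frames × voxels matrix: one row per
acquired volume (time frame), one column per voxel inside a binary brain
mask. Columns follow the ascending (x, y, z) index order of the mask so
that the same mask always yields the same column layout. Downstream code
(the Mapper pipeline) treats each row as a point in voxel space.

This module assumes spatially preprocessed input (registration, motion
correction etc. happen upstream); it only offers temporal band-pass
filtering and per-voxel normalization, the two steps applied immediately
before graph construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSeries",
    "TaskDesign",
    "load_volume_series",
    "save_volume_series",
    "temporal_bandpass",
    "normalize_frames",
]

INSTRUCTION_LABEL = "instruction"


class DimensionError(ValueError):
    """Image and mask grids do not agree."""


@dataclass
class VolumeSeries:
    """A masked 4D scan as a frames × voxels matrix.

    Parameters
    ----------
    data
        Real matrix of shape ``(frame_count, voxel_count)``.
    tr
        Repetition time in seconds (time between consecutive frames).
    mask
        Boolean 3-D array; ``voxel_count`` equals its number of True voxels.
    affine
        4×4 voxel-to-world affine of the mask grid.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise DimensionError(f"data must be 2-D, got shape {self.data.shape}")
        if self.frame_count < 2:
            raise ValueError("a volume series needs at least 2 frames")
        n_mask = int(self.mask.sum())
        if n_mask == 0:
            raise ValueError("mask selects no voxels")
        if n_mask != self.voxel_count:
            raise DimensionError(
                f"mask has {n_mask} voxels but data has {self.voxel_count} columns"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def frame_count(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_count(self) -> int:
        return self.data.shape[1]

    @property
    def mask_coords(self) -> np.ndarray:
        """In-mask voxel coordinates, ascending (x, y, z) order; shape (V, 3)."""
        return np.argwhere(self.mask)  # argwhere is lexicographic == C order


@dataclass
class TaskDesign:
    """Per-frame task labels plus the block structure they imply.

    ``blocks`` are ``(label, onset, offset)`` triples with half-open frame
    intervals ``[onset, offset)``; ``task_set`` is the ordered list of task
    names (instruction periods are not tasks).
    """

    labels: np.ndarray
    task_set: list[str]
    blocks: list[tuple[str, int, int]]
    rest_label: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        prev_end = 0
        for label, onset, offset in self.blocks:
            if not (0 <= onset < offset <= len(self.labels)):
                raise ValueError(f"block {(label, onset, offset)} out of range")
            if onset < prev_end:
                raise ValueError("blocks must be disjoint and ordered")
            prev_end = offset
            if not all(l == label for l in self.labels[onset:offset]):
                raise ValueError(f"labels within block {(label, onset, offset)} disagree")

    @classmethod
    def from_labels(cls, labels, task_set: list[str] | None = None,
                    rest_label: str | None = None) -> "TaskDesign":
        """Derive the block structure from a per-frame label sequence."""
        labels = np.asarray(labels, dtype=object)
        blocks: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                blocks.append((str(labels[start]), start, i))
                start = i
        if task_set is None:
            task_set = []
            for lab in labels:
                if lab != INSTRUCTION_LABEL and lab not in task_set:
                    task_set.append(str(lab))
        return cls(labels=labels, task_set=list(task_set), blocks=blocks,
                   rest_label=rest_label)

    @property
    def frame_count(self) -> int:
        return len(self.labels)

    def task_blocks(self) -> list[tuple[str, int, int]]:
        """Blocks whose label is a task (instruction periods dropped)."""
        return [b for b in self.blocks if b[0] in self.task_set]

    def boundaries(self, kind: str = "onset") -> np.ndarray:
        """Ground-truth transition frames of the task blocks.

        kind: ``onset`` (task-block starts), ``offset`` (task-block ends,
        end-of-scan excluded), ``both``, or ``evoked`` — onsets and offsets
        of evoked blocks only, i.e. every block except ``rest_label``.
        Rest and instruction periods are both idle states, so a boundary
        between them produces no activity change; ``evoked`` keeps only
        boundaries at which evoked activity actually switches.
        """
        tb = self.task_blocks()
        if kind == "evoked":
            if self.rest_label is not None:
                tb = [b for b in tb if b[0] != self.rest_label]
            kind = "both"
        onsets = [b[1] for b in tb]
        offsets = [b[2] for b in tb if b[2] < self.frame_count]
        if kind == "onset":
            out = onsets
        elif kind == "offset":
            out = offsets
        elif kind == "both":
            out = sorted(set(onsets) | set(offsets))
        else:
            raise ValueError(f"unknown boundary kind {kind!r}")
        return np.asarray(out, dtype=int)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame_index": np.arange(self.frame_count), "label": self.labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, task_set: list[str] | None = None) -> "TaskDesign":
        df = pd.read_csv(path)
        df = df.sort_values("frame_index")
        if not np.array_equal(df["frame_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("frame_index must be 0..n-1 without gaps")
        return cls.from_labels(df["label"].astype(str).to_numpy(), task_set=task_set)

    def split_half(self) -> tuple["TaskDesign", "TaskDesign"]:
        """First/second half designs; an odd frame goes to the first half."""
        cut = (self.frame_count + 1) // 2
        first = TaskDesign.from_labels(self.labels[:cut], task_set=self.task_set,
                                       rest_label=self.rest_label)
        second = TaskDesign.from_labels(self.labels[cut:], task_set=self.task_set,
                                        rest_label=self.rest_label)
        return first, second


def load_volume_series(path, mask_path, tr: float | None = None) -> VolumeSeries:
    """Load a 4D NIfTI image and a 3D mask into a frames × voxels matrix.

    Column ``j`` of the result is the time series of the j-th in-mask voxel
    in ascending (x, y, z) coordinate order. ``tr`` overrides the value in
    the NIfTI header (zooms) when given.
    """
    img = nib.load(str(path))
    mask_img = nib.load(str(mask_path))
    if img.ndim != 4:
        raise DimensionError(f"expected a 4D image, got {img.ndim}D")
    if img.shape[:3] != mask_img.shape[:3]:
        raise DimensionError(
            f"image grid {img.shape[:3]} != mask grid {mask_img.shape[:3]}"
        )
    mask = np.asarray(mask_img.get_fdata()) > 0
    if not mask.any():
        raise ValueError("mask selects no voxels")
    vols = np.asarray(img.get_fdata(), dtype=np.float64)
    data = vols[mask].T  # boolean indexing walks the mask in C order -> (V, T)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(data=np.ascontiguousarray(data), tr=float(tr),
                        mask=mask, affine=np.asarray(img.affine))


def save_volume_series(vs: VolumeSeries, path) -> None:
    """Write the matrix back to a 4D NIfTI (zeros outside the mask)."""
    shape = vs.mask.shape + (vs.frame_count,)
    vols = np.zeros(shape, dtype=np.float64)
    vols[vs.mask] = vs.data.T
    img = nib.Nifti1Image(vols, vs.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (vs.tr,))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             np.eye(4) if affine is None else affine), str(path))


def temporal_bandpass(vs: VolumeSeries, low: float, high: float) -> VolumeSeries:
    """Zero-phase band-pass of every voxel time series.

    Second-order Butterworth applied forward-backward (``filtfilt``), so the
    pass band is ``(low, high)`` Hz and block boundaries are not shifted in
    time. Requires ``0 <= low < high < 1/(2 tr)``.
    """
    nyquist = 1.0 / (2.0 * vs.tr)
    if not (0.0 <= low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    if low == 0.0:
        b, a = signal.butter(2, high, btype="lowpass", fs=1.0 / vs.tr)
    else:
        b, a = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / vs.tr)
    filtered = signal.filtfilt(b, a, vs.data, axis=0)
    return replace(vs, data=filtered)


def normalize_frames(vs: VolumeSeries) -> VolumeSeries:
    """Demean each voxel time series and scale it to unit sample variance.

    Zero-variance (constant) voxels cannot be scaled; their columns are set
    to all zeros and a warning is emitted — real masks routinely contain a
    few such voxels and erroring out would be unhelpful.
    """
    mean = vs.data.mean(axis=0, keepdims=True)
    centered = vs.data - mean
    std = centered.std(axis=0, ddof=1, keepdims=True)
    constant = std[0] == 0.0
    if constant.any():
        n = int(constant.sum())
        warnings.warn(f"{n} constant voxel(s) set to zero during normalization")
        logger.info("normalize_frames: zeroed %d constant voxel(s)", n)
    std = np.where(std == 0.0, 1.0, std)
    out = centered / std
    out[:, constant] = 0.0
    return replace(vs, data=out)
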