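"""From block image stacks plus a label mask to a Cell x Channel matrix.

The measurement pipeline: concatenate the four acquisition-block stacks into
one multi-channel stack, maximum-intensity project it to a single image for
segmentation, apply a label mask (from any segmentation tool, or the built-in
fallback segmenter), and record the mean pixel intensity of every channel
inside every cell mask. The resulting n_cells x n_channels matrix is the unit
record for all downstream decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .spectral_core import AcquisitionScheme, channel_columns, default_scheme

log = logging.getLogger(__name__)

FORMAT_HEADER = "# cosidex-format v1"


@dataclass
class HyperStack:
    """channel x row x col intensity array tied to an acquisition scheme."""

    pixels: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("HyperStack pixels must be channel x row x col")
        if self.pixels.shape[0] != self.scheme.total_channels:
            raise ValueError(
                f"stack has {self.pixels.shape[0]} channels but scheme "
                f"defines {self.scheme.total_channels}"
            )
        if np.any(self.pixels < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class LabelMask:
    """Integer label image: 0 = background, positive integers = cell ids."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("label mask may not contain negative ids")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


@dataclass
class CellSpectraMatrix:
    """Per-cell mean pixel intensity at every channel (rows ordered by id)."""

    cell_ids: np.ndarray
    matrix: np.ndarray
    truth_labels: list[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.cell_ids.size:
            raise ValueError("matrix must have one row per cell id")
        if self.truth_labels is not None and len(self.truth_labels) != self.cell_ids.size:
            raise ValueError("truth_labels length must match cell_ids")

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    @property
    def n_channels(self) -> int:
        return int(self.matrix.shape[1])

    def radiances(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=channel_columns(self.n_channels))
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "truth_label", self.truth_labels if self.truth_labels else "")
        with open(path, "w") as fh:
            fh.write(FORMAT_HEADER + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellSpectraMatrix":
        df = pd.read_csv(path, comment="#")
        chans = [c for c in df.columns if c.startswith("ch")]
        truth = None
        if "truth_label" in df.columns:
            vals = df["truth_label"].fillna("").astype(str).tolist()
            if any(vals):
                truth = vals
        return cls(
            cell_ids=df["cell_id"].to_numpy(),
            matrix=df[chans].to_numpy(dtype=float),
            truth_labels=truth,
            source=str(path),
        )


def load_stacks(block_paths: Sequence, scheme: AcquisitionScheme | None = None) -> HyperStack:
    """Load block TIFFs and concatenate them channel-wise, in block order.

    Accepts either one file per acquisition block, or a single file already
    containing the full concatenated stack.
    """
    scheme = scheme or default_scheme()
    paths = [Path(p) for p in block_paths]
    arrays = [np.asarray(tifffile.imread(p)) for p in paths]
    for i, a in enumerate(arrays):
        if a.ndim == 2:
            arrays[i] = a[None, :, :]
        elif a.ndim != 3:
            raise ValueError(f"{paths[i]}: expected a 2-D or 3-D image")
    shapes = {a.shape[1:] for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"block files disagree on image shape: {sorted(shapes)}")
    if len(arrays) == 1:
        if arrays[0].shape[0] != scheme.total_channels:
            raise ValueError(
                f"{paths[0]}: expected {scheme.total_channels} channels in a "
                f"pre-concatenated stack, found {arrays[0].shape[0]}"
            )
        return HyperStack(pixels=arrays[0], scheme=scheme)
    if len(arrays) != len(scheme.blocks):
        raise ValueError(
            f"expected {len(scheme.blocks)} block files (or one concatenated "
            f"stack), got {len(arrays)}"
        )
    for p, a, block in zip(paths, arrays, scheme.blocks):
        if a.shape[0] != block.n_channels:
            raise ValueError(
                f"{p}: block {block.block_index} expects {block.n_channels} "
                f"channels, found {a.shape[0]}"
            )
    return HyperStack(pixels=np.concatenate(arrays, axis=0), scheme=scheme)


def load_mask(path) -> LabelMask:
    """Read an integer label-mask image (TIFF or PNG)."""
    arr = np.asarray(tifffile.imread(path)) if str(path).lower().endswith(
        (".tif", ".tiff")
    ) else None
    if arr is None:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    return LabelMask(labels=arr)


def max_intensity_projection(stack: HyperStack) -> np.ndarray:
    """Per-pixel maximum across all channels (the segmentation image)."""
    return stack.pixels.max(axis=0)


def segment_mip(
    mip: np.ndarray, min_area: int = 20, smoothing_sigma: float = 2.0
) -> LabelMask:
    """Simple built-in segmenter for the MIP image.

    Gaussian smoothing, Otsu threshold, connected components, then a
    watershed split on distance-transform maxima so touching cells separate.
    Deterministic for fixed inputs; an all-background image yields an empty
    mask rather than an error. Intended as a fallback — masks from a
    dedicated segmentation model can be supplied instead.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.ndim != 2:
        raise ValueError("segment_mip expects a 2-D image")
    smoothed = gaussian(mip, sigma=smoothing_sigma, preserve_range=True)
    if smoothed.max() <= smoothed.min():
        return LabelMask(labels=np.zeros(mip.shape, dtype=np.int32))
    thresh = threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        return LabelMask(labels=np.zeros(mip.shape, dtype=np.int32))
    dist = ndimage.distance_transform_edt(fg)
    # one marker per local distance peak, aggregated over a neighborhood the
    # size of a typical cell radius, keeps round cells from over-splitting
    footprint = np.ones((7, 7), dtype=bool)
    peaks = (dist == ndimage.maximum_filter(dist, footprint=footprint)) & fg
    markers = cc_label(peaks)
    labels = watershed(-dist, markers=markers, mask=fg)
    # drop fragments below min_area and relabel compactly
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return LabelMask(labels=out)


def extract_cell_spectra(
    stack: HyperStack,
    mask: LabelMask,
    truth_labels: dict[int, str] | None = None,
    source: str = "",
) -> CellSpectraMatrix:
    """Mean pixel intensity per channel per cell mask, rows by ascending id."""
    if mask.labels.shape != stack.shape_2d:
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match stack "
            f"shape {stack.shape_2d}"
        )
    ids = mask.cell_ids
    if ids.size == 0:
        raise ValueError("label mask contains no cells")
    n_ch = stack.pixels.shape[0]
    out = np.empty((ids.size, n_ch), dtype=float)
    for ch in range(n_ch):
        out[:, ch] = ndimage.mean(stack.pixels[ch], labels=mask.labels, index=ids)
    truth = None
    if truth_labels is not None:
        truth = [truth_labels[int(i)] for i in ids]
    return CellSpectraMatrix(cell_ids=ids, matrix=out, truth_labels=truth, source=source)
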