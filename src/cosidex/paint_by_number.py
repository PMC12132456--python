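"""Render decoded scenes: pseudocolored cell masks on a grayscale MIP.

Non-cell pixels show the grayscale maximum-intensity projection; each cell's
pixels take its predicted FP's RGB color, with brightness scaled
monotonically by the cell's radiance (min-max of log10 radiance mapped to
[0.3, 1.0], gamma-adjustable — the 0.3 floor keeps dim cells visible).
FPs can be filtered, individual cells highlighted with a complementary
outline, and per-cell spectra retrieved for side-by-side comparison with
the predicted reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import find_boundaries

from .decoder import UNCLASSIFIED, ClassificationResult
from .image_pipeline import CellSpectraMatrix, LabelMask
from .reference_library import ReferenceLibrary
from .spectral_core import cosine_similarity

# fixed 16-color cycle used when no colormap is supplied (library order)
DEFAULT_COLOR_CYCLE: list[tuple[int, int, int]] = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
    (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
]

GRAY = (180, 180, 180)


@dataclass
class ColorMap:
    colors: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    unclassified_color: tuple[int, int, int] = GRAY

    def color_for(self, fp_name: str) -> tuple[int, int, int]:
        if fp_name == UNCLASSIFIED:
            return self.unclassified_color
        if fp_name in self.colors:
            return self.colors[fp_name]
        # stable fallback: cycle position by insertion order of first use
        idx = len(self.colors) % len(DEFAULT_COLOR_CYCLE)
        self.colors[fp_name] = DEFAULT_COLOR_CYCLE[idx]
        return self.colors[fp_name]

    @classmethod
    def from_names(cls, fp_names) -> "ColorMap":
        return cls(
            colors={
                name: DEFAULT_COLOR_CYCLE[i % len(DEFAULT_COLOR_CYCLE)]
                for i, name in enumerate(fp_names)
            }
        )


def complementary(rgb: tuple[int, int, int]) -> tuple[int, int, int]:
    r, g, b = rgb
    return (255 - r, 255 - g, 255 - b)


@dataclass
class RenderOptions:
    show_outlines: bool = False
    color_enabled: bool = True
    visible_fps: set[str] | None = None
    highlight_cells: set[int] | None = None
    intensity_gamma: float = 1.0
    brightness_floor: float = 0.3


def _grayscale(mip: np.ndarray) -> np.ndarray:
    mx = mip.max()
    norm = mip / mx if mx > 0 else np.zeros_like(mip)
    return (norm * 255).astype(np.uint8)


def render(
    mip: np.ndarray,
    mask: LabelMask,
    result: ClassificationResult,
    cells: CellSpectraMatrix,
    colors: ColorMap | None = None,
    options: RenderOptions | None = None,
) -> np.ndarray:
    """Pseudocolored RGB image (uint8, row x col x 3)."""
    options = options or RenderOptions()
    if colors is None:
        colors = ColorMap.from_names(
            [p for p in dict.fromkeys(result.predicted_fp) if p != UNCLASSIFIED]
        )
    mip = np.asarray(mip, dtype=float)
    if mip.shape != mask.labels.shape:
        raise ValueError("MIP and mask shapes differ")
    mask_ids = set(int(i) for i in mask.cell_ids)
    result_ids = set(int(i) for i in result.cell_ids)
    missing = sorted(mask_ids - result_ids)
    if missing:
        raise ValueError(f"mask cell ids missing from classification: {missing}")

    gray = _grayscale(mip)
    rgb = np.stack([gray] * 3, axis=-1)
    if not options.color_enabled:
        return rgb

    pred_of = {int(i): p for i, p in zip(result.cell_ids, result.predicted_fp)}
    rad_of = {int(i): r for i, r in zip(cells.cell_ids, cells.radiances())}

    # radiance -> brightness: min-max of log10 radiance to [floor, 1]
    log_rad = {
        i: np.log10(r) if r > 0 else None for i, r in rad_of.items() if i in mask_ids
    }
    finite = [v for v in log_rad.values() if v is not None]
    lo = min(finite) if finite else 0.0
    hi = max(finite) if finite else 1.0
    span = hi - lo

    for cid in sorted(mask_ids):
        fp = pred_of[cid]
        visible = (
            fp != UNCLASSIFIED
            and (options.visible_fps is None or fp in options.visible_fps)
        )
        sel = mask.labels == cid
        if not visible:
            continue  # hidden / unclassified cells keep the grayscale MIP
        lr = log_rad.get(cid)
        if lr is None:
            scale = options.brightness_floor
        else:
            t = (lr - lo) / span if span > 0 else 1.0
            scale = options.brightness_floor + (1.0 - options.brightness_floor) * (
                t**options.intensity_gamma
            )
        color = np.array(colors.color_for(fp), dtype=float) * scale
        rgb[sel] = np.clip(color, 0, 255).astype(np.uint8)
        outline_this = options.show_outlines or (
            options.highlight_cells is not None and cid in options.highlight_cells
        )
        if outline_this:
            edge = find_boundaries(sel, mode="inner")
            rgb[edge] = complementary(colors.color_for(fp))
    return rgb


def save_png(rgb: np.ndarray, path) -> None:
    """Deterministic PNG export (fixed encoder settings)."""
    from PIL import Image

    Image.fromarray(rgb, mode="RGB").save(path, format="PNG", compress_level=6)


def legend_counts(result: ClassificationResult) -> dict[str, int]:
    """Cell counts per predicted FP; counts partition the total."""
    if result.n_cells == 0:
        raise ValueError("empty classification result")
    counts: dict[str, int] = {}
    for p in result.predicted_fp:
        counts[p] = counts.get(p, 0) + 1
    return counts


def cell_spectrum(
    cells: CellSpectraMatrix,
    result: ClassificationResult,
    library: ReferenceLibrary,
    cell_id: int,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """A cell's spectrum, its predicted FP's reference spectrum, and the MCS.

    The reference is None for unclassified cells (similarity NaN).
    """
    matches = np.where(cells.cell_ids == cell_id)[0]
    if matches.size == 0:
        raise KeyError(f"cell id {cell_id} not found")
    row = int(matches[0])
    spectrum = cells.matrix[row].copy()
    r_matches = np.where(result.cell_ids == cell_id)[0]
    if r_matches.size == 0:
        raise KeyError(f"cell id {cell_id} not in classification result")
    pred = result.predicted_fp[int(r_matches[0])]
    if pred == UNCLASSIFIED:
        return spectrum, None, float("nan")
    ref = library[pred].spectrum.values.copy()
    mcs = cosine_similarity(spectrum, ref)
    return spectrum, ref, mcs
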