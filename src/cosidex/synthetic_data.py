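"""Ground-truthed synthetic hyperspectral scenes.

The generator emulates what the microscope produces: for each fluorescent
protein, a model emission spectrum sampled on the 4-block channel grid
(Gaussian excitation and emission profiles, per-block excitation efficiency
at the block's laser lines, and a notch guard above the laser line); for
each scene, cells rendered as discs of expected intensity
``expression_level x model_spectrum`` plus background and detector noise,
with the exact label mask and per-cell identities carried along as ground
truth. Gaussian profiles stand in for true (asymmetric) FP spectra — shape
fidelity is irrelevant to exercising the decoder's contracts, and measured
spectra can always be supplied as a reference library instead.

Expression levels are log-normal across cells (median ~10^4.5 detector
units, 0.3 decades spread), which puts per-cell radiance in the 10^4.5-10^5.5
range typical of bright FPs under fixed confocal settings. Detector noise
is additive Gaussian (default sd 20 units/pixel) with optional Poisson shot
noise on the expected counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .image_pipeline import HyperStack, LabelMask
from .spectral_core import AcquisitionScheme, Spectrum, default_scheme

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# study conditions for generated experiments
EXPRESSION_LOG10_MEAN = 4.5
EXPRESSION_LOG10_SD = 0.3
DEFAULT_GAUSSIAN_SD = 20.0
DEFAULT_BACKGROUND = 5.0
DEFAULT_CELL_RADIUS = 3
NOTCH_GUARD_NM = 10.0
CLONE_DILUTION_PER_DAY = 0.6


@dataclass(frozen=True)
class SyntheticFP:
    """Gaussian-profile fluorescent protein for the simulator."""

    name: str
    ex_max_nm: float
    em_max_nm: float
    ex_width_nm: float = 55.0  # FWHM
    em_width_nm: float = 35.0  # FWHM
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.em_max_nm < self.ex_max_nm:
            raise ValueError(f"{self.name}: Stokes shift must be >= 0")
        if self.ex_width_nm <= 0 or self.em_width_nm <= 0:
            raise ValueError(f"{self.name}: spectral widths must be positive")
        if self.brightness <= 0:
            raise ValueError(f"{self.name}: brightness must be positive")


def model_spectrum(
    fp: SyntheticFP,
    scheme: AcquisitionScheme | None = None,
    notch_guard_nm: float = NOTCH_GUARD_NM,
) -> Spectrum:
    """The FP's expected per-channel signature on the acquisition grid.

    Per block: intensity at a channel = brightness x (sum over the block's
    laser lines of the Gaussian excitation efficiency at that laser) x the
    Gaussian emission density at the channel center. Channels below the
    block's highest laser line + ``notch_guard_nm`` are zeroed, mimicking
    the detector's laser-exclusion margin. Blocks concatenate in order.
    """
    scheme = scheme or default_scheme()
    sig_ex = fp.ex_width_nm * _FWHM_TO_SIGMA
    sig_em = fp.em_width_nm * _FWHM_TO_SIGMA
    parts = []
    for block in scheme.blocks:
        centers = block.channel_centers_nm()
        ex_eff = sum(
            np.exp(-((laser - fp.ex_max_nm) ** 2) / (2.0 * sig_ex**2))
            for laser in block.laser_lines_nm
        )
        em = np.exp(-((centers - fp.em_max_nm) ** 2) / (2.0 * sig_em**2))
        vals = fp.brightness * ex_eff * em
        vals[centers < max(block.laser_lines_nm) + notch_guard_nm] = 0.0
        # flush far-tail underflow to exact zero so out-of-band FPs yield a
        # genuinely empty (flaggable) spectrum rather than 1e-100 residue
        vals[vals < fp.brightness * 1e-20] = 0.0
        parts.append(vals)
    return Spectrum(values=np.concatenate(parts), label=fp.name)


@dataclass(frozen=True)
class CellSpec:
    center: tuple[int, int]  # row, col
    radius: int
    fp_name: str
    expression_level: float


@dataclass
class SceneSpec:
    image_shape: tuple[int, int]
    cells: list[CellSpec]
    seed: int
    gaussian_sd: float = DEFAULT_GAUSSIAN_SD
    poisson_enabled: bool = False
    background_level: float = DEFAULT_BACKGROUND

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        with open(path) as fh:
            data = json.load(fh)
        data["cells"] = [
            CellSpec(
                center=tuple(c["center"]),
                radius=c["radius"],
                fp_name=c["fp_name"],
                expression_level=c["expression_level"],
            )
            for c in data["cells"]
        ]
        data["image_shape"] = tuple(data["image_shape"])
        return cls(**data)


@dataclass
class SceneResult:
    stack: HyperStack
    mask: LabelMask
    truth: dict[int, str]  # cell id -> FP name
    spec: SceneSpec
    overlapping_cells: list[int] = field(default_factory=list)

    def block_stacks(self) -> list[np.ndarray]:
        return [self.stack.pixels[s] for s in self.stack.scheme.block_slices()]

    def write(self, out_dir) -> None:
        """Block TIFFs, truth-mask TIFF, truth CSV and the scene JSON."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, blk in enumerate(self.block_stacks(), start=1):
            tifffile.imwrite(out / f"block{i}.tif", blk.astype(np.float32))
        tifffile.imwrite(out / "truth_mask.tif", self.mask.labels.astype(np.int32))
        with open(out / "truth.csv", "w") as fh:
            fh.write("cell_id,fp_name\n")
            for cid in sorted(self.truth):
                fh.write(f"{cid},{self.truth[cid]}\n")
        self.spec.to_json(out / "scene.json")


def _disc(center: tuple[int, int], radius: int, shape: tuple[int, int]):
    from skimage.draw import disk

    return disk(center, radius + 0.5, shape=shape)


def simulate_scene(
    spec: SceneSpec,
    fps: dict[str, SyntheticFP],
    scheme: AcquisitionScheme | None = None,
) -> SceneResult:
    """Render a scene: discs of expected FP signal, background, noise.

    Deterministic for a fixed ``spec.seed``. Overlapping cells are allowed
    but flagged; cells whose disc leaves the image are an error.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    n_ch = scheme.total_channels
    stack = np.full((n_ch, rows, cols), float(spec.background_level), dtype=np.float32)
    labels = np.zeros((rows, cols), dtype=np.int32)
    truth: dict[int, str] = {}
    overlapping: list[int] = []

    spectra_cache: dict[str, np.ndarray] = {}
    for cell_id, cell in enumerate(spec.cells, start=1):
        if cell.fp_name not in fps:
            raise KeyError(f"cell {cell_id}: FP {cell.fp_name!r} not defined")
        r, c = cell.center
        if (
            r - cell.radius < 0
            or c - cell.radius < 0
            or r + cell.radius >= rows
            or c + cell.radius >= cols
        ):
            raise ValueError(f"cell {cell_id} at {cell.center} extends out of bounds")
        if cell.fp_name not in spectra_cache:
            spectra_cache[cell.fp_name] = model_spectrum(
                fps[cell.fp_name], scheme
            ).values.astype(np.float32)
        vec = spectra_cache[cell.fp_name]
        rr, cc = _disc(cell.center, cell.radius, (rows, cols))
        if np.any(labels[rr, cc] > 0):
            overlapping.append(cell_id)
        stack[:, rr, cc] += cell.expression_level * vec[:, None]
        labels[rr, cc] = cell_id
        truth[cell_id] = cell.fp_name

    if spec.poisson_enabled:
        stack = rng.poisson(stack).astype(np.float32)
    if spec.gaussian_sd > 0:
        stack += rng.standard_normal(stack.shape, dtype=np.float32) * np.float32(
            spec.gaussian_sd
        )
    np.clip(stack, 0.0, None, out=stack)
    return SceneResult(
        stack=HyperStack(pixels=stack, scheme=scheme),
        mask=LabelMask(labels=labels),
        truth=truth,
        spec=spec,
        overlapping_cells=overlapping,
    )


def _grid_layout(
    n_cells: int, radius: int, rng: np.random.Generator, jitter: int = 1
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Jittered-grid, non-overlapping cell centers and a fitting image shape."""
    pitch = 2 * radius + 3 + 2 * jitter
    side = int(np.ceil(np.sqrt(n_cells)))
    margin = radius + jitter + 1
    shape = (side * pitch + 2 * margin, side * pitch + 2 * margin)
    centers = []
    for k in range(n_cells):
        i, j = divmod(k, side)
        r = margin + i * pitch + pitch // 2 + int(rng.integers(-jitter, jitter + 1))
        c = margin + j * pitch + pitch // 2 + int(rng.integers(-jitter, jitter + 1))
        centers.append((r, c))
    return centers, shape


def _draw_expression(rng: np.random.Generator, n: int) -> np.ndarray:
    return 10.0 ** rng.normal(EXPRESSION_LOG10_MEAN, EXPRESSION_LOG10_SD, size=n)


@dataclass
class ExperimentResult:
    design: str
    scenes: list[SceneResult]
    scene_names: list[str]
    panel: dict[str, SyntheticFP]
    missing_fp: str | None = None


def simulate_experiment(
    design: str,
    n_fps: int = 3,
    n_cells: int = 100,
    days: int = 1,
    noise_sd: float = DEFAULT_GAUSSIAN_SD,
    seed: int = 0,
    missing_fp: str | None = None,
    panel: dict[str, SyntheticFP] | None = None,
    cell_radius: int = DEFAULT_CELL_RADIUS,
    poisson: bool = False,
    scheme: AcquisitionScheme | None = None,
) -> ExperimentResult:
    """Generate a ground-truthed experiment of a standard design.

    Designs
    -------
    ``monoculture``  one scene per panel FP, all cells that FP.
    ``equal_mix``    one scene, identities uniform over the panel.
    ``fpmo``         one scene, uniform over the panel minus ``missing_fp``
                     (default: the last panel member); the decoder is still
                     offered the full panel downstream.
    ``clonal_growth`` one scene per day; seeded single cells grow a ring of
                     adjacent cells each day while expression decays by
                     ``CLONE_DILUTION_PER_DAY`` per day (plasmid dilution
                     across divisions).
    """
    if panel is None:
        panel = {fp.name: fp for fp in default_fp_panel(n_fps)}
    names = list(panel)
    rng = np.random.default_rng(seed)
    scenes: list[SceneResult] = []
    scene_names: list[str] = []

    def make_scene(assignments: list[str], sub_seed: int, expr=None) -> SceneResult:
        sub_rng = np.random.default_rng(sub_seed)
        centers, shape = _grid_layout(len(assignments), cell_radius, sub_rng)
        expr = _draw_expression(sub_rng, len(assignments)) if expr is None else expr
        cells = [
            CellSpec(center=c, radius=cell_radius, fp_name=fp, expression_level=float(e))
            for c, fp, e in zip(centers, assignments, expr)
        ]
        spec = SceneSpec(
            image_shape=shape,
            cells=cells,
            seed=sub_seed,
            gaussian_sd=noise_sd,
            poisson_enabled=poisson,
        )
        return simulate_scene(spec, panel, scheme)

    if design == "monoculture":
        for i, name in enumerate(names):
            scenes.append(make_scene([name] * n_cells, int(rng.integers(2**31))))
            scene_names.append(name)
    elif design == "equal_mix":
        assignments = [names[i] for i in rng.integers(0, len(names), size=n_cells)]
        scenes.append(make_scene(assignments, int(rng.integers(2**31))))
        scene_names.append("equal_mix")
    elif design == "fpmo":
        missing_fp = missing_fp or names[-1]
        if missing_fp not in panel:
            raise KeyError(f"missing FP {missing_fp!r} not in panel")
        present = [n for n in names if n != missing_fp]
        assignments = [present[i] for i in rng.integers(0, len(present), size=n_cells)]
        scenes.append(make_scene(assignments, int(rng.integers(2**31))))
        scene_names.append(f"fpmo_{missing_fp}")
    elif design == "clonal_growth":
        if days < 2:
            raise ValueError("clonal_growth needs days >= 2")
        n_clones = max(1, n_cells)
        clone_fps = [names[i] for i in rng.integers(0, len(names), size=n_clones)]
        base_expr = _draw_expression(rng, n_clones)
        for day in range(1, days + 1):
            assignments, expr, centers = [], [], []
            pitch = 2 * cell_radius + 2
            clone_pitch = (2 * days + 1) * pitch + 4
            side = int(np.ceil(np.sqrt(n_clones)))
            margin = days * pitch + cell_radius + 2
            shape = (side * clone_pitch + 2 * margin, side * clone_pitch + 2 * margin)
            for k, fp in enumerate(clone_fps):
                ci, cj = divmod(k, side)
                cr = margin + ci * clone_pitch + clone_pitch // 2
                cc = margin + cj * clone_pitch + clone_pitch // 2
                level = base_expr[k] * CLONE_DILUTION_PER_DAY ** (day - 1)
                offsets = [(0, 0)]
                for ring in range(1, day):
                    for t in range(6 * ring):
                        ang = 2 * np.pi * t / (6 * ring)
                        offsets.append(
                            (
                                int(round(ring * pitch * np.sin(ang))),
                                int(round(ring * pitch * np.cos(ang))),
                            )
                        )
                for dr, dc in offsets:
                    centers.append((cr + dr, cc + dc))
                    assignments.append(fp)
                    expr.append(level)
            cells = [
                CellSpec(center=c, radius=cell_radius, fp_name=fp, expression_level=float(e))
                for c, fp, e in zip(centers, assignments, expr)
            ]
            spec = SceneSpec(
                image_shape=shape,
                cells=cells,
                seed=int(rng.integers(2**31)),
                gaussian_sd=noise_sd,
                poisson_enabled=poisson,
            )
            scenes.append(simulate_scene(spec, panel, scheme))
            scene_names.append(f"day{day}")
    else:
        raise ValueError(
            f"unknown design {design!r}; expected monoculture, equal_mix, "
            "fpmo or clonal_growth"
        )
    return ExperimentResult(
        design=design,
        scenes=scenes,
        scene_names=scene_names,
        panel=panel,
        missing_fp=missing_fp if design == "fpmo" else None,
    )


# Fifteen synthetic FPs spanning the visible range. Excitation maxima track
# the available laser lines and emission maxima are spaced so that any panel
# of the first 12 has all pairwise model-spectrum similarities < 0.9 under
# the default scheme.
_PANEL_PARAMS: list[tuple[str, float, float]] = [
    ("sFP440", 405.0, 440.0),
    ("sFP460", 430.0, 460.0),
    ("sFP480", 455.0, 480.0),
    ("sFP505", 488.0, 505.0),
    ("sFP525", 505.0, 525.0),
    ("sFP545", 520.0, 545.0),
    ("sFP565", 540.0, 565.0),
    ("sFP585", 560.0, 585.0),
    ("sFP605", 580.0, 605.0),
    ("sFP625", 595.0, 625.0),
    ("sFP650", 610.0, 650.0),
    ("sFP675", 630.0, 675.0),
    ("sFP495", 470.0, 495.0),
    ("sFP555", 530.0, 555.0),
    ("sFP615", 590.0, 615.0),
]


def default_fp_panel(n: int) -> list[SyntheticFP]:
    """A spectrally spread panel of n synthetic FPs (1 <= n <= 15)."""
    if not 1 <= n <= len(_PANEL_PARAMS):
        raise ValueError(f"panel size must be in 1..{len(_PANEL_PARAMS)}")
    return [
        SyntheticFP(name=name, ex_max_nm=ex, em_max_nm=em)
        for name, ex, em in _PANEL_PARAMS[:n]
    ]


def confusable_pair() -> tuple[SyntheticFP, SyntheticFP]:
    """Two deliberately near-identical FPs (model similarity > 0.95).

    Useful for negative tests: their spectra differ by a 1 nm emission
    shift, so under realistic noise the decoder confuses them at high rates.
    """
    return (
        SyntheticFP(name="twinA", ex_max_nm=488.0, em_max_nm=507.0),
        SyntheticFP(name="twinB", ex_max_nm=488.0, em_max_nm=508.0),
    )
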