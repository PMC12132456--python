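"""Spectrum representation and the cosine-similarity kernel.

A single cell's hyperspectral signature is a 100-dimensional vector of mean
pixel intensities, assembled from four sequential confocal acquisition blocks
(each with its own excitation laser set and emission channel range). Because
fluorescent-protein identity is carried by spectral *shape* and not absolute
brightness, spectra are compared with cosine similarity,

    CS(a, b) = sum_ch a_ch * b_ch / (||a|| * ||b||),

which is invariant to positive rescaling of either argument and lies in
[0, 1] for non-negative spectra (1 = identical shape, 0 = orthogonal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class SpectrumError(ValueError):
    """Invalid spectrum input (wrong length, negative, malformed)."""


class ZeroNormError(SpectrumError):
    """Cosine similarity is undefined for a zero-norm spectrum.

    Raised instead of silently returning 0 or NaN: a silent zero would be
    indistinguishable from genuine spectral orthogonality.
    """


@dataclass(frozen=True)
class AcquisitionBlock:
    """One sequential spectral scan: an excitation laser set plus an
    emission channel range divided into ~8.9 nm detector bins."""

    block_index: int
    laser_lines_nm: tuple[float, ...]
    emission_start_nm: float
    emission_end_nm: float
    n_channels: int
    channel_width_nm: float = 8.9

    def __post_init__(self) -> None:
        if self.emission_start_nm >= self.emission_end_nm:
            raise ValueError(
                f"block {self.block_index}: emission_start_nm "
                f"({self.emission_start_nm}) must be < emission_end_nm "
                f"({self.emission_end_nm})"
            )
        if self.n_channels < 1:
            raise ValueError(f"block {self.block_index}: n_channels must be >= 1")
        object.__setattr__(self, "laser_lines_nm", tuple(self.laser_lines_nm))

    def channel_centers_nm(self) -> np.ndarray:
        """Center wavelength of each channel.

        Channel k (1-based) is centered at ``emission_start + (k - 0.5) * width``
        — a half-offset convention, since only the range endpoints and the
        nominal bin width are physically specified.
        """
        k = np.arange(1, self.n_channels + 1)
        return self.emission_start_nm + (k - 0.5) * self.channel_width_nm


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered acquisition blocks whose channels concatenate into one spectrum."""

    blocks: tuple[AcquisitionBlock, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("scheme needs at least one block")

    @property
    def total_channels(self) -> int:
        return sum(b.n_channels for b in self.blocks)

    def block_slices(self) -> list[slice]:
        """Slice of the concatenated vector occupied by each block."""
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + b.n_channels))
            start += b.n_channels
        return out

    def channel_centers_nm(self) -> np.ndarray:
        return np.concatenate([b.channel_centers_nm() for b in self.blocks])

    def to_json(self, path) -> None:
        payload = [
            {
                "block_index": b.block_index,
                "laser_lines_nm": list(b.laser_lines_nm),
                "emission_start_nm": b.emission_start_nm,
                "emission_end_nm": b.emission_end_nm,
                "n_channels": b.n_channels,
                "channel_width_nm": b.channel_width_nm,
            }
            for b in self.blocks
        ]
        with open(path, "w") as fh:
            json.dump({"blocks": payload}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AcquisitionScheme":
        with open(path) as fh:
            data = json.load(fh)
        blocks = []
        for i, b in enumerate(data["blocks"], start=1):
            blocks.append(
                AcquisitionBlock(
                    block_index=b.get("block_index", i),
                    laser_lines_nm=tuple(b["laser_lines_nm"]),
                    emission_start_nm=b["emission_start_nm"],
                    emission_end_nm=b["emission_end_nm"],
                    n_channels=b["n_channels"],
                    channel_width_nm=b.get("channel_width_nm", 8.9),
                )
            )
        return cls(blocks=tuple(blocks))


def default_scheme() -> AcquisitionScheme:
    """The standard 4-block, 100-channel acquisition scheme.

    Block 1: 405 nm laser, emission 420-695 nm, 31 channels.
    Block 2: 458/561 nm lasers, emission 455-695 nm, 27 channels.
    Block 3: 488 nm laser, emission 500-695 nm, 22 channels.
    Block 4: 514/594 nm lasers, emission 517-695 nm, 20 channels.
    """
    return AcquisitionScheme(
        blocks=(
            AcquisitionBlock(1, (405.0,), 420.0, 695.0, 31),
            AcquisitionBlock(2, (458.0, 561.0), 455.0, 695.0, 27),
            AcquisitionBlock(3, (488.0,), 500.0, 695.0, 22),
            AcquisitionBlock(4, (514.0, 594.0), 517.0, 695.0, 20),
        )
    )


@dataclass
class Spectrum:
    """A non-negative intensity vector on an acquisition scheme's channel grid."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SpectrumError("spectrum values must be one-dimensional")
        if np.any(self.values < 0):
            raise SpectrumError("spectrum values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def _values(s) -> np.ndarray:
    if isinstance(s, Spectrum):
        return s.values
    return np.asarray(s, dtype=float)


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two spectra, in [0, 1].

    Raises
    ------
    SpectrumError
        If the spectra differ in length.
    ZeroNormError
        If either spectrum has zero Euclidean norm.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise SpectrumError(
            f"spectrum length mismatch: {va.size} vs {vb.size}"
        )
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ZeroNormError(
            "cosine similarity is undefined for a zero-norm spectrum"
        )
    # clip guards float round-off only; non-negative inputs keep this in [0, 1]
    return float(np.clip(np.dot(va, vb) / (na * nb), 0.0, 1.0))


def pairwise_similarity_matrix(spectra: Sequence) -> np.ndarray:
    """Symmetric matrix of cosine similarities, unit diagonal, input order.

    Raises ``ZeroNormError`` naming the offending entry if any spectrum has
    zero norm.
    """
    if len(spectra) < 2:
        raise SpectrumError("need at least two spectra")
    vecs = np.stack([_values(s) for s in spectra]).astype(float)
    norms = np.linalg.norm(vecs, axis=1)
    for i, n in enumerate(norms):
        if n == 0.0:
            name = getattr(spectra[i], "label", None) or f"index {i}"
            raise ZeroNormError(f"zero-norm spectrum at {name}")
    unit = vecs / norms[:, None]
    mat = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return mat


def radiance(s) -> float:
    """Total signal: the sum of intensity across all channels."""
    return float(_values(s).sum())


def log10_radiance(s) -> float:
    """Base-10 log of radiance; errors on a zero-radiance spectrum."""
    r = radiance(s)
    if r <= 0.0:
        raise ZeroNormError("log10 radiance undefined for zero-radiance spectrum")
    return float(np.log10(r))


def concatenate_blocks(
    block_spectra: Sequence, scheme: AcquisitionScheme, label: str | None = None
) -> Spectrum:
    """Concatenate one per-block vector per acquisition block, in block order."""
    if len(block_spectra) != len(scheme.blocks):
        raise SpectrumError(
            f"expected {len(scheme.blocks)} block vectors, got {len(block_spectra)}"
        )
    parts = []
    for vec, block in zip(block_spectra, scheme.blocks):
        v = _values(vec)
        if v.size != block.n_channels:
            raise SpectrumError(
                f"block {block.block_index}: expected {block.n_channels} "
                f"channels, got {v.size}"
            )
        parts.append(v)
    return Spectrum(values=np.concatenate(parts), label=label)


def normalize(s) -> Spectrum:
    """Rescale to unit Euclidean norm (shape-only representation)."""
    v = _values(s)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ZeroNormError("cannot normalize a zero-norm spectrum")
    return Spectrum(values=v / n, label=getattr(s, "label", None))


def channel_columns(n_channels: int = 100) -> list[str]:
    """Zero-padded channel column names used across all CSV formats."""
    return [f"ch{k:03d}" for k in range(1, n_channels + 1)]
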