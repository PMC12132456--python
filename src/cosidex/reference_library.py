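"""Reference spectral library: per-FP codebook spectra and brightness QC.

A reference spectrum is the channel-wise average over all cells of a
monoculture expressing one fluorescent protein; the library of such spectra
is the codebook against which unknown cells are decoded. Because some FPs
are orders of magnitude dimmer than others under fixed imaging conditions,
the library also compares per-cell log10 radiance distributions (1-D
Wasserstein distance + average-linkage hierarchical clustering) to flag a
low-brightness group that should be excluded from multiplexing panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import wasserstein_distance

from .image_pipeline import FORMAT_HEADER, CellSpectraMatrix
from .spectral_core import (
    Spectrum,
    channel_columns,
    pairwise_similarity_matrix,
)

log = logging.getLogger(__name__)


@dataclass
class ReferenceSpectrum:
    fp_name: str
    spectrum: Spectrum
    n_cells: int = 1
    dim: bool = False


@dataclass
class ReferenceLibrary:
    """Ordered, uniquely named reference spectra sharing one channel grid."""

    references: list[ReferenceSpectrum]

    def __post_init__(self) -> None:
        names = [r.fp_name for r in self.references]
        if len(set(names)) != len(names):
            raise ValueError("reference FP names must be unique")
        lengths = {len(r.spectrum) for r in self.references}
        if len(lengths) > 1:
            raise ValueError("all reference spectra must share one channel grid")

    @property
    def fp_names(self) -> list[str]:
        return [r.fp_name for r in self.references]

    def __getitem__(self, fp_name: str) -> ReferenceSpectrum:
        for r in self.references:
            if r.fp_name == fp_name:
                return r
        raise KeyError(f"FP {fp_name!r} not in library")

    def __contains__(self, fp_name: str) -> bool:
        return fp_name in self.fp_names

    def __len__(self) -> int:
        return len(self.references)

    def subset(self, fp_names) -> "ReferenceLibrary":
        return ReferenceLibrary(references=[self[n] for n in fp_names])

    def spectra_matrix(self) -> np.ndarray:
        return np.stack([r.spectrum.values for r in self.references])

    def similarity_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise cosine-similarity matrix over the library, library order."""
        mat = pairwise_similarity_matrix([r.spectrum for r in self.references])
        return self.fp_names, mat

    def to_csv(self, path) -> None:
        n_ch = len(self.references[0].spectrum)
        df = pd.DataFrame(self.spectra_matrix(), columns=channel_columns(n_ch))
        df.insert(0, "fp_name", self.fp_names)
        df.insert(1, "n_cells", [r.n_cells for r in self.references])
        df.insert(2, "dim", [r.dim for r in self.references])
        with open(path, "w") as fh:
            fh.write(FORMAT_HEADER + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceLibrary":
        df = pd.read_csv(path, comment="#")
        chans = [c for c in df.columns if c.startswith("ch")]
        refs = [
            ReferenceSpectrum(
                fp_name=str(row["fp_name"]),
                spectrum=Spectrum(
                    values=row[chans].to_numpy(dtype=float), label=str(row["fp_name"])
                ),
                n_cells=int(row.get("n_cells", 1)),
                dim=bool(row.get("dim", False)),
            )
            for _, row in df.iterrows()
        ]
        return cls(references=refs)


def build_reference(cells: CellSpectraMatrix, fp_name: str) -> ReferenceSpectrum:
    """Average a monoculture's cell spectra channel-wise into one reference.

    Zero-radiance cells (no signal in any channel) are excluded from the
    average with a logged count; an all-zero monoculture is an error.
    """
    if cells.n_cells == 0:
        raise ValueError("cannot build a reference from an empty matrix")
    rad = cells.radiances()
    keep = rad > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%s: dropped %d zero-radiance cells", fp_name, n_dropped)
    if not keep.any():
        raise ValueError(f"{fp_name}: all cells have zero radiance")
    mean = cells.matrix[keep].mean(axis=0)
    return ReferenceSpectrum(
        fp_name=fp_name,
        spectrum=Spectrum(values=mean, label=fp_name),
        n_cells=int(keep.sum()),
    )


def radiance_distribution(cells: CellSpectraMatrix) -> np.ndarray:
    """Per-cell log10 radiance; zero-radiance cells dropped with a log entry."""
    rad = cells.radiances()
    keep = rad > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d zero-radiance cells from distribution", n_dropped)
    if not keep.any():
        raise ValueError("all cells have zero radiance")
    return np.log10(rad[keep])


def detect_dim_groups(
    distributions: dict[str, np.ndarray], n_groups: int = 2
) -> tuple[dict[str, int], set[str]]:
    """Cluster FP brightness distributions and flag the dimmest cluster.

    Pairwise 1-D empirical Wasserstein-1 distances between per-FP log10
    radiance distributions, average-linkage hierarchical clustering, cut at
    ``n_groups``; the cluster with the lowest mean log10 radiance is the dim
    set. Returns (fp_name -> group id, set of dim fp_names).
    """
    names = list(distributions)
    if len(names) < n_groups:
        raise ValueError(
            f"need at least {n_groups} FPs to form {n_groups} groups, "
            f"got {len(names)}"
        )
    for name in names:
        if len(np.atleast_1d(distributions[name])) < 2:
            raise ValueError(f"{name}: need at least 2 cells per FP")
    k = len(names)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = wasserstein_distance(distributions[names[i]], distributions[names[j]])
            dist[i, j] = dist[j, i] = d
    if n_groups == 1:
        groups = {name: 1 for name in names}
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        flat = fcluster(z, t=n_groups, criterion="maxclust")
        groups = {name: int(g) for name, g in zip(names, flat)}
    cluster_means = {
        g: float(
            np.mean(np.concatenate([np.atleast_1d(distributions[n])
                                    for n in names if groups[n] == g]))
        )
        for g in set(groups.values())
    }
    dim_cluster = min(cluster_means, key=cluster_means.get)
    dim_set = {n for n in names if groups[n] == dim_cluster}
    if len(set(groups.values())) == 1:
        dim_set = set()  # a single cluster carries no dim/bright contrast
    return groups, dim_set


def build_library(
    monocultures: dict[str, CellSpectraMatrix],
    detect_dim: bool = False,
    n_groups: int = 2,
) -> ReferenceLibrary:
    """Build a full library from per-FP monoculture matrices."""
    refs = [build_reference(cells, name) for name, cells in monocultures.items()]
    lib = ReferenceLibrary(references=refs)
    if detect_dim and len(refs) >= n_groups:
        dists = {
            name: radiance_distribution(cells)
            for name, cells in monocultures.items()
        }
        _, dim_set = detect_dim_groups(dists, n_groups=n_groups)
        for r in lib.references:
            r.dim = r.fp_name in dim_set
    return lib
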