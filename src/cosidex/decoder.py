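"""Maximum-cosine-similarity (MCS) decoding of cell identity.

Each cell spectrum is compared against every candidate reference spectrum;
the reference with the highest cosine similarity is the predicted FP. Two
accuracy statistics accompany the decoder: the monoculture error rate (the
percentage of cells whose prediction differs from the known identity) and
the FP-minus-one false-positive rate (the percentage of cells assigned to a
candidate FP that was deliberately absent from the culture). Cells with no
signal in any channel cannot be compared and are labeled "unclassified"
rather than dropped, so counts always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_pipeline import CellSpectraMatrix
from .reference_library import ReferenceLibrary

UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationResult:
    cell_ids: np.ndarray
    predicted_fp: list[str]
    mcs_value: np.ndarray
    similarity_table: np.ndarray  # n_cells x n_candidates, candidate order
    candidate_names: list[str]
    ambiguous: np.ndarray  # bool per cell: exact tie at the maximum
    truth_labels: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "predicted_fp": self.predicted_fp,
                "mcs": self.mcs_value,
                "ambiguous": self.ambiguous,
            }
        )
        if self.truth_labels is not None:
            df["truth_label"] = self.truth_labels
        return df


def classify_cells(
    cells: CellSpectraMatrix,
    library: ReferenceLibrary,
    candidates: list[str] | None = None,
    min_mcs: float | None = None,
) -> ClassificationResult:
    """Assign each cell the candidate FP with maximum cosine similarity.

    Parameters
    ----------
    candidates
        Subset of library FP names to decode against; defaults to the whole
        library. Unknown names raise ``KeyError``.
    min_mcs
        Optional rejection threshold: cells whose best similarity falls below
        it become "unclassified". Off by default — every cell with signal is
        assigned a label.

    Exact ties at the maximum go to the first candidate in library order and
    set the per-cell ``ambiguous`` flag. Zero-norm cells are "unclassified"
    with similarity NaN.
    """
    if candidates is None:
        candidates = library.fp_names
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    for name in candidates:
        if name not in library:
            raise KeyError(f"candidate FP {name!r} not in library")
    refs = library.subset(candidates).spectra_matrix()
    ref_norms = np.linalg.norm(refs, axis=1)
    if np.any(ref_norms == 0):
        bad = [candidates[i] for i in np.where(ref_norms == 0)[0]]
        raise ValueError(f"zero-norm reference spectra: {bad}")

    X = cells.matrix
    cell_norms = np.linalg.norm(X, axis=1)
    nonzero = cell_norms > 0
    sims = np.full((cells.n_cells, len(candidates)), np.nan)
    if nonzero.any():
        sims[nonzero] = np.clip(
            (X[nonzero] / cell_norms[nonzero, None]) @ (refs / ref_norms[:, None]).T,
            0.0,
            1.0,
        )

    predicted: list[str] = []
    mcs = np.full(cells.n_cells, np.nan)
    ambiguous = np.zeros(cells.n_cells, dtype=bool)
    for i in range(cells.n_cells):
        if not nonzero[i]:
            predicted.append(UNCLASSIFIED)
            continue
        row = sims[i]
        best = int(np.argmax(row))
        mcs[i] = row[best]
        if min_mcs is not None and row[best] < min_mcs:
            predicted.append(UNCLASSIFIED)
            continue
        ambiguous[i] = bool(np.sum(row == row[best]) > 1)
        predicted.append(candidates[best])
    return ClassificationResult(
        cell_ids=cells.cell_ids.copy(),
        predicted_fp=predicted,
        mcs_value=mcs,
        similarity_table=sims,
        candidate_names=list(candidates),
        ambiguous=ambiguous,
        truth_labels=list(cells.truth_labels) if cells.truth_labels else None,
    )


def error_rate(result: ClassificationResult, truth: str) -> float:
    """Monoculture misclassification percentage against a known identity.

    ``100 * #(predicted != truth) / n_cells``; unclassified cells count as
    misclassified (the conservative choice).
    """
    if result.n_cells == 0:
        raise ValueError("empty classification result")
    if truth not in result.candidate_names:
        raise ValueError(f"truth FP {truth!r} was not among the candidates")
    wrong = sum(p != truth for p in result.predicted_fp)
    return 100.0 * wrong / result.n_cells


def false_positive_rate(result: ClassificationResult, missing_fp: str) -> float:
    """FP-minus-one statistic: % of cells called as a deliberately absent FP."""
    if result.n_cells == 0:
        raise ValueError("empty classification result")
    if missing_fp not in result.candidate_names:
        raise ValueError(
            f"missing FP {missing_fp!r} was not among the candidates"
        )
    hits = sum(p == missing_fp for p in result.predicted_fp)
    return 100.0 * hits / result.n_cells


def stratify_by_intensity(
    cells: CellSpectraMatrix, n_strata: int = 3
) -> list[str]:
    """Rank cells by radiance and split into equal-count intensity strata.

    Returns one stratum label per cell (matrix row order). With the default
    three strata the labels are low / medium / high; remainder cells go to
    the lower strata so sizes differ by at most one. Rank order (not value
    thresholds) is used so duplicated radiances still split.
    """
    if cells.n_cells < n_strata:
        raise ValueError(
            f"need at least {n_strata} cells for {n_strata} strata, "
            f"got {cells.n_cells}"
        )
    if n_strata == 3:
        names = ["low", "medium", "high"]
    else:
        names = [f"stratum_{k + 1}" for k in range(n_strata)]
    order = np.argsort(cells.radiances(), kind="stable")
    out = [""] * cells.n_cells
    for stratum, chunk in zip(names, np.array_split(order, n_strata)):
        for idx in chunk:
            out[int(idx)] = stratum
    return out


def summarize(
    result: ClassificationResult,
    truth: str | None = None,
    missing_fp: str | None = None,
) -> dict:
    """Per-FP counts plus the accuracy statistics, JSON-serializable."""
    counts: dict[str, int] = {}
    for p in result.predicted_fp:
        counts[p] = counts.get(p, 0) + 1
    summary: dict = {"n_cells": result.n_cells, "counts": counts}
    if truth is not None:
        summary["error_rate"] = error_rate(result, truth)
    if missing_fp is not None:
        summary["false_positive_rate"] = false_positive_rate(result, missing_fp)
    return summary
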