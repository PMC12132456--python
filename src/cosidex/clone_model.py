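"""Spatial-clone misclassification model.

Cells in a clone share one FP label, so when a clone of N adjacent cells is
decoded the chance that *all* of them are misclassified — the failure mode
that would mislabel the clone — is P^N under independent per-cell errors
with rate P. Clones are modeled on a 3x3 grid with the center square always
occupied and the remaining N-1 cells placed uniformly among the 8 outer
squares, giving C(8, N-1) distinct placements. A Monte-Carlo simulator
cross-checks the analytic probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

GRID_SQUARES = 9
OUTER_SQUARES = 8


@dataclass(frozen=True)
class CloneErrorModel:
    """Independent per-cell misclassification with probability ``per_cell_error_p``."""

    per_cell_error_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_cell_error_p <= 1.0:
            raise ValueError("per_cell_error_p must be in [0, 1]")


def _check_n(n: int) -> None:
    if not 1 <= n <= GRID_SQUARES:
        raise ValueError(f"clone size must be in 1..{GRID_SQUARES}, got {n}")


def clone_misclassification_probability(model: CloneErrorModel, n: int) -> float:
    """P^n: probability that every cell of an n-cell clone is misclassified."""
    _check_n(n)
    return model.per_cell_error_p ** n


def placement_count(n: int) -> int:
    """Number of distinct placements of an n-cell clone on the 3x3 grid.

    The center square is always occupied, so this is C(8, n-1): the ways to
    choose outer squares for the remaining n-1 cells.
    """
    _check_n(n)
    return comb(OUTER_SQUARES, n - 1)


def simulate_clone_errors(
    model: CloneErrorModel, n: int, reps: int, seed: int
) -> float:
    """Monte-Carlo fraction of replicates in which the whole clone is wrong.

    Each replicate places the clone (center fixed, n-1 outer squares chosen
    uniformly over the C(8, n-1) placements) and draws an independent
    misclassification event per cell. Deterministic for a fixed seed.
    """
    _check_n(n)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if n > 1:
        # uniform random placement of the n-1 outer cells; errors are
        # position-independent, so the placement only fixes the geometry
        scores = rng.random((reps, OUTER_SQUARES))
        np.argpartition(scores, n - 2, axis=1)[:, : n - 1]
    errors = rng.random((reps, n)) < model.per_cell_error_p
    return float(errors.all(axis=1).mean())


def clone_error_table(
    model: CloneErrorModel,
    sizes=range(1, GRID_SQUARES + 1),
    reps: int | None = None,
    seed: int = 0,
) -> list[dict]:
    """Analytic (and optionally empirical) clone error rates per clone size."""
    rows = []
    for n in sizes:
        row = {
            "n": int(n),
            "placements": placement_count(n),
            "analytic": clone_misclassification_probability(model, n),
        }
        if reps is not None:
            row["empirical"] = simulate_clone_errors(model, n, reps, seed + n)
        rows.append(row)
    return rows
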