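"""Enumerate and rank spectrally resolvable N-tuple FP palettes.

A palette of N fluorescent proteins is usable for multiplexed imaging only
if every pair is spectrally resolvable — operationally, every pairwise
cosine similarity is below a threshold (default 0.9). Among all feasible
N-subsets of a library, the best palette minimizes the sum of pairwise
similarities. The search is a depth-first branch over the compatibility
graph (extending a partial tuple only with FPs compatible with every member
so far), which equals brute force over all C(n, N) subsets but prunes
infeasible branches early.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PaletteQuery:
    """Constraints for a palette search."""

    n: int
    threshold: float = 0.9
    strict: bool = True  # feasible iff similarity < threshold (else <=)
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    max_results: int = 10_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", tuple(self.include))
        object.__setattr__(self, "exclude", tuple(self.exclude))
        if not 2 <= self.n <= 15:
            raise ValueError("tuple size n must be in 2..15")
        if set(self.include) & set(self.exclude):
            raise ValueError("include and exclude sets overlap")
        if self.n < len(self.include):
            raise ValueError("n is smaller than the number of required FPs")


@dataclass
class PaletteSolution:
    fp_names: tuple[str, ...]
    objective: float  # sum of the N(N-1)/2 pairwise similarities
    submatrix: np.ndarray
    feasible: bool = True

    def to_dict(self) -> dict:
        return {
            "fp_names": list(self.fp_names),
            "objective": self.objective,
            "submatrix": self.submatrix.tolist(),
            "feasible": self.feasible,
        }


def _check_matrix(names: list[str], matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(names), len(names)):
        raise ValueError("similarity matrix shape must match the name list")
    if len(set(names)) != len(names):
        raise ValueError("FP names must be unique")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 1.0):
        raise ValueError("similarity matrix must have a unit diagonal")
    return matrix


def _pair_ok(value: float, threshold: float, strict: bool) -> bool:
    return value < threshold if strict else value <= threshold


def enumerate_feasible_tuples(
    names: list[str], matrix: np.ndarray, query: PaletteQuery
) -> tuple[list[PaletteSolution], bool]:
    """All feasible N-tuples, sorted by ascending objective.

    Ties in the objective break lexicographically on the member names.
    Returns ``(solutions, truncated)``; truncated is True when more than
    ``query.max_results`` feasible tuples exist and the list was cut.
    An over-constrained query (n larger than the eligible FP count) returns
    an empty list, not an error.
    """
    matrix = _check_matrix(names, matrix)
    idx_of = {name: i for i, name in enumerate(names)}
    for name in query.include:
        if name not in idx_of:
            raise KeyError(f"required FP {name!r} not in similarity matrix")
    eligible = [n for n in names if n not in set(query.exclude)]
    required = [idx_of[n] for n in query.include]
    pool = [idx_of[n] for n in eligible if n not in set(query.include)]

    # required members must be mutually compatible
    for a, b in itertools.combinations(required, 2):
        if not _pair_ok(matrix[a, b], query.threshold, query.strict):
            return [], False

    solutions: list[PaletteSolution] = []

    def extend(chosen: list[int], candidates: list[int]) -> None:
        if len(chosen) == query.n:
            members = tuple(sorted(names[i] for i in chosen))
            order = [idx_of[m] for m in members]
            sub = matrix[np.ix_(order, order)]
            obj = float(sub[np.triu_indices(len(order), k=1)].sum())
            solutions.append(
                PaletteSolution(fp_names=members, objective=obj, submatrix=sub)
            )
            return
        need = query.n - len(chosen)
        for pos, cand in enumerate(candidates):
            if len(candidates) - pos < need:
                break
            if all(
                _pair_ok(matrix[cand, c], query.threshold, query.strict)
                for c in chosen
            ):
                extend(chosen + [cand], candidates[pos + 1 :])

    extend(required, pool)
    solutions.sort(key=lambda s: (s.objective, s.fp_names))
    truncated = len(solutions) > query.max_results
    return solutions[: query.max_results], truncated


def optimal_ntuple(
    names: list[str], matrix: np.ndarray, query: PaletteQuery
) -> PaletteSolution | None:
    """The feasible N-tuple with minimum summed pairwise similarity, or None."""
    solutions, _ = enumerate_feasible_tuples(names, matrix, query)
    return solutions[0] if solutions else None


def dedupe_prefilter(
    names: list[str], matrix: np.ndarray, threshold: float = 0.9, strict: bool = True
) -> tuple[list[str], np.ndarray]:
    """Collapse groups of near-identical FPs to one representative each.

    FPs whose similarity reaches the threshold are linked; each connected
    component of that graph keeps only its earliest-listed member. Optional:
    combined with pairwise feasibility checking it is redundant, and it can
    silently drop FPs a user wanted, so it is off by default in the CLI.
    """
    matrix = _check_matrix(names, matrix)
    k = len(names)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(k):
        for j in range(i + 1, k):
            conflict = not _pair_ok(matrix[i, j], threshold, strict)
            if conflict:
                parent[find(j)] = find(i)
    keep = []
    seen: set[int] = set()
    for i in range(k):
        root = find(i)
        if root not in seen:
            seen.add(root)
            keep.append(i)
    kept_names = [names[i] for i in keep]
    return kept_names, matrix[np.ix_(keep, keep)]


def export_palette_report(
    solution: PaletteSolution, library, out_dir, basename: str = "palette"
) -> dict[str, str]:
    """Write a similarity heatmap PNG, a reference-spectra PNG, and a JSON
    record of the solution. Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not solution.fp_names:
        raise ValueError("cannot export an empty palette solution")
    for name in solution.fp_names:
        if name not in library:
            raise KeyError(f"FP {name!r} not in library")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = len(solution.fp_names)

    heat_path = out_dir / f"{basename}_heatmap.png"
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * k), max(3.5, 0.55 * k)))
    im = ax.imshow(solution.submatrix, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(k), solution.fp_names, rotation=90, fontsize=7)
    ax.set_yticks(range(k), solution.fp_names, fontsize=7)
    for i in range(k):
        for j in range(k):
            ax.text(j, i, f"{solution.submatrix[i, j]:.2f}",
                    ha="center", va="center", fontsize=6, color="w")
    fig.colorbar(im, ax=ax, label="cosine similarity")
    fig.tight_layout()
    fig.savefig(heat_path, dpi=150)
    plt.close(fig)

    spectra_path = out_dir / f"{basename}_spectra.png"
    fig, ax = plt.subplots(figsize=(8, 3.5))
    for name in solution.fp_names:
        v = library[name].spectrum.values
        peak = v.max()
        ax.plot(np.arange(1, v.size + 1), v / peak if peak > 0 else v, label=name)
    ax.set_xlabel("channel")
    ax.set_ylabel("normalized intensity")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(spectra_path, dpi=150)
    plt.close(fig)

    json_path = out_dir / f"{basename}.json"
    with open(json_path, "w") as fh:
        json.dump(solution.to_dict(), fh, indent=2)
    return {
        "heatmap": str(heat_path),
        "spectra": str(spectra_path),
        "json": str(json_path),
    }
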