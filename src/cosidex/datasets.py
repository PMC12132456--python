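"""Small built-in fixtures.

The green-panel similarity fixture reconstructs the pairwise
cosine-similarity structure of a seven-FP green panel whose spectra fall
into three qualitative patterns: four pattern-1 FPs that are nearly
indistinguishable from each other, two pattern-2 FPs that are effectively
identical, and one violet-excited pattern-3 FP (mT-Sapphire-like) that is
well separated from everything. Within-category entries use the midpoint of
the observed similarity range for that pair category.
"""

from __future__ import annotations

import numpy as np

GREEN_PANEL_NAMES = [
    "mAvicFP1",   # pattern 1
    "mUkG",       # pattern 1
    "mNeonGreen", # pattern 1
    "Clover",     # pattern 1
    "EGFP",       # pattern 2
    "Emerald",    # pattern 2
    "mT-Sapphire",  # pattern 3
]

_PATTERN = {name: 1 for name in GREEN_PANEL_NAMES[:4]}
_PATTERN.update({"EGFP": 2, "Emerald": 2, "mT-Sapphire": 3})

# midpoints of the pairwise similarity ranges per pair category
_WITHIN_P1 = 0.97    # pattern 1 internal: 0.95-0.99
_WITHIN_P2 = 1.00    # pattern 2 internal: identical spectra
_CROSS_P1_P2 = 0.84  # cross pattern 1/2: 0.81-0.87
_SAPPHIRE = 0.365    # mT-Sapphire vs all others: 0.15-0.58


def green_panel_similarity() -> tuple[list[str], np.ndarray]:
    """(names, 7x7 symmetric similarity matrix) for the green panel."""
    k = len(GREEN_PANEL_NAMES)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = GREEN_PANEL_NAMES[i], GREEN_PANEL_NAMES[j]
            pa, pb = _PATTERN[a], _PATTERN[b]
            if 3 in (pa, pb):
                val = _SAPPHIRE
            elif pa == pb:
                val = _WITHIN_P1 if pa == 1 else _WITHIN_P2
            else:
                val = _CROSS_P1_P2
            mat[i, j] = mat[j, i] = val
    return list(GREEN_PANEL_NAMES), mat
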