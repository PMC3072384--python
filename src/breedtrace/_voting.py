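"""Shared nearest-neighbour voting primitives.

Distance ties are broken by sample id so that every vote is deterministic.
"""

from __future__ import annotations

import numpy as np


def neighbor_order(dists: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorting by distance, ties by id (lexicographic)."""
    return np.lexsort((np.asarray(ids, dtype=str), np.asarray(dists)))


def majority_label(labels) -> str | None:
    """Label held by a strict majority of the votes, or None.

    With m votes the threshold is m//2 + 1 (3 of 5 for the standard
    five-neighbour vote); at most one label can reach it.
    """
    labels = list(labels)
    needed = len(labels) // 2 + 1
    uniq, counts = np.unique(np.asarray(labels, dtype=str), return_counts=True)
    top = counts.argmax()
    if counts[top] >= needed:
        return str(uniq[top])
    return None
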