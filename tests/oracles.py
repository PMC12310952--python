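"""Independent brute-force oracles used by the test suite.

These deliberately recompute everything from first principles (exhaustive
scans, full enumeration) and share no code path with the package internals
they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd


def brute_force_average_linkage(D: np.ndarray, cut_height: float) -> list[frozenset]:
    """Exhaustive-recomputation average-linkage partition.

    At every step the distance between each cluster pair is recomputed from
    scratch as the mean of the original pairwise distances (rounded to 9
    decimals, like the implementation); the minimal pair merges, first pair in
    smallest-member lexicographic order winning ties; merging stops once the
    minimum exceeds ``cut_height`` or equals 1 (no shared barcode at all).
    """
    n = len(D)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        clusters.sort(key=min)
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = round(
                    float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])), 9
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if d > cut_height or d >= 1.0:
            break
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return [frozenset(c) for c in clusters]


def partition_from_clone_table(clones: pd.DataFrame, cell_order) -> list[frozenset]:
    pos = {c: i for i, c in enumerate(cell_order)}
    groups: dict[int, set] = {}
    for row in clones.itertuples(index=False):
        groups.setdefault(row.clone_id, set()).add(pos[row.cell_id])
    return [frozenset(g) for g in groups.values()]


def exhaustive_shared_counts(clones: pd.DataFrame, states, min_cells: int = 2,
                             state_col: str = "cell_type") -> np.ndarray:
    """Per-clone scan of the shared-clone count matrix."""
    S = len(states)
    out = np.zeros((S, S), dtype=int)
    for _, grp in clones.groupby("clone_id"):
        counts = grp[state_col].value_counts()
        for a in range(S):
            for b in range(S):
                if counts.get(states[a], 0) >= min_cells and counts.get(states[b], 0) >= min_cells:
                    out[a, b] += 1
    return out


def enumerate_permutation_moments(clone_idx: np.ndarray, labels: np.ndarray,
                                  n_states: int, min_cells: int = 2):
    """Exact permutation mean/sd of the shared-count matrix plus the exact
    fourth central moment (for Monte-Carlo error bounds), by enumerating all
    orderings of the label vector."""
    n = len(labels)
    K = clone_idx.max() + 1
    vals = []
    for perm in permutations(range(n)):
        lab = labels[list(perm)]
        counts = np.zeros((K, n_states), dtype=int)
        for c, s in zip(clone_idx, lab):
            counts[c, s] += 1
        present = counts >= min_cells
        vals.append(present.T.astype(int) @ present)
    vals = np.array(vals, dtype=float)
    mu = vals.mean(axis=0)
    var = vals.var(axis=0)
    m4 = ((vals - mu) ** 4).mean(axis=0)
    return mu, np.sqrt(var), m4


def exhaustive_upset(clones: pd.DataFrame, states, presence_min: int = 1,
                     state_col: str = "cell_type") -> dict[tuple, int]:
    """Per-clone scan of intersection counts keyed by the presence tuple."""
    out: dict[tuple, int] = {}
    for _, grp in clones.groupby("clone_id"):
        counts = grp[state_col].value_counts()
        key = tuple(counts.get(s, 0) >= presence_min for s in states)
        if any(key):
            out[key] = out.get(key, 0) + 1
    return out
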