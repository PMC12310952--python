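"""Clone calling: Jaccard similarity + average-linkage clustering of the
cell x barcode matrix.

Cells sharing (most of) an integration-barcode set are grouped into clones by
agglomerative average linkage on Jaccard distance, cutting the dendrogram at
``cut_height`` (default 0.5: cells merging only when they share the majority
of their integrations).

The agglomeration is implemented here rather than delegated to
:func:`scipy.cluster.hierarchy.linkage` because Jaccard distances on small
barcode sets are small-denominator rationals, ties are therefore pervasive,
and the partition must be deterministic with ties broken by lexicographic
cell ID.  Cluster-pair distances are maintained as exact sums of the original
pairwise distances (so they equal the from-scratch average) and rounded to 9
decimals before comparison, which makes mathematically equal averages compare
equal regardless of summation order.  Two groups with no shared barcode at
all (distance exactly 1) are never merged; with that rule ``cut_height=1``
yields the connected components of the similarity graph and ``cut_height``
near 0 the partition by exact barcode-set equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcode_io import CellBarcodeMatrix


def jaccard_similarity(a: set, b: set) -> float:
    """|a n b| / |a u b| for two non-empty barcode sets."""
    if not a or not b:
        raise ValueError("barcode sets must be non-empty (drop barcode-less cells upstream)")
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


_ROUND = 9  # decimals; stabilizes ties among exact-rational averages


def jaccard_distance_matrix(matrix: CellBarcodeMatrix) -> np.ndarray:
    """Dense pairwise Jaccard distance between the matrix's cells."""
    B = matrix.matrix.astype(np.int64)
    inter = np.asarray((B @ B.T).todense(), dtype=np.float64)
    sizes = np.asarray(B.sum(axis=1), dtype=np.float64).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        D = 1.0 - inter / union
    return np.round(D, _ROUND)


def average_linkage_merges(
    D: np.ndarray, cut_height: float | None = None
) -> list[tuple[int, int, float]]:
    """Deterministic average-linkage merge sequence on a distance matrix.

    Returns ``(i, j, height)`` merges where ``i < j`` are cluster slots (a
    merged cluster occupies the smaller slot, i.e. the slot of its smallest
    member).  Ties are broken by the row-major order of the slot pair, which
    for a matrix whose rows are sorted by cell ID is the lexicographic rule.
    If ``cut_height`` is given the sequence stops once the minimum distance
    exceeds it (average linkage is monotone, so this is exactly the cut
    prefix); merges at distance 1 (no shared barcode) never happen.
    """
    n = D.shape[0]
    if n <= 1:
        return []
    S = D.astype(np.float64).copy()  # sums of original pairwise distances
    sizes = np.ones(n, dtype=np.int64)
    cur = np.round(S.copy(), _ROUND)
    np.fill_diagonal(cur, np.inf)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        flat = int(np.argmin(cur))
        i, j = divmod(flat, n)
        h = float(cur[i, j])
        if not np.isfinite(h):
            break
        if h >= 1.0 or (cut_height is not None and h > cut_height):
            break
        merges.append((i, j, h))
        S[i, :] += S[j, :]
        S[:, i] = S[i, :]
        sizes[i] += sizes[j]
        active[j] = False
        cur[j, :] = np.inf
        cur[:, j] = np.inf
        upd = np.round(S[i, active] / (sizes[i] * sizes[active]), _ROUND)
        cur[i, active] = upd
        cur[active, i] = upd
        cur[i, i] = np.inf
    return merges


def _labels_from_merges(n: int, merges: list[tuple[int, int, float]], cut_height: float) -> np.ndarray:
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, h in merges:
        if h <= cut_height and h < 1.0:
            ri, rj = find(i), find(j)
            lo, hi = min(ri, rj), max(ri, rj)
            parent[hi] = lo
    roots = np.array([find(x) for x in range(n)])
    # contiguous CloneIDs from 1, ordered by smallest member (= root index)
    ids = {r: k + 1 for k, r in enumerate(sorted(set(roots.tolist())))}
    return np.array([ids[r] for r in roots], dtype=np.int64)


def call_clones(matrix: CellBarcodeMatrix, cut_height: float = 0.5) -> pd.DataFrame:
    """Partition cells into clones.

    Returns a clone table with columns ``cell_id`` and ``clone_id`` (dense
    integers from 1, clones ordered by their lexicographically smallest cell).
    Deterministic given the matrix and ``cut_height``.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError(f"cut_height must be in (0, 1], got {cut_height}")
    n = matrix.shape[0]
    if n == 0:
        return pd.DataFrame({"cell_id": pd.Series(dtype=object), "clone_id": pd.Series(dtype=np.int64)})
    D = jaccard_distance_matrix(matrix)
    merges = average_linkage_merges(D, cut_height=cut_height)
    labels = _labels_from_merges(n, merges, cut_height)
    return pd.DataFrame({"cell_id": matrix.cell_ids, "clone_id": labels})


def call_clones_per_dataset(
    matrix: CellBarcodeMatrix,
    annotations: pd.DataFrame,
    cut_height: float = 0.5,
    cross_dataset: bool = False,
) -> pd.DataFrame:
    """Call clones independently within each dataset (10x reaction).

    Barcodes are delivered per embryo, so by default cells from different
    datasets are never co-clustered; ``cross_dataset=True`` pools everything
    but warns, since identical barcodes in different animals are library
    collisions, not clonal relations.
    """
    ann = annotations.set_index("cell_id")
    if cross_dataset or "dataset" not in annotations.columns:
        if cross_dataset:
            warnings.warn(
                "cross-dataset clone calling: shared barcodes between animals "
                "are library collisions and may fuse unrelated clones"
            )
        return call_clones(matrix, cut_height)
    datasets = ann.reindex(matrix.cell_ids)["dataset"].to_numpy()
    out = []
    offset = 0
    for ds in pd.unique(datasets):
        idx = np.flatnonzero(datasets == ds)
        sub = matrix.matrix[idx]
        keep_cols = np.flatnonzero(np.asarray(sub.sum(axis=0)).ravel() > 0)
        sub_m = CellBarcodeMatrix(
            cell_ids=matrix.cell_ids[idx],
            barcode_ids=matrix.barcode_ids[keep_cols],
            matrix=sub[:, keep_cols],
        )
        tab = call_clones(sub_m, cut_height)
        tab["clone_id"] += offset
        offset = int(tab["clone_id"].max())
        out.append(tab)
    res = pd.concat(out, ignore_index=True)
    return res.sort_values("cell_id", kind="mergesort").reset_index(drop=True)


def attach_annotations(clones: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join per-cell annotations (cell type, subtype, timepoint, dataset)."""
    cols = [c for c in ("cell_id", "cell_type", "subtype", "timepoint", "dataset")
            if c in annotations.columns]
    return clones.merge(annotations[cols], on="cell_id", how="left")


@dataclass
class CloneSizeStats:
    n_clones: int
    mean_size: float
    size_histogram: pd.Series  # index: integer clone size; value: count


def clone_size_stats(clones: pd.DataFrame) -> CloneSizeStats:
    """Number of clones, mean clone size and the integer size histogram."""
    if not len(clones):
        raise ValueError("empty clone table")
    sizes = clones.groupby("clone_id").size()
    hist = sizes.value_counts().sort_index()
    hist.index.name = "size"
    return CloneSizeStats(
        n_clones=int(sizes.shape[0]),
        mean_size=float(sizes.mean()),
        size_histogram=hist,
    )


def dendrogram_newick(matrix: CellBarcodeMatrix) -> str:
    """Full average-linkage dendrogram in Newick, for inspection.

    Branch lengths are differences of merge heights; components that never
    merge (distance 1 everywhere between them) are attached to an artificial
    root at height 1.
    """
    n = matrix.shape[0]
    if n == 0:
        return ";"
    D = jaccard_distance_matrix(matrix)
    merges = average_linkage_merges(D, cut_height=None)
    nodes = {i: (str(matrix.cell_ids[i]), 0.0) for i in range(n)}
    for i, j, h in merges:
        si, hi = nodes[i]
        sj, hj = nodes.pop(j)
        nodes[i] = (f"({si}:{max(h - hi, 0.0):.6g},{sj}:{max(h - hj, 0.0):.6g})", h)
    if len(nodes) == 1:
        return next(iter(nodes.values()))[0] + ";"
    parts = [f"{s}:{max(1.0 - h, 0.0):.6g}" for s, h in (nodes[k] for k in sorted(nodes))]
    return "(" + ",".join(parts) + ");"
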