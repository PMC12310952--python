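"""Expression-side statistics: depth normalization, the scrambled-normalized
PCA-distance stability statistic, and binned-control gene-set module scores.

Expression lives in an :class:`anndata.AnnData` (cells x genes).  Raw counts
are normalized per cell as ``x -> ln(1 + scale_factor * x / total)`` with
``scale_factor = 10,000`` — the standard depth normalization — after which
``sum(exp(x') - 1) == scale_factor`` holds for every cell (a conservation
check used in the tests).

The PCA-distance statistic measures how far a cell subtype drifts in
transcriptional space between a reference timepoint and later ones: principal
components are computed once on the whole (standardized) dataset, D is the
mean pairwise Euclidean distance in the first ``n_components`` (default 30)
scores between reference-time and later-time cells of the subtype, and D is
normalized by a scrambled distance D_s — the mean cross-half distance over
random splits of the whole dataset — giving R = D / D_s.  R ~ 1 means the
subtype moved no more than arbitrary halves of the data differ; R > 1 marks
genuine temporal divergence.
"""

from __future__ import annotations

from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA


def read_expression_mtx(
    mtx_path: str, genes_path: str, cells_path: str,
    annotations: Optional[pd.DataFrame] = None,
) -> ad.AnnData:
    """Load a genes x cells MTX (+ name files) as a cells x genes AnnData."""
    from pathlib import Path

    from scipy.io import mmread

    m = sparse.csr_matrix(mmread(str(mtx_path)).T)
    genes = Path(genes_path).read_text().splitlines()
    cells = Path(cells_path).read_text().splitlines()
    adata = ad.AnnData(X=m)
    adata.var_names = genes
    adata.obs_names = cells
    if annotations is not None:
        ann = annotations.set_index("cell_id").reindex(cells)
        for c in ann.columns:
            adata.obs[c] = ann[c].to_numpy()
    return adata


def read_expression_csv(
    path: str, annotations: Optional[pd.DataFrame] = None
) -> ad.AnnData:
    """Load a dense genes x cells CSV (gene IDs in the first column)."""
    df = pd.read_csv(path, index_col=0)
    adata = ad.AnnData(X=sparse.csr_matrix(df.to_numpy().T))
    adata.var_names = df.index.astype(str)
    adata.obs_names = df.columns.astype(str)
    if annotations is not None:
        ann = annotations.set_index("cell_id").reindex(adata.obs_names)
        for c in ann.columns:
            adata.obs[c] = ann[c].to_numpy()
    return adata


def lognormalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Depth-normalize and log-transform raw counts.

    Each entry becomes ``ln(1 + scale_factor * x / cell_total)``.  The raw
    counts are kept in ``layers["counts"]`` and the result is tagged
    ``uns["layer"] = "lognorm"``.  A cell with zero total counts is an error
    naming the cell.
    """
    X = sparse.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"all-zero cell(s): {list(adata.obs_names[zero[:5]])}")
    Y = X.multiply(scale_factor / totals[:, None]).tocsr()
    Y.data = np.log1p(Y.data)
    out = ad.AnnData(X=Y, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.layers["counts"] = X
    out.uns["layer"] = "lognorm"
    return out


# ---------------------------------------------------------------------------
# PCA-distance stability statistic


class PCADistanceResults:
    """Per (subtype, timepoint) distances: D, the scrambled D_s and R = D/D_s."""

    def __init__(self, table: pd.DataFrame, d_scrambled: float, n_components: int,
                 n_scrambles: int, seed: int) -> None:
        self.table = table
        self.d_scrambled = d_scrambled
        self.n_components = n_components
        self.n_scrambles = n_scrambles
        self.seed = seed

    def summary(self) -> str:
        lines = [
            "PCA-distance stability",
            f"  components: {self.n_components}   scrambles: {self.n_scrambles}"
            f"   seed: {self.seed}   D_s: {self.d_scrambled:.4f}",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot(self, path: Optional[str] = None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for st, grp in self.table.groupby("subtype"):
            ax.plot(grp["timepoint"], grp["R"], marker="o", label=str(st))
        ax.axhline(1.0, color="0.6", ls="--", lw=1)
        ax.set_ylabel("normalized PCA distance R")
        ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig


class PCADistance:
    """Within-subtype cross-timepoint PCA distance, scramble-normalized.

    Parameters
    ----------
    adata
        Log-normalized expression (cells x genes).
    subtype_col, time_col
        ``obs`` columns holding the subtype and timepoint labels.
    """

    def __init__(self, adata: ad.AnnData, subtype_col: str = "subtype",
                 time_col: str = "timepoint") -> None:
        for c in (subtype_col, time_col):
            if c not in adata.obs.columns:
                raise ValueError(f"missing obs column {c!r}")
        self.adata = adata
        self.subtype_col = subtype_col
        self.time_col = time_col

    def _scores(self, n_components: int, seed: int) -> np.ndarray:
        X = self.adata.X
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
        if n_components > min(X.shape):
            raise ValueError(
                f"n_components={n_components} exceeds data dimensions {X.shape}"
            )
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant genes carry no signal
        Xs = (X - mu) / sd
        pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
        return pca.fit_transform(Xs)

    def fit(
        self,
        ref_time: str,
        times: Optional[Sequence[str]] = None,
        subtypes: Optional[Sequence[str]] = None,
        n_components: int = 30,
        n_scrambles: int = 20,
        seed: int = 0,
        mode: str = "pairwise",
    ) -> PCADistanceResults:
        """Compute D, D_s and R per (subtype, timepoint).

        ``mode="pairwise"`` (default) takes the mean distance over all
        (reference cell, later cell) pairs; ``mode="centroid"`` the distance
        between group centroids.  ``n_scrambles`` random half-splits of the
        whole dataset are averaged for D_s (1 reproduces a single split).
        """
        if mode not in ("pairwise", "centroid"):
            raise ValueError("mode must be 'pairwise' or 'centroid'")
        if n_scrambles < 1:
            raise ValueError("n_scrambles must be >= 1")
        obs = self.adata.obs
        tvals = obs[self.time_col].astype(str).to_numpy()
        svals = obs[self.subtype_col].astype(str).to_numpy()
        if times is None:
            times = sorted(t for t in np.unique(tvals) if t != str(ref_time))
        if subtypes is None:
            subtypes = sorted(np.unique(svals))
        scores = self._scores(n_components, seed)

        def group_dist(A: np.ndarray, B: np.ndarray) -> float:
            if mode == "centroid":
                return float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
            return float(cdist(A, B).mean())

        rng = np.random.default_rng(seed)
        n = scores.shape[0]
        half = n // 2
        if half < 2:
            raise ValueError("too few cells to scramble-split")
        ds_vals = []
        for _ in range(n_scrambles):
            perm = rng.permutation(n)
            ds_vals.append(group_dist(scores[perm[:half]], scores[perm[half:]]))
        d_s = float(np.mean(ds_vals))
        if d_s == 0:
            raise ValueError("scrambled distance is zero (all cells identical)")

        rows = []
        for st in subtypes:
            ref_idx = np.flatnonzero((svals == st) & (tvals == str(ref_time)))
            if len(ref_idx) < 2:
                raise ValueError(f"fewer than 2 {st!r} cells at reference time {ref_time!r}")
            for t in times:
                idx = np.flatnonzero((svals == st) & (tvals == str(t)))
                if len(idx) < 2:
                    raise ValueError(f"fewer than 2 {st!r} cells at time {t!r}")
                d = group_dist(scores[ref_idx], scores[idx])
                rows.append((st, t, d, d_s, d / d_s))
        table = pd.DataFrame(rows, columns=["subtype", "timepoint", "D", "D_s", "R"])
        return PCADistanceResults(table, d_s, n_components, n_scrambles, seed)


def pca_distance(
    adata: ad.AnnData,
    subtype: str,
    ref_time: str,
    times: Sequence[str],
    subtype_col: str = "subtype",
    time_col: str = "timepoint",
    n_components: int = 30,
    n_scrambles: int = 20,
    seed: int = 0,
    mode: str = "pairwise",
) -> PCADistanceResults:
    """One-subtype convenience wrapper around :class:`PCADistance`."""
    model = PCADistance(adata, subtype_col=subtype_col, time_col=time_col)
    return model.fit(
        ref_time=ref_time, times=times, subtypes=[subtype],
        n_components=n_components, n_scrambles=n_scrambles, seed=seed, mode=mode,
    )


# ---------------------------------------------------------------------------
# gene-set module score


def module_score(
    adata: ad.AnnData,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control gene-set score per cell.

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-size bins; for every gene of the set, ``n_ctrl`` control
    genes are sampled (with replacement, excluding the gene itself) from its
    bin.  The score is the mean expression of the set minus the mean of the
    pooled controls — so a set behaving like its expression-matched controls
    scores ~0.  Deterministic given ``seed``.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    genes = pd.Index(adata.var_names)
    matched = [g for g in gene_set if g in genes]
    if not matched:
        raise ValueError("gene set has no gene matched in the expression matrix")
    X = adata.X
    X = sparse.csr_matrix(X) if sparse.issparse(X) else np.asarray(X, dtype=float)
    mean_expr = np.asarray(X.mean(axis=0)).ravel()
    # equal-occupancy bins on the expression rank (ties broken by gene order)
    order = pd.Series(mean_expr, index=genes).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(genes)), labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    gi = {g: i for i, g in enumerate(genes)}
    for g in matched:
        b = bins[g]
        pool = np.flatnonzero((bins == b).to_numpy())
        pool = pool[pool != gi[g]]
        if not len(pool):
            pool = np.array([gi[g]])
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True).tolist())
    set_cols = np.array([gi[g] for g in matched])
    set_mean = np.asarray(X[:, set_cols].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, np.array(ctrl_idx)].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=adata.obs_names, name="module_score")
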