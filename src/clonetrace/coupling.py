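"""Permutation-null lineage coupling between cell states.

A clone is "shared" between two states when it contains at least ``min_cells``
(default 2) cells of each.  The observed shared-clone count for every state
pair is compared to its null distribution obtained by shuffling the cell ->
state assignment over all cells (clone membership and marginal state counts
fixed), 10,000 permutations by default:

    Z(a, b) = (O(a, b) - mean_perm(a, b)) / sd_perm(a, b)

Positive Z marks coupled states (more shared clones than chance), negative Z
anti-coupled ones.  Row-wise Pearson correlations of Z give the
lineage-coupling correlation matrix, and average-linkage clustering of Z rows
provides the heatmap ordering.

:class:`LineageCoupling` is the model (built from a clone table);
:meth:`LineageCoupling.fit` runs the permutations and returns a
:class:`LineageCouplingResults` carrying the matrices, the Monte-Carlo
standard errors, the degenerate-cell mask and ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def _clone_state_counts(
    clone_idx: np.ndarray, state_idx: np.ndarray, n_clones: int, n_states: int
) -> np.ndarray:
    return np.bincount(
        clone_idx * n_states + state_idx, minlength=n_clones * n_states
    ).reshape(n_clones, n_states)


def _shared_matrix(counts: np.ndarray, min_cells: int) -> np.ndarray:
    """Symmetric shared-clone count matrix from a clone x state count table.

    Off-diagonal (a, b): clones with >= min_cells of both a and b.
    Diagonal (a, a): clones with >= min_cells cells of a (self-coupling).
    """
    present = counts >= min_cells
    return present.T.astype(np.int64) @ present


def shared_clone_count(
    clones: pd.DataFrame,
    state_a: str,
    state_b: str,
    min_cells: int = 2,
    state_col: str = "cell_type",
) -> int:
    """Number of clones with >= ``min_cells`` cells of each of two states."""
    known = set(clones[state_col].dropna().unique())
    for s in (state_a, state_b):
        if s not in known:
            raise ValueError(f"unknown state {s!r}; known states: {sorted(known)}")
    per_clone = clones.groupby("clone_id")[state_col].value_counts().unstack(fill_value=0)
    ok_a = per_clone.get(state_a, 0) >= min_cells
    ok_b = per_clone.get(state_b, 0) >= min_cells
    return int((ok_a & ok_b).sum())


class LineageCoupling:
    """Permutation model of clone sharing between cell states.

    Parameters
    ----------
    clones
        Clone table with ``clone_id`` and a state column per cell.
    state_col
        Column holding the state (cell type / subtype) labels.
    min_cells
        Minimum cells of a state within a clone for the clone to count as
        containing that state (the ">= 2 cells of each state" sharing rule).
    stratify_col
        Optional column (e.g. ``dataset``); labels are then shuffled within
        each stratum instead of globally.
    """

    def __init__(
        self,
        clones: pd.DataFrame,
        state_col: str = "cell_type",
        min_cells: int = 2,
        stratify_col: Optional[str] = None,
    ) -> None:
        if min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        tab = clones.dropna(subset=[state_col])
        # canonical cell order: results are invariant to input row order
        tab = tab.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
        n_na = len(clones) - len(tab)
        if n_na:
            warnings.warn(f"dropping {n_na} cells without a {state_col!r} label")
        if not len(tab):
            raise ValueError("no labelled cells")
        states = np.array(sorted(tab[state_col].unique()))
        if len(states) < 2:
            raise ValueError("need at least 2 states")
        self.clones = tab.reset_index(drop=True)
        self.state_col = state_col
        self.min_cells = min_cells
        self.stratify_col = stratify_col
        self.states = states
        cid, self._clone_idx = np.unique(tab["clone_id"].to_numpy(), return_inverse=True)
        self._n_clones = len(cid)
        sindex = pd.Series(np.arange(len(states)), index=states)
        self._state_idx = sindex[tab[state_col]].to_numpy()
        self._strata = (
            tab[stratify_col].to_numpy() if stratify_col is not None else None
        )

    @property
    def observed(self) -> pd.DataFrame:
        counts = _clone_state_counts(
            self._clone_idx, self._state_idx, self._n_clones, len(self.states)
        )
        O = _shared_matrix(counts, self.min_cells)
        return pd.DataFrame(O, index=self.states, columns=self.states)

    def fit(self, n_permutations: int = 10_000, seed: int = 0) -> "LineageCouplingResults":
        """Run the permutation null and return the coupling results."""
        if n_permutations < 2:
            raise ValueError("n_permutations must be >= 2")
        rng = np.random.default_rng(seed)
        S = len(self.states)
        K = self._n_clones
        O = self.observed.to_numpy()
        labels = self._state_idx.copy()
        if self._strata is not None:
            groups = [np.flatnonzero(self._strata == g) for g in pd.unique(self._strata)]
        acc = np.zeros((S, S), dtype=np.float64)
        acc2 = np.zeros((S, S), dtype=np.float64)
        for _ in range(n_permutations):
            if self._strata is None:
                perm = rng.permutation(labels)
            else:
                perm = labels.copy()
                for g in groups:
                    perm[g] = labels[g][rng.permutation(len(g))]
            counts = _clone_state_counts(self._clone_idx, perm, K, S)
            Op = _shared_matrix(counts, self.min_cells)
            acc += Op
            acc2 += Op.astype(np.float64) ** 2
        mu = acc / n_permutations
        var = np.maximum(acc2 / n_permutations - mu**2, 0.0)
        sd = np.sqrt(var)
        mask = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (O - mu) / sd
        Z[mask] = 0.0
        if mask.any():
            warnings.warn(
                f"{int(mask.sum())} state pairs with zero permutation spread; "
                "their z-scores are set to 0 and flagged in zero_sd_mask"
            )
        corr, corr_mask = _z_row_correlations(Z)
        ordering = _cluster_order(Z, self.states)
        idx = self.states
        return LineageCouplingResults(
            states=idx,
            observed=pd.DataFrame(O, index=idx, columns=idx),
            perm_mean=pd.DataFrame(mu, index=idx, columns=idx),
            perm_std=pd.DataFrame(sd, index=idx, columns=idx),
            zscores=pd.DataFrame(Z, index=idx, columns=idx),
            corr=pd.DataFrame(corr, index=idx, columns=idx),
            zero_sd_mask=pd.DataFrame(mask, index=idx, columns=idx),
            corr_mask=pd.DataFrame(corr_mask, index=idx, columns=idx),
            ordering=ordering,
            n_permutations=n_permutations,
            seed=seed,
            min_cells=self.min_cells,
        )


def _z_row_correlations(Z: np.ndarray, method: str = "pearson") -> tuple[np.ndarray, np.ndarray]:
    """Correlations between z-score rows, self-coupling entries excluded.

    For a pair of states (a, b) the correlated vectors are the rows
    ``Z[a, .]`` and ``Z[b, .]`` restricted to partner states other than a and
    b, so no self-coupling (diagonal) value enters.  Constant rows give an
    undefined correlation: masked and NaN.
    """
    S = Z.shape[0]
    C = np.eye(S)
    mask = np.zeros((S, S), dtype=bool)
    for a in range(S):
        for b in range(a + 1, S):
            keep = np.ones(S, dtype=bool)
            keep[[a, b]] = False
            x, y = Z[a, keep], Z[b, keep]
            if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                C[a, b] = C[b, a] = np.nan
                mask[a, b] = mask[b, a] = True
                continue
            if method == "pearson":
                r = np.corrcoef(x, y)[0, 1]
            elif method == "spearman":
                from scipy.stats import spearmanr

                r = spearmanr(x, y).statistic
            else:
                raise ValueError(f"unknown correlation method {method!r}")
            C[a, b] = C[b, a] = r
    return C, mask


def _cluster_order(Z: np.ndarray, states: Sequence[str]) -> list:
    """Average-linkage (Euclidean) leaf order of z-score rows."""
    if Z.shape[0] < 3:
        return list(states)
    link = hierarchy.linkage(pdist(Z, metric="euclidean"), method="average")
    return [states[i] for i in hierarchy.leaves_list(link)]


def coupling_correlations(result: "LineageCouplingResults", method: str = "pearson"):
    """Correlation matrix of z-score rows plus the clustered state ordering."""
    C, mask = _z_row_correlations(result.zscores.to_numpy(), method=method)
    idx = result.states
    ordering = _cluster_order(result.zscores.to_numpy(), idx)
    df = pd.DataFrame(C, index=idx, columns=idx)
    if mask.any():
        warnings.warn("constant z-score rows: correlations masked as NaN")
    return df, ordering


class LineageCouplingResults:
    """Observed counts, permutation moments, z-scores and correlations."""

    def __init__(
        self,
        states,
        observed,
        perm_mean,
        perm_std,
        zscores,
        corr,
        zero_sd_mask,
        corr_mask,
        ordering,
        n_permutations,
        seed,
        min_cells,
    ) -> None:
        self.states = states
        self.observed = observed
        self.perm_mean = perm_mean
        self.perm_std = perm_std
        self.zscores = zscores
        self.corr = corr
        self.zero_sd_mask = zero_sd_mask
        self.corr_mask = corr_mask
        self.ordering = ordering
        self.n_permutations = n_permutations
        self.seed = seed
        self.min_cells = min_cells

    @property
    def mc_standard_error(self) -> pd.DataFrame:
        """Monte-Carlo standard error of each permutation mean, in count units."""
        return self.perm_std / np.sqrt(self.n_permutations)

    def summary(self) -> str:
        lines = [
            "Lineage coupling (permutation null)",
            f"  states: {len(self.states)}   permutations: {self.n_permutations}"
            f"   seed: {self.seed}   min_cells: {self.min_cells}",
            "",
            f"{'pair':<34}{'observed':>9}{'mean':>10}{'sd':>9}{'z':>9}",
        ]
        for i, a in enumerate(self.states):
            for j, b in enumerate(self.states):
                if j < i:
                    continue
                lines.append(
                    f"{a + ' ~ ' + b:<34}"
                    f"{self.observed.iloc[i, j]:>9d}"
                    f"{self.perm_mean.iloc[i, j]:>10.2f}"
                    f"{self.perm_std.iloc[i, j]:>9.2f}"
                    f"{self.zscores.iloc[i, j]:>9.2f}"
                )
        lines.append("")
        lines.append("clustered ordering: " + ", ".join(map(str, self.ordering)))
        return "\n".join(lines)

    def to_csv_dir(self, outdir: str | Path) -> dict:
        """Write O, mu, sigma, Z, C, the masks and a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("observed", self.observed),
            ("perm_mean", self.perm_mean),
            ("perm_std", self.perm_std),
            ("zscores", self.zscores),
            ("correlations", self.corr),
            ("zero_sd_mask", self.zero_sd_mask),
            ("corr_mask", self.corr_mask),
        ]:
            p = outdir / f"coupling_{name}.csv"
            df.to_csv(p)
            paths[name] = str(p)
        meta = {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "min_cells": self.min_cells,
            "states": list(map(str, self.states)),
            "ordering": list(map(str, self.ordering)),
        }
        p = outdir / "coupling_summary.json"
        p.write_text(json.dumps(meta, indent=2) + "\n")
        paths["summary"] = str(p)
        return paths

    def plot_heatmap(self, which: str = "zscores", path: Optional[str] = None):
        """Clustered heatmap of the z-score or correlation matrix."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        mat = {"zscores": self.zscores, "correlations": self.corr}[which]
        order = list(self.ordering)
        mat = mat.loc[order, order]
        fig, ax = plt.subplots(figsize=(6, 5))
        vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(len(order)), order, rotation=90)
        ax.set_yticks(range(len(order)), order)
        fig.colorbar(im, ax=ax, label=which)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig
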