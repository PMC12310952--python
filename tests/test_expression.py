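"""Normalization closed forms, PCA-distance behaviour, module scores."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import clonetrace as ct


def _adata(counts, obs=None):
    a = ad.AnnData(X=sparse.csr_matrix(np.asarray(counts, dtype=np.int64)))
    a.obs_names = [f"cell{i}" for i in range(a.n_obs)]
    a.var_names = [f"g{i}" for i in range(a.n_vars)]
    if obs:
        for k, v in obs.items():
            a.obs[k] = v
    return a


class TestLognormalize:
    def test_unit_closed_form(self):
        """A gene with 1 count in a 10,000-count cell maps to ln(2)."""
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [1, 9999, 0]
        out = ct.lognormalize(_adata(counts))
        X = out.X.toarray()
        assert X[0, 0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert X[0, 2] == 0.0

    def test_per_cell_conservation(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(40, 100))
        counts[:, 0] += 1  # no all-zero cells
        out = ct.lognormalize(_adata(counts))
        X = out.X.toarray()
        recon = (np.exp(X) - 1.0).sum(axis=1)
        np.testing.assert_allclose(recon, 10_000.0, rtol=0, atol=1e-9 * 10_000)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(10, 20)) + 1
        out = ct.lognormalize(_adata(counts)).X.toarray()
        perm = rng.permutation(10)
        out_perm = ct.lognormalize(_adata(counts[perm])).X.toarray()
        np.testing.assert_allclose(out_perm, out[perm])

    def test_all_zero_cell_named(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="cell1"):
            ct.lognormalize(_adata(counts))

    def test_agrees_with_scanpy(self):
        import scanpy as sc

        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(25, 60)) + (rng.random((25, 60)) < 0.1)
        counts[:, 0] += 1
        mine = ct.lognormalize(_adata(counts)).X.toarray()
        other = _adata(counts)
        sc.pp.normalize_total(other, target_sum=1e4)
        sc.pp.log1p(other)
        # scanpy computes in float32; agreement to that precision
        np.testing.assert_allclose(mine, other.X.toarray(), rtol=1e-5, atol=1e-6)


def _gaussian_adata(rng, n_per_group, shift=0.0, n_genes=50):
    """Two 'timepoints' drawn i.i.d. (plus an optional mean shift)."""
    a = rng.normal(size=(n_per_group, n_genes))
    b = rng.normal(size=(n_per_group, n_genes)) + shift
    X = np.vstack([a, b])
    adata = ad.AnnData(X=X)
    adata.obs_names = [f"c{i}" for i in range(2 * n_per_group)]
    adata.var_names = [f"g{i}" for i in range(n_genes)]
    adata.obs["subtype"] = "S"
    adata.obs["timepoint"] = ["t0"] * n_per_group + ["t1"] * n_per_group
    return adata


class TestPCADistance:
    def test_iid_groups_give_unit_ratio(self):
        """Two groups from one distribution: R within 10% of 1."""
        adata = _gaussian_adata(np.random.default_rng(3), 200)
        res = ct.PCADistance(adata).fit(ref_time="t0", n_components=10, seed=0)
        assert abs(res.table["R"].iloc[0] - 1.0) < 0.1

    def test_monotone_in_drift(self):
        rs = []
        for delta in (0.0, 0.3, 0.6, 0.9, 1.2):
            adata = _gaussian_adata(np.random.default_rng(4), 120, shift=delta)
            res = ct.PCADistance(adata).fit(ref_time="t0", n_components=10, seed=0)
            rs.append(res.table["R"].iloc[0])
        assert all(b > a for a, b in zip(rs, rs[1:]))

    def test_identical_cells_is_error_not_nan(self):
        X = np.ones((20, 10))
        adata = ad.AnnData(X=X)
        adata.obs["subtype"] = "S"
        adata.obs["timepoint"] = ["t0"] * 10 + ["t1"] * 10
        with pytest.raises(ValueError, match="scrambled distance is zero"):
            ct.PCADistance(adata).fit(ref_time="t0", n_components=5, seed=0)

    def test_too_few_cells_or_components_rejected(self):
        adata = _gaussian_adata(np.random.default_rng(5), 30)
        with pytest.raises(ValueError, match="n_components"):
            ct.PCADistance(adata).fit(ref_time="t0", n_components=500, seed=0)
        adata.obs.loc[adata.obs_names[1:60], "subtype"] = "other"
        with pytest.raises(ValueError, match="fewer than 2"):
            ct.PCADistance(adata).fit(ref_time="t0", subtypes=["S"], n_components=5, seed=0)

    def test_cell_order_invariance(self):
        adata = _gaussian_adata(np.random.default_rng(6), 60)
        r1 = ct.PCADistance(adata).fit(ref_time="t0", n_components=8, seed=1)
        perm = np.random.default_rng(7).permutation(adata.n_obs)
        r2 = ct.PCADistance(adata[perm].copy()).fit(ref_time="t0", n_components=8, seed=1)
        assert r1.table["D"].iloc[0] == pytest.approx(r2.table["D"].iloc[0], rel=1e-9)


class TestModuleScore:
    def test_null_gene_set_scores_near_zero(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, size=(150, 200)) + 1
        adata = ct.lognormalize(_adata(counts))
        scores = ct.module_score(adata, [f"g{i}" for i in range(0, 20)], seed=0)
        assert abs(scores.mean()) < 0.05

    def test_marker_set_separates_types(self):
        """Marker scores rank the matching cell type with AUC > 0.9 at the
        generator's default effect size."""
        cfg = ct.SimulationConfig(
            n_progenitors_per_subtype={"RGC_1": 40, "RGC_2": 40},
            n_genes=200, n_marker_genes_per_type=20, seed=21,
        )
        sim = ct.simulate_experiment(cfg)
        adata = ct.lognormalize(sim.adata)
        markers = sim.adata.uns["marker_genes"]["Ex_neuron"]
        scores = ct.module_score(adata, markers, seed=0)
        is_neuron = (adata.obs["cell_type"] == "Ex_neuron").to_numpy()
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(is_neuron, scores.to_numpy()) > 0.9

    def test_constant_matrix_scores_zero(self):
        adata = _adata(np.full((10, 50), 3))
        scores = ct.module_score(adata, ["g1", "g2"], seed=0)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_unmatched_gene_set_is_error(self):
        adata = _adata(np.ones((5, 10), dtype=int))
        with pytest.raises(ValueError, match="no gene matched"):
            ct.module_score(adata, ["absent1", "absent2"])

    def test_depends_only_on_set_and_controls(self):
        """Perturbing a gene that is in neither the set nor the control pool,
        without changing its mean-expression rank, leaves scores unchanged."""
        rng = np.random.default_rng(9)
        X = rng.normal(loc=5.0, scale=0.5, size=(30, 40))
        adata = ad.AnnData(X=X.copy())
        adata.obs_names = [f"c{i}" for i in range(30)]
        adata.var_names = [f"g{i}" for i in range(40)]
        gene_set = ["g0", "g1"]
        s1 = ct.module_score(adata, gene_set, n_bins=4, n_ctrl=5, seed=3)
        # reconstruct the control pool to find an uninvolved gene
        means = X.mean(axis=0)
        order = pd.Series(means, index=adata.var_names).rank(method="first")
        bins = pd.qcut(order, q=4, labels=False)
        used_bins = {bins["g0"], bins["g1"]}
        candidates = [g for g in adata.var_names
                      if bins[g] not in used_bins and g not in gene_set]
        g = candidates[0]
        j = list(adata.var_names).index(g)
        X2 = X.copy()
        X2[:, j] += rng.normal(scale=1e-3, size=30)  # tiny, rank-preserving
        adata2 = ad.AnnData(X=X2)
        adata2.obs_names = adata.obs_names
        adata2.var_names = adata.var_names
        s2 = ct.module_score(adata2, gene_set, n_bins=4, n_ctrl=5, seed=3)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    def test_correlates_with_scanpy_score(self):
        import scanpy as sc

        rng = np.random.default_rng(10)
        counts = rng.poisson(2.0, size=(120, 150)) + 1
        counts[:60, :15] += rng.poisson(10.0, size=(60, 15))  # elevated block
        adata = ct.lognormalize(_adata(counts))
        gene_set = [f"g{i}" for i in range(15)]
        mine = ct.module_score(adata, gene_set, seed=0)
        sc.tl.score_genes(adata, gene_set, score_name="sc_score", random_state=0)
        r = np.corrcoef(mine.to_numpy(), adata.obs["sc_score"].to_numpy())[0, 1]
        assert r > 0.9
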