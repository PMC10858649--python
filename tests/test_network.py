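import numpy as np
import pandas as pd
import pytest

from dinolnc.network import (
    NetworkParams,
    bicor,
    build_network,
    code_traits,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit_index,
    signed_adjacency,
    tom_from_adjacency,
)


def _planted_expression(rng, n_per=60, n_samples=20, r_within=0.95):
    """Two blocks of tightly co-expressed features plus noise features."""
    rows, names = [], []
    for b in range(2):
        latent = rng.normal(size=n_samples)
        for i in range(n_per):
            noise_sd = np.sqrt(1 / r_within**2 - 1)
            rows.append(latent + rng.normal(scale=noise_sd, size=n_samples))
            names.append(f"b{b}_f{i}")
    for i in range(20):
        rows.append(rng.normal(size=n_samples))
        names.append(f"noise_{i}")
    return pd.DataFrame(rows, index=names)


class TestCorrelation:
    def test_bicor_agrees_with_pearson_on_clean_gaussians(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 200))
        b = bicor(x)
        p = np.corrcoef(x)
        assert np.allclose(b, p, atol=0.05)

    def test_bicor_resists_a_single_outlier(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100)
        x = np.vstack([z, z + rng.normal(scale=0.1, size=100)])
        x_out = x.copy()
        x_out[1, 0] = 1000.0
        r_bicor = bicor(x_out)[0, 1]
        r_pearson = np.corrcoef(x_out)[0, 1]
        assert r_bicor > 0.9 > r_pearson

    def test_mad_zero_rows_fall_back_to_pearson(self):
        x = np.vstack([
            np.concatenate([np.zeros(18), [5.0, 9.0]]),  # MAD = 0
            np.arange(20.0),
        ])
        r = bicor(x)
        assert np.isfinite(r).all()

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bicor(np.vstack([np.ones(10), np.arange(10.0)]))


class TestSoftThreshold:
    def test_power_monotonically_shrinks_adjacency(self):
        rng = np.random.default_rng(2)
        cor = np.corrcoef(rng.normal(size=(12, 30)))
        a6 = signed_adjacency(cor, 6)
        a12 = signed_adjacency(cor, 12)
        off = ~np.eye(12, dtype=bool)
        assert (a12[off] <= a6[off] + 1e-12).all()

    def test_fit_index_matches_independent_binned_regression(self):
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        k = rng.pareto(1.5, size=2000) + 1.0
        rsq, slope = scale_free_fit_index(k, n_bins=10)
        # independent recomputation of the binned log-log regression
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            m = which == b
            if m.sum():
                xs.append(np.log10(k[m].mean()))
                ys.append(np.log10(m.sum() / len(k)))
        fit = sps.linregress(xs, ys)
        assert slope == pytest.approx(fit.slope)
        assert rsq == pytest.approx(fit.rvalue**2)
        assert slope < 0 and rsq > 0.8  # heavy tail is close to scale-free

    def test_no_qualifying_power_returns_default(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(40, 10)))
        params = pick_soft_threshold(expr, powers=range(1, 6))
        assert params.power == 18

    def test_degenerate_matrix_rejected(self):
        expr = pd.DataFrame(np.ones((5, 8)))
        with pytest.raises(ValueError, match="degenerate"):
            pick_soft_threshold(expr)


class TestTOM:
    def test_zero_offdiagonal_adjacency_gives_zero_tom(self):
        a = np.eye(3)
        tom = tom_from_adjacency(a)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(tom[off], 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_matches_hand_computed_formula_on_dense_graph(self):
        a = np.array([
            [1.0, 0.8, 0.2, 0.5, 0.1],
            [0.8, 1.0, 0.4, 0.3, 0.2],
            [0.2, 0.4, 1.0, 0.6, 0.7],
            [0.5, 0.3, 0.6, 1.0, 0.4],
            [0.1, 0.2, 0.7, 0.4, 1.0],
        ])
        tom = tom_from_adjacency(a)
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                shared = sum(a0[i, u] * a0[u, j] for u in range(5))
                want = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                assert tom[i, j] == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(3))
    def test_bounds_and_symmetry_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 1, size=(10, 10))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        tom = tom_from_adjacency(signed_adjacency(c, 6))
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(tom, tom.T)


class TestModules:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        expr = _planted_expression(rng)
        params = NetworkParams(power=6, min_module_size=30)
        _, tom = build_network(expr, params)
        labels = detect_modules(tom, params)
        for b in range(2):
            block = labels[[f"b{b}_f{i}" for i in range(60)]]
            assert block.nunique() == 1
            assert block.iloc[0] > 0
        assert labels[labels.index.str.startswith("b0")].iloc[0] != \
            labels[labels.index.str.startswith("b1")].iloc[0]

    def test_below_min_size_left_unassigned(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(20, 10)),
                            index=[f"f{i}" for i in range(20)])
        params = NetworkParams(power=6, min_module_size=30)
        _, tom = build_network(expr, params)
        with pytest.warns(UserWarning):
            labels = detect_modules(tom, params)
        assert (labels == 0).all()

    def test_labels_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(6)
        expr = _planted_expression(rng, n_per=40)
        params = NetworkParams(power=6, min_module_size=30)
        _, tom = build_network(expr, params)
        labels = detect_modules(tom, params)
        perm = rng.permutation(expr.index)
        _, tom_p = build_network(expr.loc[perm], params)
        labels_p = detect_modules(tom_p, params)
        # same partition up to label names
        for m in labels.unique():
            members = labels.index[labels == m]
            assert labels_p[members].nunique() == 1


class TestEigengenes:
    def test_duplicated_module_is_merged(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=15)
        rows = {f"a{i}": latent + rng.normal(scale=0.1, size=15) for i in range(35)}
        rows.update({f"b{i}": latent + rng.normal(scale=0.1, size=15)
                     for i in range(35)})
        expr = pd.DataFrame(rows).T
        assign = pd.Series([1] * 35 + [2] * 35, index=expr.index)
        _, merged, _ = module_eigengenes(expr, assign, NetworkParams(power=6))
        assert merged[merged > 0].nunique() == 1

    def test_identical_feature_module_eigengene_is_standardized_vector(self):
        v = np.arange(12.0)
        expr = pd.DataFrame([v] * 30 + [np.random.default_rng(8).normal(size=12)
                                        for _ in range(5)],
                            index=[f"f{i}" for i in range(35)])
        assign = pd.Series([1] * 30 + [0] * 5, index=expr.index)
        eg, _, _ = module_eigengenes(expr, assign, NetworkParams(power=6))
        z = (v - v.mean()) / v.std()
        e = eg[1].to_numpy()
        cor = np.corrcoef(e, z)[0, 1]
        assert abs(cor) == pytest.approx(1.0)
        assert np.dot(e, z) > 0  # oriented with module mean expression

    def test_eigengene_variance_explained_is_maximal(self):
        rng = np.random.default_rng(9)
        expr = _planted_expression(rng, n_per=40)
        assign = pd.Series(
            [1] * 40 + [2] * 40 + [0] * 20, index=expr.index
        )
        eg, _, _ = module_eigengenes(expr, assign, NetworkParams(power=6))
        sub = expr.iloc[:40].to_numpy()
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        e = eg[1].to_numpy()
        var_e = ((z @ e) ** 2).sum()
        for _ in range(100):
            d = rng.normal(size=len(e))
            d /= np.linalg.norm(d)
            assert ((z @ d) ** 2).sum() <= var_e + 1e-9

    def test_planted_temperature_module_correlates_with_trait(self):
        rng = np.random.default_rng(10)
        temp = np.array([20] * 6 + [30] * 6)
        latent = (temp - 25) / 5.0
        rows = {f"f{i}": latent + rng.normal(scale=0.2, size=12) for i in range(35)}
        expr = pd.DataFrame(rows).T
        assign = pd.Series(1, index=expr.index)
        traits = pd.DataFrame({"temperature": temp},
                              index=expr.columns)
        _, _, tc = module_eigengenes(expr, assign, NetworkParams(power=6),
                                     traits=traits)
        r = tc.loc[(tc.module == 1) & (tc.trait == "temperature"), "r"].iloc[0]
        assert abs(r) >= 0.9

    def test_trait_coding_binary_and_numeric(self):
        traits = pd.DataFrame({
            "temperature": [20, 30, 20],
            "phase": ["expo", "stat", "expo"],
        }, index=list("abc"))
        coded = code_traits(traits)
        assert list(coded["temperature"]) == [20.0, 30.0, 20.0]
        assert sorted(coded["phase"].unique()) == [0.0, 1.0]

    def test_module_gene_lncrna_counts_rank_correlate(self, bundle):
        # proportional plants: bigger modules carry both more genes and more
        # lncRNA-class features
        from scipy.stats import spearmanr

        truth = bundle.module_truth
        sizes_genes, sizes_lnc = [], []
        for m in sorted(truth[truth > 0].unique()):
            members = truth.index[truth == m]
            sizes_genes.append(sum(f.startswith("gene") for f in members))
            sizes_lnc.append(sum(not f.startswith("gene") for f in members))
        if len(sizes_genes) > 2:
            rho, _ = spearmanr(sizes_genes, sizes_lnc)
            assert rho > 0
        else:
            assert min(sizes_lnc) > 0
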