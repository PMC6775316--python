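import numpy as np
import pandas as pd
import pytest
from scipy import special
from sklearn.metrics import adjusted_rand_score

from lncnet import syndata
from lncnet.network import (
    adjacency,
    analyze_group,
    correlation_pvalue,
    detect_modules,
    detect_outlier_samples,
    module_eigengene,
    module_eigengenes,
    module_membership_gene_significance,
    module_trait_correlation,
    pick_soft_threshold,
    tom_from_expression,
    tom_similarity,
)


def tom_oracle(A):
    """O(n^3) triple-loop reference implementation."""
    n = A.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
    return tom


def random_adjacency(rng, n):
    C = rng.uniform(-1, 1, size=(n, n))
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    return adjacency(C, int(rng.integers(1, 8)))


def expr_frame(mat):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(
        mat,
        index=[f"T{i}" for i in range(mat.shape[0])],
        columns=[f"S{j}" for j in range(mat.shape[1])],
    )


class TestOutliers:
    def test_identical_samples_none_flagged(self):
        X = expr_frame(np.tile(np.arange(10.0)[:, None], (1, 6)))
        assert detect_outlier_samples(X) == []

    def test_shifted_sample_flagged(self, rng):
        mat = rng.standard_normal((100, 8))
        mat[:, 3] += 10.0
        assert detect_outlier_samples(expr_frame(mat)) == ["S3"]

    def test_order_invariance(self, rng):
        mat = rng.standard_normal((50, 8))
        mat[:, 0] += 10.0
        X = expr_frame(mat)
        flagged = set(detect_outlier_samples(X))
        perm = list(rng.permutation(X.columns))
        assert set(detect_outlier_samples(X[perm])) == flagged

    def test_clean_data_none_flagged(self, rng):
        X = expr_frame(rng.standard_normal((80, 10)))
        assert detect_outlier_samples(X) == []

    def test_invalid_cut_height(self, rng):
        X = expr_frame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            detect_outlier_samples(X, cut_height=-1.0)

    def test_needs_three_samples(self, rng):
        with pytest.raises(ValueError):
            detect_outlier_samples(expr_frame(rng.standard_normal((10, 2))))


class TestSoftThreshold:
    def test_hub_data_satisfies_rule(self):
        X = syndata.scale_free_expression(seed=11)
        scan = pick_soft_threshold(X)
        assert scan.satisfied
        idx = scan.powers.index(scan.chosen_power)
        assert scan.scale_free_r2[idx] >= 0.8
        assert scan.chosen_power <= 15

    def test_candidates_capped_at_15_by_default(self):
        X = syndata.scale_free_expression(seed=11)
        scan = pick_soft_threshold(X)
        assert max(scan.powers) == 15 and min(scan.powers) == 1

    def test_identical_genes_degenerate(self, rng):
        v = rng.standard_normal(10)
        X = expr_frame(np.tile(v, (25, 1)) + 1e-9 * rng.standard_normal((25, 10)))
        with pytest.warns(UserWarning):
            scan = pick_soft_threshold(X)
        assert not scan.satisfied

    def test_all_constant_rejected(self):
        X = expr_frame(np.ones((25, 10)))
        with pytest.raises(ValueError):
            pick_soft_threshold(X)

    def test_minimum_sizes(self, rng):
        with pytest.raises(ValueError, match="20 transcripts"):
            pick_soft_threshold(expr_frame(rng.standard_normal((5, 10))))
        with pytest.raises(ValueError, match="4 samples"):
            pick_soft_threshold(expr_frame(rng.standard_normal((25, 3))))


class TestAdjacency:
    def test_perfect_correlation(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 4, 9):
            np.testing.assert_allclose(adjacency(C, beta), 1.0)

    def test_direct_power(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency(C, 4)[0, 1] == pytest.approx(0.0625)

    def test_unsigned_symmetry(self):
        Cp = np.array([[1.0, 0.5], [0.5, 1.0]])
        Cn = np.array([[1.0, -0.5], [-0.5, 1.0]])
        np.testing.assert_allclose(adjacency(Cp, 5), adjacency(Cn, 5))

    def test_monotone_decreasing_in_beta(self, rng):
        A1 = random_adjacency(rng, 10)
        C = rng.uniform(-0.99, 0.99, size=(10, 10))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        A3, A5 = adjacency(C, 3), adjacency(C, 5)
        off = ~np.eye(10, dtype=bool)
        assert (A5[off] <= A3[off] + 1e-15).all()

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency(np.eye(2), 0)

    def test_asymmetric_rejected(self):
        C = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            adjacency(C, 2)


class TestTOM:
    def test_two_node_closed_form(self):
        A = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.37)
        assert tom[0, 0] == 1.0

    def test_complete_graph(self):
        n = 7
        A = np.ones((n, n))
        np.testing.assert_allclose(tom_similarity(A), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        rng = np.random.default_rng(5)
        A = random_adjacency(rng, 12)
        np.testing.assert_allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)

    def test_range_and_symmetry(self, rng):
        for _ in range(10):
            A = random_adjacency(rng, int(rng.integers(3, 15)))
            tom = tom_similarity(A)
            assert (tom >= 0).all() and (tom <= 1).all()
            np.testing.assert_allclose(tom, tom.T)
            np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_asymmetric_rejected(self):
        A = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError):
            tom_similarity(A)


def two_block_expression(rng, block=50, n_samples=30, within=0.9):
    f = rng.standard_normal((2, n_samples))
    rows = [
        np.sqrt(within) * f[i // block]
        + np.sqrt(1 - within) * rng.standard_normal(n_samples)
        for i in range(2 * block)
    ]
    return expr_frame(np.array(rows))


class TestDetectModules:
    def test_two_planted_blocks_perfectly_recovered(self):
        rng = np.random.default_rng(17)
        X = two_block_expression(rng)
        tom = tom_from_expression(X, 6)
        labels = detect_modules(tom, min_module_size=20)
        truth = [i // 50 for i in range(100)]
        assert adjusted_rand_score(truth, labels.values) == 1.0

    def test_noise_genes_mostly_unassigned(self):
        rng = np.random.default_rng(23)
        X = expr_frame(rng.standard_normal((100, 20)))
        tom = tom_from_expression(X, 6)
        labels = detect_modules(tom, min_module_size=10)
        assert (labels == 0).mean() >= 0.9

    def test_undersized_cluster_labeled_zero(self):
        rng = np.random.default_rng(3)
        X = two_block_expression(rng, block=9, n_samples=25)
        tom = tom_from_expression(X, 6)
        labels = detect_modules(tom, min_module_size=10)
        assert (labels == 0).all()

    def test_min_module_size_validation(self):
        with pytest.raises(ValueError):
            detect_modules(np.eye(5), min_module_size=1)

    def test_modules_numbered_by_decreasing_size(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal((2, 30))
        rows = [np.sqrt(0.9) * f[0 if i < 40 else 1]
                + np.sqrt(0.1) * rng.standard_normal(30) for i in range(60)]
        tom = tom_from_expression(expr_frame(np.array(rows)), 6)
        labels = detect_modules(tom, min_module_size=10)
        sizes = labels[labels > 0].value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)


class TestEigengene:
    def test_rank_one_module_is_zscore(self, rng):
        v = rng.standard_normal(12)
        X = expr_frame(np.tile(v, (5, 1)))
        eig = module_eigengene(X)
        z = (v - v.mean()) / v.std()
        np.testing.assert_allclose(np.abs(np.corrcoef(eig, z)[0, 1]), 1.0)
        np.testing.assert_allclose(eig, z, atol=1e-8)

    def test_single_transcript_module(self, rng):
        v = rng.standard_normal(10)
        eig = module_eigengene(expr_frame(v[None, :]))
        np.testing.assert_allclose(eig, (v - v.mean()) / v.std())

    def test_matches_svd_oracle(self, rng):
        X = expr_frame(rng.standard_normal((30, 10)))
        eig = module_eigengene(X)
        mat = X.to_numpy()
        zs = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(zs)
        pc1 = vt[0]
        r = np.corrcoef(eig, pc1)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        assert eig.std() == pytest.approx(1.0)

    def test_orientation_rule(self, rng):
        f = rng.standard_normal(20)
        rows = [f + 0.1 * rng.standard_normal(20) for _ in range(10)]
        eig = module_eigengene(expr_frame(np.array(rows)))
        zs = expr_frame(np.array(rows)).apply(
            lambda r: (r - r.mean()) / r.std(), axis=1
        )
        assert np.corrcoef(eig, zs.mean(axis=0))[0, 1] >= 0


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        trait = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        eig = pd.DataFrame({1: (trait - trait.mean()) / trait.std()})
        mt = module_trait_correlation(eig, trait)
        assert mt.loc[1, "r"] == pytest.approx(1.0)
        # numerically r is 1 - O(eps); p collapses to ~0
        assert mt.loc[1, "pvalue"] < 1e-30
        assert correlation_pvalue(1.0, 8) == 0.0
        assert correlation_pvalue(-1.0, 8) == 0.0

    def test_zero_correlation_gives_p_one(self):
        trait = np.array([0, 1, 0, 1, 0, 1])
        eig = pd.DataFrame({1: [1.0, 1.0, -1.0, -1.0, 0.0, 0.0]})
        mt = module_trait_correlation(eig, trait)
        assert mt.loc[1, "pvalue"] == pytest.approx(1.0)

    def test_p_matches_t_cdf_oracle(self):
        # r = 0.6, n = 20 -> t = 2.846, df = 18; independent oracle via
        # the regularized incomplete beta function
        r, n = 0.6, 20
        df = n - 2
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)
        oracle = special.betainc(df / 2.0, 0.5, df / (df + t * t))
        assert correlation_pvalue(r, n) == pytest.approx(oracle, rel=1e-12)
        assert t == pytest.approx(r * np.sqrt(df) / np.sqrt(1 - r**2))

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame({1: [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(eig, [1, 1, 1, 1])


class TestMMGS:
    def test_transcript_equal_to_eigengene(self, rng):
        f = rng.standard_normal(16)
        rows = np.array([f + 0.05 * rng.standard_normal(16) for _ in range(6)])
        X = expr_frame(rows)
        labels = pd.Series(1, index=X.index)
        eig = module_eigengenes(X, labels)
        X2 = X.copy()
        X2.loc["T0"] = 3.0 * eig[1].to_numpy() + 1.0  # affine copy of eigengene
        out = module_membership_gene_significance(
            X2, labels, eig, rng.integers(0, 2, 16)
        )
        assert out.loc["T0", "mm"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        f = rng.standard_normal(16)
        rows = np.array([f + 0.3 * rng.standard_normal(16) for _ in range(6)])
        X = expr_frame(rows)
        labels = pd.Series(1, index=X.index)
        eig = module_eigengenes(X, labels)
        trait = np.array([0, 1] * 8)
        out1 = module_membership_gene_significance(X, labels, eig, trait)
        X.loc["T2"] = 5.0 * X.loc["T2"] + 7.0
        out2 = module_membership_gene_significance(X, labels, eig, trait)
        assert out1.loc["T2", "mm"] == pytest.approx(out2.loc["T2", "mm"])
        assert out1.loc["T2", "gs"] == pytest.approx(out2.loc["T2", "gs"])

    def test_unassigned_gets_nan_mm(self, rng):
        X = expr_frame(rng.standard_normal((4, 12)))
        labels = pd.Series([1, 1, 1, 0], index=X.index)
        eig = module_eigengenes(X, labels)
        out = module_membership_gene_significance(
            X, labels, eig, rng.integers(0, 2, 12)
        )
        assert np.isnan(out.loc["T3", "mm"])

    def test_gs_near_one_for_trait_defining_transcript(self, rng):
        trait = np.array([0] * 8 + [1] * 8)
        rows = rng.standard_normal((5, 16))
        rows[0] = trait * 10 + 0.01 * rng.standard_normal(16)
        X = expr_frame(rows)
        labels = pd.Series([1, 1, 1, 1, 1], index=X.index)
        eig = module_eigengenes(X, labels)
        out = module_membership_gene_significance(X, labels, eig, trait)
        assert out.loc["T0", "gs"] > 0.99


class TestAnalyzeGroup:
    def test_trait_module_selected_on_synthetic_data(self):
        from conftest import small_config

        cfg = small_config(seed=42)
        counts, samples, truth = syndata.generate_counts(cfg)
        g = truth.groups[0]
        from conftest import normalized_expression

        X = normalized_expression(counts[g])
        res = analyze_group(
            X, samples[g]["trait"].to_numpy(), group=g, powers=range(1, 7),
            min_module_size=8,
        )
        module1 = {t for t, m in truth.module_label.items() if m == 1}
        selected = set(res.selected_transcripts)
        assert len(module1 & selected) / len(module1) >= 0.5
        assert res.selected_module == res.module_trait["r"].abs().idxmax()
        # eigengenes have unit variance
        assert np.allclose(res.eigengenes.std(axis=0, ddof=0), 1.0)
        # every transcript labeled
        assert res.labels.notna().all()
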