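"""Spin nulls, permutation p-values, PLS1, gene ranking, receptor LMG."""

from math import factorial
from itertools import permutations

import numpy as np
import pytest

import msngrad as mg
from msngrad.molecular import _greedy_assignment, lmg_importance


@pytest.fixture(scope="module")
def coords100():
    return mg.generate_partition(100, 4, seed=0).coords


class TestSpinPermutations:
    def test_rows_are_permutations(self, coords100):
        nulls = mg.spin_permutations(coords100, n_perm=20, seed=0)
        for row in nulls.perms:
            assert np.array_equal(np.sort(row), np.arange(100))

    def test_identity_rotation_gives_identity(self, coords100):
        perm = _greedy_assignment(coords100, coords100)
        assert np.array_equal(perm, np.arange(100))

    def test_nulls_preserve_spatial_autocorrelation(self, coords100):
        def morans_i(vals, coords):
            W = np.exp(-np.sum((coords[:, None] - coords[None]) ** 2, -1))
            np.fill_diagonal(W, 0)
            z = vals - vals.mean()
            return (len(vals) / W.sum()) * (z @ W @ z) / (z @ z)

        part = mg.generate_partition(100, 4, seed=0)
        smooth = mg.generate_annotation_maps(part, 1, smoothing_scale=0.5, seed=1)[:, 0]
        obs = morans_i(smooth, coords100)
        assert obs > 0
        nulls = mg.spin_permutations(coords100, n_perm=30, seed=2)
        null_i = np.mean([morans_i(smooth[p], coords100) for p in nulls.perms])
        shuffled = np.random.default_rng(3).permutation(smooth)
        assert null_i > morans_i(shuffled, coords100)
        assert null_i > 0

    def test_non_unit_coords_raise(self):
        with pytest.raises(ValueError, match="unit"):
            mg.spin_permutations(np.ones((10, 3)), n_perm=5, seed=0)


class TestNullPvalue:
    def test_extreme_and_median(self):
        nulls = np.arange(999, dtype=float)
        assert mg.null_pvalue(2000.0, nulls, two_sided=False) == pytest.approx(1 / 1000)
        p_mid = mg.null_pvalue(499.0, nulls, two_sided=False)
        assert abs(p_mid - 0.5) < 0.01

    def test_finite_sample_floor(self):
        nulls = np.zeros(200)
        assert mg.null_pvalue(10.0, nulls) >= 1 / 201

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mg.null_pvalue(1.0, [])

    def test_calibration_under_null(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            nulls = rng.standard_normal(99)
            obs = rng.standard_normal()
            ps.append(mg.null_pvalue(obs, nulls))
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestPls1:
    def test_response_equals_one_gene(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 10))
        res = mg.pls1(X, X[:, 3])
        # other genes' chance correlations leak into w, so the score tracks
        # the response closely but not perfectly
        assert abs(np.corrcoef(res.scores, X[:, 3])[0, 1]) > 0.9
        assert np.argmax(np.abs(res.weights)) == 3

    def test_single_gene_reduces_to_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        y = 0.6 * x + rng.standard_normal(40)
        res = mg.pls1(x[:, None], y)
        assert res.explained_variance == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12
        )

    def test_orthogonal_response_explains_nothing(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        # orthogonalize y against every centered gene column
        Xc = X - X.mean(0)
        y = y - y.mean()
        y -= Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        res = mg.pls1(X, y)
        assert res.explained_variance < 1e-10

    def test_matches_sklearn_first_component(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 12))
        y = X @ rng.standard_normal(12) + rng.standard_normal(80)
        res = mg.pls1(X, y)
        sk = PLSRegression(n_components=1, scale=True).fit(X, y)
        w_sk = sk.x_weights_[:, 0]
        if w_sk @ res.weights < 0:
            w_sk = -w_sk
        assert np.allclose(res.weights, w_sk / np.linalg.norm(w_sk), atol=1e-8)

    def test_latent_recovery(self):
        rng = np.random.default_rng(5)
        latent = rng.standard_normal(200)
        X = np.column_stack(
            [latent + 0.5 * rng.standard_normal(200) for _ in range(50)]
            + [rng.standard_normal(200) for _ in range(50)]
        )
        y = latent + 0.3 * rng.standard_normal(200)
        res = mg.pls1(X, y)
        assert abs(np.corrcoef(res.scores, latent)[0, 1]) > 0.9

    def test_constant_response_raises(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            mg.pls1(rng.standard_normal((20, 5)), np.ones(20))


class TestPlsSignificance:
    def test_strong_signal_hits_floor(self, coords100):
        rng = np.random.default_rng(7)
        latent = rng.standard_normal(100)
        X = latent[:, None] + 0.3 * rng.standard_normal((100, 30))
        y = latent + 0.1 * rng.standard_normal(100)
        nulls = mg.spin_permutations(coords100, n_perm=99, seed=7)
        p = mg.pls_significance(X, y, nulls)
        assert p == pytest.approx(1 / 100)

    def test_region_mismatch_raises(self, coords100):
        rng = np.random.default_rng(8)
        nulls = mg.spin_permutations(coords100, n_perm=5, seed=8)
        with pytest.raises(ValueError):
            mg.pls_significance(rng.standard_normal((50, 5)), rng.standard_normal(50), nulls)


class TestBootstrapGeneZ:
    def test_duplicated_gene_gets_equal_z(self):
        rng = np.random.default_rng(9)
        latent = rng.standard_normal(80)
        X = latent[:, None] + 0.5 * rng.standard_normal((80, 10))
        X = np.column_stack([X, X[:, 0]])          # exact duplicate
        y = latent + 0.3 * rng.standard_normal(80)
        res = mg.bootstrap_gene_z(X, y, n_boot=300, top_k=5, seed=9)
        assert abs(res.gene_z[0] - res.gene_z[10]) < 0.5
        assert len(res.top_list) == 5

    def test_null_genes_rarely_fdr_significant(self):
        rng = np.random.default_rng(10)
        frac = []
        for s in range(10):
            X = rng.standard_normal((100, 60))
            y = rng.standard_normal(100)
            res = mg.bootstrap_gene_z(X, y, n_boot=300, top_k=10, seed=s)
            frac.append(np.mean(res.gene_p_fdr < 0.05))
        assert np.mean(frac) <= 0.05

    def test_top_k_too_large_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            mg.bootstrap_gene_z(rng.standard_normal((30, 5)), rng.standard_normal(30), top_k=6)


class TestReceptorRegression:
    def test_exact_linear_combination(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 4))
        y = X @ [0.5, -0.2, 0.8, 0.1]
        model = mg.receptor_regression(X, y, n_boot=20, seed=12)
        assert model.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
        assert model.lmg_shares.sum() == pytest.approx(model.r2, abs=1e-8)

    def test_orthogonal_predictors_shares_equal_marginal_r2(self):
        rng = np.random.default_rng(13)
        A = rng.standard_normal((64, 4))
        Q, _ = np.linalg.qr(A - A.mean(0))
        X = Q[:, :4]
        y = X @ [1.0, 0.5, 0.2, 0.1] + 0.5 * rng.standard_normal(64)
        model = mg.receptor_regression(X, y, n_boot=20, seed=13)
        yz = (y - y.mean()) / y.std()
        for j in range(4):
            marg = np.corrcoef(X[:, j], yz)[0, 1] ** 2
            assert model.lmg_shares[j] == pytest.approx(marg, abs=1e-8)

    def test_lmg_matches_factorial_brute_force(self):
        rng = np.random.default_rng(14)
        n, P = 50, 4
        X = rng.standard_normal((n, P))
        X[:, 1] += 0.7 * X[:, 0]                   # collinearity on purpose
        y = X @ rng.standard_normal(P) + rng.standard_normal(n)
        Xc, yc = X - X.mean(0), y - y.mean()

        def r2_of(cols):
            if not cols:
                return 0.0
            Xs = Xc[:, list(cols)]
            b = np.linalg.lstsq(Xs, yc, rcond=None)[0]
            return 1 - ((yc - Xs @ b) ** 2).sum() / (yc**2).sum()

        brute = np.zeros(P)
        for order in permutations(range(P)):
            seen = []
            for j in order:
                brute[j] += r2_of(seen + [j]) - r2_of(seen)
                seen.append(j)
        brute /= factorial(P)
        shares, r2 = lmg_importance(X, y)
        assert np.allclose(shares, brute, atol=1e-10)
        assert shares.sum() == pytest.approx(r2, abs=1e-8)

    def test_spin_pvalues_attached(self, coords100):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((100, 3))
        y = X[:, 0] + 0.2 * rng.standard_normal(100)
        nulls = mg.spin_permutations(coords100, n_perm=49, seed=15)
        model = mg.receptor_regression(X, y, nulls, n_boot=20, seed=15)
        assert model.p_spin.shape == (3,)
        assert np.all(model.p_spin >= 1 / 50)
        assert model.p_spin[0] == pytest.approx(1 / 50)

    def test_too_many_predictors_raise(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError):
            mg.receptor_regression(rng.standard_normal((5, 6)), rng.standard_normal(5))
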