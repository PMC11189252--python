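"""Thresholding, cosine affinity, diffusion embedding, template, alignment."""

import numpy as np
import pytest
from scipy import linalg

import msngrad as mg
from msngrad.manifold import threshold_rows, cosine_affinity, diffusion_embedding
from conftest import random_rotation


def dense_markov_oracle(W, k=3, alpha=0.5):
    """Independent route: build P explicitly, non-symmetric scipy.linalg.eig.

    Eigenvectors are rescaled to the convention of a unit-norm eigenbasis of
    the symmetric conjugate, with the trivial eigenvector mapped to ones.
    """
    d = W.sum(1)
    Wa = W / np.outer(d**alpha, d**alpha)
    da = Wa.sum(1)
    P = Wa / da[:, None]
    evals, evecs = linalg.eig(P)
    order = np.argsort(-evals.real)
    evals, evecs = evals.real[order], evecs[:, order].real
    w = np.sqrt(da)
    cols = []
    for j in range(1, k + 1):
        v = w * evecs[:, j]
        v = v / np.linalg.norm(v)
        cols.append(v / w * np.linalg.norm(w))
    psi = np.column_stack(cols)
    lam = evals[1 : k + 1]
    lam_pos = np.clip(lam, 0.0, None)       # same degenerate-component rule
    G = psi * (lam_pos / (1 - lam_pos))
    for j in range(k):
        i = np.argmax(np.abs(G[:, j]))
        if G[i, j] < 0:
            G[:, j] = -G[:, j]
    return G, lam


def random_connected_affinity(R, rng):
    A = rng.uniform(0.05, 1.0, size=(R, R))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestThresholdRows:
    def test_kept_count(self):
        rng = np.random.default_rng(0)
        m = mg.build_msn(rng.standard_normal((20, 5)))
        S = threshold_rows(m, 0.10)
        assert all((S[i] != 0).sum() == 2 for i in range(20))

    def test_tie_break_lowest_column_first(self):
        V = np.ones((20, 20))
        S = threshold_rows(mg.MSNMatrix(V), 0.10)
        # all-equal rows: first two off-diagonal columns kept
        assert list(np.flatnonzero(S[0])) == [1, 2]
        assert list(np.flatnonzero(S[5])) == [0, 1]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        m = mg.build_msn(rng.standard_normal((30, 5)))
        S = threshold_rows(m, 0.10)
        A = m.values - 2 * np.eye(30)   # exclude diagonal from ranking
        for i in range(30):
            top3 = set(np.argsort(-A[i])[:3])
            assert set(np.flatnonzero(S[i])) == top3

    def test_too_small_density_raises(self):
        with pytest.raises(ValueError):
            threshold_rows(mg.MSNMatrix(np.eye(5)), 0.10)


class TestCosineAffinity:
    def test_identical_and_orthogonal_rows(self):
        S = np.zeros((3, 6))
        S[0, :3] = [1.0, 2.0, 3.0]
        S[1, :3] = [2.0, 4.0, 6.0]      # same direction
        S[2, 3:] = [1.0, 1.0, 1.0]      # disjoint support
        W = cosine_affinity(S)
        assert W[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert W[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(W) == 0)

    def test_matches_normalized_dot_oracle(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((15, 15)) * (rng.random((15, 15)) < 0.3)
        S[(S != 0).sum(1) == 0, 0] = 1.0
        W = cosine_affinity(S)
        N = S / np.linalg.norm(S, axis=1, keepdims=True)
        expect = np.clip(N @ N.T, 0, None)
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(W, expect, atol=1e-12)

    def test_zero_row_raises_with_region(self):
        S = np.ones((4, 4))
        S[2] = 0.0
        with pytest.raises(ValueError, match="2"):
            cosine_affinity(S)


class TestDiffusionEmbedding:
    def test_uniform_complete_graph_degenerate(self):
        W = np.ones((10, 10)) - np.eye(10)
        gs = diffusion_embedding(W, k=3)
        assert np.all(np.abs(gs.gradients) < 1e-8)

    def test_two_cliques_separated_by_first_gradient(self):
        R = 12
        W = np.zeros((R, R))
        W[:6, :6] = 1.0
        W[6:, 6:] = 1.0
        np.fill_diagonal(W, 0.0)
        W[5, 6] = W[6, 5] = 0.01
        gs = diffusion_embedding(W, k=2)
        g1 = gs.gradients[:, 0]
        assert len(set(np.sign(g1[:6]))) == 1
        assert len(set(np.sign(g1[6:]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[-1])

    def test_matches_dense_nonsymmetric_eig_oracle(self):
        rng = np.random.default_rng(7)
        W = random_connected_affinity(12, rng)
        gs = diffusion_embedding(W, k=3)
        G_oracle, lam_oracle = dense_markov_oracle(W, k=3)
        assert np.allclose(gs.eigenvalues, lam_oracle, atol=1e-10)
        assert np.allclose(gs.gradients, G_oracle, atol=1e-8)

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(8)
        W = random_connected_affinity(15, rng)
        g1 = diffusion_embedding(W, k=3)
        g2 = diffusion_embedding(4.2 * W, k=3)
        assert np.allclose(g1.gradients, g2.gradients, atol=1e-9)

    def test_disconnected_graph_reports_components(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0.0)
        with pytest.raises(ValueError, match="component sizes"):
            diffusion_embedding(W, k=2)

    def test_eigenvalues_descending_in_unit_interval(self, small_msns):
        gs = mg.embed_msn(small_msns[0])
        lam = gs.eigenvalues
        assert np.all(lam > 0) and np.all(lam <= 1)
        assert np.all(np.diff(lam) <= 1e-12)


class TestTemplateAndAlignment:
    def test_template_of_one_equals_own_embedding(self, small_msns):
        tpl = mg.build_template([small_msns[0]])
        own = mg.embed_msn(small_msns[0])
        assert np.allclose(tpl.gradients, own.gradients, atol=1e-12)

    def test_template_mean_is_elementwise(self, small_msns):
        m1, m2 = small_msns[:2]
        dup = mg.build_template([m1, m1, m1])
        single = mg.build_template([m1])
        assert np.allclose(dup.gradients, single.gradients, atol=1e-12)
        mean = (m1.values + m2.values) / 2
        tpl = mg.build_template([m1, m2])
        direct = mg.embed_msn(mg.MSNMatrix(mean, list(m1.region_ids)))
        assert np.allclose(tpl.gradients, direct.gradients, atol=1e-12)

    def test_empty_template_raises(self):
        with pytest.raises(ValueError):
            mg.build_template([])

    def test_align_identity_and_signed_permutation(self, small_msns):
        tpl = mg.build_template(small_msns[:4])
        same = mg.align_gradients(tpl, tpl)
        assert np.allclose(same.gradients, tpl.gradients, atol=1e-12)
        scrambled = tpl.gradients[:, [1, 0, 2]] * np.array([-1.0, -1.0, 1.0])
        g = mg.GradientSet(scrambled, tpl.eigenvalues.copy())
        rec = mg.align_gradients(g, tpl)
        assert np.allclose(rec.gradients, tpl.gradients, atol=1e-10)

    def test_align_recovers_random_rotation(self):
        rng = np.random.default_rng(9)
        G = rng.standard_normal((40, 3))
        Q = random_rotation(3, rng)
        rotated = mg.GradientSet(G @ Q, np.array([0.5, 0.4, 0.3]))
        tpl = mg.GradientSet(G, np.array([0.5, 0.4, 0.3]))
        rec = mg.align_gradients(rotated, tpl)
        assert np.linalg.norm(rec.gradients - G) < 1e-8

    def test_alignment_is_isometric(self, small_msns):
        from scipy.spatial.distance import pdist

        tpl = mg.build_template(small_msns[:4])
        gs = mg.embed_msn(small_msns[5])
        aligned = mg.align_gradients(gs, tpl)
        assert np.allclose(pdist(gs.gradients), pdist(aligned.gradients), atol=1e-10)

    def test_shape_mismatch_raises(self, small_msns):
        tpl = mg.build_template(small_msns[:2])
        bad = mg.GradientSet(np.zeros((10, 3)), np.array([0.5, 0.4, 0.3]))
        with pytest.raises(ValueError):
            mg.align_gradients(bad, tpl)


def test_network_structure_recovered_in_gradient_space(partition150, small_msns):
    """Same-network regions cluster in 3-D gradient space (silhouette > 0)."""
    from sklearn.metrics import silhouette_score

    tpl = mg.build_template(small_msns)
    assert silhouette_score(tpl.gradients, partition150.labels) > 0
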