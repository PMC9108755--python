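import itertools

import numpy as np
import pytest

from psnvaria.netcompare import (ComparisonResult, SpectralDecomposition,
                                 correspondence_score, edge_difference_score,
                                 ewcs_score, fiedler_difference,
                                 laplacian_spectrum, nds)
from psnvaria.psn_core import PSNGraph

from conftest import random_psn


def _graph(weights, name="g"):
    w = np.asarray(weights, dtype=float)
    labels = tuple((i, str(i + 1), "ALA") for i in range(w.shape[0]))
    return PSNGraph(labels=labels, weights=w, source_id=name)


def _path3():
    return _graph([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


class TestLaplacianSpectrum:
    def test_path_graph_closed_form(self):
        # characteristic polynomial of L for the 3-path: l(l-1)(l-3)
        spec = laplacian_spectrum(_path3())
        np.testing.assert_allclose(spec.eigenvalues, [0.0, 1.0, 3.0], atol=1e-12)

    def test_empty_graph_all_zero(self):
        spec = laplacian_spectrum(_graph(np.zeros((4, 4))))
        np.testing.assert_allclose(spec.eigenvalues, 0.0, atol=1e-14)

    def test_eigenpairs_satisfy_definition(self):
        g = random_psn(25, seed=5)
        lap = np.diag(g.weights.sum(axis=1)) - g.weights
        spec = laplacian_spectrum(g)
        for m in range(g.n_nodes):
            v = spec.eigenvectors[:, m]
            assert np.linalg.norm(lap @ v - spec.eigenvalues[m] * v) < 1e-8

    def test_vectors_orthonormal_and_sign_fixed(self):
        spec = laplacian_spectrum(random_psn(20, seed=1))
        gram = spec.eigenvectors.T @ spec.eigenvectors
        np.testing.assert_allclose(gram, np.eye(20), atol=1e-8)
        for m in range(20):
            v = spec.eigenvectors[:, m]
            assert v[np.argmax(np.abs(v))] > 0


class TestEds:
    def test_identical_graphs(self):
        g = random_psn(10, seed=2)
        assert edge_difference_score(g, g) == 0.0

    def test_disjoint_support_is_one(self):
        a = np.zeros((4, 4))
        a[0, 2] = a[2, 0] = 0.8
        assert edge_difference_score(_graph(a), _graph(np.zeros((4, 4)))) == 1.0

    def test_both_empty_is_zero(self):
        z = _graph(np.zeros((5, 5)))
        assert edge_difference_score(z, z) == 0.0

    def test_single_edge_perturbation_matches_direct_sum(self):
        g = random_psn(8, seed=3, density=0.5)
        w2 = g.weights.copy()
        iu = np.triu_indices(8, k=2)
        nz = np.flatnonzero(g.weights[iu])
        i, j = iu[0][nz[0]], iu[1][nz[0]]
        w2[i, j] = w2[j, i] = w2[i, j] + 0.1
        h = _graph(w2)
        # direct summation oracle over the upper triangle
        num = den = 0.0
        for p in range(8):
            for q in range(p + 1, 8):
                num += abs(g.weights[p, q] - w2[p, q])
                den += max(g.weights[p, q], w2[p, q])
        assert edge_difference_score(g, h) == pytest.approx(num / den, abs=1e-14)

    def test_label_mismatch_rejected(self):
        g = random_psn(6, seed=0)
        other = PSNGraph(labels=tuple((i, str(i + 1), "GLY") for i in range(6)),
                         weights=g.weights)
        with pytest.raises(ValueError, match="labels"):
            edge_difference_score(g, other)


class TestEwcs:
    def test_identical_graphs_zero(self):
        g = random_psn(12, seed=4)
        assert ewcs_score(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_mode_contributes_full_weight(self):
        # same eigenvalues; second nontrivial eigenvector pair orthogonal
        g = _graph(np.zeros((4, 4)))
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        basis = np.eye(4)
        vecs_b = basis.copy()
        vecs_b[:, [2, 3]] = basis[:, [3, 2]]  # modes 2 and 3 swapped -> orthogonal
        sa = SpectralDecomposition(eigenvalues=vals, eigenvectors=basis)
        sb = SpectralDecomposition(eigenvalues=vals, eigenvectors=vecs_b)
        score = ewcs_score(g, g, spec_a=sa, spec_b=sb)
        # modes with lambda 2 and 3 are fully misaligned: (2+3)/(1+2+3)
        assert score == pytest.approx(5 / 6, abs=1e-12)

    def test_small_pair_matches_stepwise_recomputation(self):
        a = random_psn(5, seed=6, density=0.9)
        b = random_psn(5, seed=7, density=0.9)
        b = PSNGraph(labels=a.labels, weights=b.weights)
        # independent recomputation from the definition
        def spect(g):
            lap = np.diag(g.weights.sum(axis=1)) - g.weights
            vals, vecs = np.linalg.eigh(lap)
            for m in range(5):
                k = np.argmax(np.abs(vecs[:, m]))
                if vecs[k, m] < 0:
                    vecs[:, m] *= -1
            return vals, vecs

        la, va = spect(a)
        lb, vb = spect(b)
        num = den = 0.0
        for m in range(1, 5):
            wm = (la[m] + lb[m]) / 2
            cos = abs(float(va[:, m] @ vb[:, m]))
            num += wm * (1 - cos)
            den += wm
        assert ewcs_score(a, b) == pytest.approx(num / den, abs=1e-10)


class TestCrs:
    def test_identical_graphs_is_one(self):
        g = random_psn(15, seed=8)
        assert correspondence_score(g, g) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_assignment_is_minimum_cost_over_permutations(self, seed):
        # brute-force assignment oracle on n <= 7
        a = random_psn(6, seed=seed, density=0.8)
        b = random_psn(6, seed=seed + 50, density=0.8)
        b = PSNGraph(labels=a.labels, weights=b.weights)
        k = 3
        from psnvaria.netcompare import laplacian_spectrum as ls
        ea = ls(a).eigenvectors[:, 1:1 + k]
        eb = ls(b).eigenvectors[:, 1:1 + k]
        cost = np.linalg.norm(ea[:, None, :] - eb[None, :, :], axis=2)
        best, best_perm = np.inf, None
        for perm in itertools.permutations(range(6)):
            c = sum(cost[i, p] for i, p in enumerate(perm))
            if c < best - 1e-12:
                best, best_perm = c, perm
        expected = np.mean([i == p for i, p in enumerate(best_perm)])
        assert correspondence_score(a, b, k=k) == pytest.approx(expected)

    def test_unrelated_graphs_near_chance(self):
        scores = []
        for seed in range(20):
            a = random_psn(30, seed=1000 + seed, density=0.3)
            b = random_psn(30, seed=2000 + seed, density=0.3)
            b = PSNGraph(labels=a.labels, weights=b.weights)
            scores.append(correspondence_score(a, b))
        assert np.mean(scores) < 0.5


class TestNds:
    def test_identical_graphs_exactly_zero(self):
        g = random_psn(10, seed=9)
        r = nds(g, g)
        assert (r.eds, r.ewcs, r.crs, r.nds) == (0.0, 0.0, 1.0, 0.0)

    def test_composition_arithmetic(self):
        r = ComparisonResult(eds=0.1, ewcs=0.1, crs=0.9,
                             nds=np.sqrt(0.1 ** 2 + 0.1 ** 2 + 0.1 ** 2))
        assert r.nds == pytest.approx(0.1732, abs=1e-4)

    def test_symmetry_and_bounds(self, sidechain_psns):
        psns, _ = sidechain_psns
        r_ab = nds(psns[0], psns[1])
        r_ba = nds(psns[1], psns[0])
        assert r_ab.nds == pytest.approx(r_ba.nds, abs=1e-9)
        for r in (r_ab, r_ba):
            assert 0 <= r.eds <= 1 and 0 <= r.ewcs <= 1 and 0 <= r.crs <= 1
            assert 0 <= r.nds <= np.sqrt(3)

    def test_node_permutation_invariance(self):
        a = random_psn(12, seed=20, density=0.6)
        b = random_psn(12, seed=21, density=0.6)
        b = PSNGraph(labels=a.labels, weights=b.weights)
        base = nds(a, b)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        labels_p = tuple(a.labels[p] for p in perm)
        ap = PSNGraph(labels=labels_p, weights=a.weights[np.ix_(perm, perm)])
        bp = PSNGraph(labels=labels_p, weights=b.weights[np.ix_(perm, perm)])
        permuted = nds(ap, bp)
        assert permuted.eds == pytest.approx(base.eds, abs=1e-9)
        assert permuted.ewcs == pytest.approx(base.ewcs, abs=1e-9)
        assert permuted.crs == pytest.approx(base.crs, abs=1e-9)

    def test_single_edge_perturbation_vanishes_smoothly(self):
        g = random_psn(10, seed=30, density=0.6)
        iu = np.triu_indices(10, k=2)
        nz = np.flatnonzero(g.weights[iu])
        i, j = iu[0][nz[0]], iu[1][nz[0]]
        deltas = [0.2, 0.1, 0.05, 0.02, 0.01, 0.005]
        scores = []
        for d in deltas:
            w = g.weights.copy()
            w[i, j] = w[j, i] = w[i, j] + d
            scores.append(nds(g, _graph(w)).nds)
        assert all(s1 >= s2 - 1e-9 for s1, s2 in zip(scores, scores[1:]))
        assert scores[-1] < 0.05


class TestFiedlerDifference:
    def test_identical_graphs_all_zero(self):
        g = random_psn(10, seed=40)
        diff, ranked = fiedler_difference(g, g)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)
        assert len(ranked) == 10

    def test_path_end_edge_reweighting_matches_direct_recomputation(self):
        n = 8
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        g = _graph(w)
        w2 = w.copy()
        w2[0, 1] = w2[1, 0] = 0.3
        h = _graph(w2)
        diff, ranked = fiedler_difference(g, h, top_m=3)
        # direct oracle: eigh of both Laplacians, global-sign minimization
        def fied(weights):
            lap = np.diag(weights.sum(axis=1)) - weights
            vals, vecs = np.linalg.eigh(lap)
            return vecs[:, 1]

        fa, fb = fied(w), fied(w2)
        sign = 1.0 if float(fa @ fb) >= 0 else -1.0
        expected = np.abs(fa - sign * fb)
        np.testing.assert_allclose(diff, expected, atol=1e-8)
        order = np.argsort(-expected, kind="stable")
        assert [r[0] for r in ranked] == list(order[:3])

    def test_sign_invariance_of_ranking(self):
        a = random_psn(12, seed=50, density=0.5)
        b = random_psn(12, seed=51, density=0.5)
        b = PSNGraph(labels=a.labels, weights=b.weights)
        diff, _ = fiedler_difference(a, b)
        fa = laplacian_spectrum(a).fiedler
        fb = laplacian_spectrum(b).fiedler
        # the global sign choice minimizes the L2 distance between vectors
        assert np.linalg.norm(diff) <= np.linalg.norm(np.abs(fa - fb)) + 1e-12
        assert np.linalg.norm(diff) <= np.linalg.norm(np.abs(fa + fb)) + 1e-12
        sign = 1.0 if float(fa @ fb) >= 0 else -1.0
        np.testing.assert_allclose(diff, np.abs(fa - sign * fb), atol=1e-8)
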