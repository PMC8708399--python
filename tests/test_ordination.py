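"""Distances, Kruskal stress-1, NMDS, envfit and the PCA sanity check."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from phagedyn.ordination import (
    DistanceMatrix,
    NMDS,
    OrdinationResult,
    curve_distance_matrix,
    envfit_factor,
    envfit_vector,
    nmds,
    pca_variance,
    stress1,
)

from conftest import make_curve


def dm_from_points(pts):
    return DistanceMatrix(n=len(pts), d=pdist(pts))


class TestDistances:
    def test_identical_curves_distance_zero(self, grid):
        c = make_curve(0.3, grid)
        d = curve_distance_matrix([c, c, c])
        assert np.all(d.d == 0)

    def test_constant_offset_closed_form(self, grid):
        a = make_curve(0.3, grid)
        b = make_curve(0.4, grid)
        c = make_curve(0.3, grid)
        d = curve_distance_matrix([a, b, c]).square()
        assert d[0, 1] == pytest.approx(0.1 * np.sqrt(45), rel=1e-12)

    def test_matches_naive_double_loop(self, grid):
        rng = np.random.default_rng(0)
        curves = [make_curve(rng.uniform(0, 1, 45), grid) for _ in range(5)]
        got = curve_distance_matrix(curves).square()
        for i in range(5):
            for j in range(5):
                want = np.sqrt(np.sum((curves[i].od - curves[j].od) ** 2))
                assert got[i, j] == pytest.approx(want, abs=1e-12)


def brute_pava(y):
    """Independent pool-adjacent-violators: merge blocks until monotone."""
    blocks = [[v, 1.0] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            m0, w0 = blocks[i]
            m1, w1 = blocks[i + 1]
            blocks[i] = [(m0 * w0 + m1 * w1) / (w0 + w1), w0 + w1]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for m, w in blocks:
        out.extend([m] * int(w))
    return np.array(out)


class TestStress1:
    def test_perfect_rank_match_gives_zero(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1]])
        d = dm_from_points(pts)
        assert stress1(d, pts) == pytest.approx(0.0, abs=1e-12)

    def test_four_point_pava_oracle(self):
        # observed dissimilarities with one rank inversion relative to the
        # configuration distances
        pts = np.array([[0.0, 0], [1, 0], [2.5, 0], [5, 0]])
        dist = pdist(pts)
        d_obs = dist.copy()
        d_obs[0], d_obs[1] = d_obs[1], d_obs[0]   # swap two ranks
        d = DistanceMatrix(n=4, d=d_obs)
        order = np.lexsort((dist, d_obs))
        dhat = np.empty_like(dist)
        dhat[order] = brute_pava(dist[order])
        want = np.sqrt(np.sum((dist - dhat) ** 2) / np.sum(dist**2))
        assert stress1(d, pts) == pytest.approx(want, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 2))
        d = dm_from_points(rng.standard_normal((8, 3)))
        s1 = stress1(d, pts)
        for c in (0.1, 3.0, 100.0):
            assert stress1(d, c * pts) == pytest.approx(s1, abs=1e-12)

    def test_all_zero_configuration_errors(self):
        d = dm_from_points(np.random.default_rng(2).standard_normal((4, 2)))
        with pytest.raises(ValueError):
            stress1(d, np.zeros((4, 2)))


class TestNmds:
    def test_planar_points_embed_perfectly(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, (10, 2))
        res = nmds(dm_from_points(pts), k=2, n_restarts=4, seed=0)
        assert res.stress < 1e-4

    def test_equilateral_triangle_exact(self):
        d = DistanceMatrix(n=3, d=np.array([1.0, 1.0, 1.0]))
        res = nmds(d, k=2, n_restarts=4, seed=0, max_iter=500)
        assert res.stress < 1e-8
        rec = pdist(res.coords)
        assert np.ptp(rec) < 1e-6          # all pairs equal up to similarity

    def test_best_of_restarts_close_to_heavy_optimisation(self):
        """6 points in 5-D: best-of-20 restarts lands within 1e-3 of an
        independent heavy numerical optimisation over configurations."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(4)
        pts = rng.standard_normal((6, 5))
        d = dm_from_points(pts)
        res = nmds(d, k=2, n_restarts=20, seed=1, max_iter=500)

        def oracle_stress(flat):
            # independent stress-1: brute-force PAVA disparities
            dist = pdist(flat.reshape(6, 2))
            order = np.lexsort((dist, d.d))
            dhat = np.empty_like(dist)
            dhat[order] = brute_pava(dist[order])
            return np.sqrt(np.sum((dist - dhat) ** 2) / np.sum(dist**2))

        best = np.inf
        for s in range(30):
            x0 = np.random.default_rng(s).standard_normal(12)
            out = minimize(oracle_stress, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10})
            best = min(best, out.fun)
        assert res.stress <= best + 1e-3

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        d = dm_from_points(rng.standard_normal((12, 4)))
        a = nmds(d, k=2, n_restarts=5, seed=7)
        b = nmds(d, k=2, n_restarts=5, seed=7)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_coords_are_centred(self):
        rng = np.random.default_rng(6)
        d = dm_from_points(rng.standard_normal((9, 3)))
        res = nmds(d, k=2, n_restarts=3, seed=0)
        np.testing.assert_allclose(res.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(n=2, d=np.array([1.0]))
        with pytest.raises(ValueError):
            NMDS(d, k=2)


def fixed_ordination(coords):
    return OrdinationResult(coords=np.asarray(coords, float), stress=0.0,
                            n_restarts_used=1, seed=0, converged=True)


class TestEnvfit:
    def test_separated_blobs_maximal_r2_minimal_p(self):
        rng = np.random.default_rng(7)
        blob1 = rng.normal(0, 0.1, (20, 2))
        blob2 = rng.normal(8, 0.1, (20, 2)) * [1, -1]
        ordr = fixed_ordination(np.vstack([blob1, blob2]))
        labels = ["a"] * 20 + ["b"] * 20
        fit = envfit_factor(ordr, labels, n_perm=99, seed=0)
        assert fit.r_squared > 0.95
        assert fit.p_perm == pytest.approx(1 / 100)

    def test_null_rejection_rate_calibrated(self):
        """Random labels: permutation p approximately uniform, so the
        rejection rate at alpha=0.05 sits in [0.03, 0.07] over 500 sims."""
        rng = np.random.default_rng(8)
        coords = rng.standard_normal((30, 2))
        ordr = fixed_ordination(coords)
        hits = 0
        n_sims = 500
        for s in range(n_sims):
            labels = np.random.default_rng(1000 + s).integers(0, 3, 30)
            fit = envfit_factor(ordr, labels, n_perm=199, seed=s)
            hits += fit.p_perm <= 0.05
        assert 0.03 <= hits / n_sims <= 0.07

    def test_single_level_errors(self):
        ordr = fixed_ordination(np.random.default_rng(9).standard_normal((10, 2)))
        with pytest.raises(ValueError):
            envfit_factor(ordr, ["x"] * 10)

    def test_rotation_invariant_p(self):
        rng = np.random.default_rng(10)
        coords = rng.standard_normal((24, 2))
        labels = ["a", "b", "c"] * 8
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        f1 = envfit_factor(fixed_ordination(coords), labels, n_perm=199, seed=3)
        f2 = envfit_factor(fixed_ordination(coords @ rot), labels, n_perm=199, seed=3)
        assert f1.p_perm == f2.p_perm
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)

    def test_vector_along_first_axis(self):
        rng = np.random.default_rng(11)
        coords = rng.standard_normal((25, 2))
        fit = envfit_vector(fixed_ordination(coords), coords[:, 0], n_perm=99, seed=0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.arrow[0]) == pytest.approx(1.0, abs=1e-6)

    def test_vector_known_linear_combination(self):
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((25, 2))
        x = 2 * coords[:, 0] - coords[:, 1]
        fit = envfit_vector(fixed_ordination(coords), x, n_perm=99, seed=0)
        want = np.array([2.0, -1.0]) / np.sqrt(5)
        np.testing.assert_allclose(np.abs(fit.arrow), np.abs(want), atol=1e-6)

    def test_vector_independent_noise_near_zero_r2(self):
        rng = np.random.default_rng(13)
        coords = rng.standard_normal((200, 2))
        fit = envfit_vector(fixed_ordination(coords), rng.standard_normal(200),
                            n_perm=99, seed=0)
        assert fit.r_squared < 0.1

    def test_zero_variance_vector_errors(self):
        ordr = fixed_ordination(np.random.default_rng(14).standard_normal((10, 2)))
        with pytest.raises(ValueError, match="variance"):
            envfit_vector(ordr, np.ones(10))


class TestPca:
    def test_planar_curves_capture_everything(self, grid):
        rng = np.random.default_rng(15)
        base1, base2 = rng.uniform(0, 1, (2, 45))
        curves = [
            make_curve(0.3 + a * base1 + b * base2, grid)
            for a, b in rng.uniform(0, 1, (10, 2))
        ]
        res = pca_variance(curves, k=2)
        assert res.cumulative_fraction == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_noise_fraction_near_2_over_45(self, grid):
        rng = np.random.default_rng(16)
        curves = [make_curve(rng.standard_normal(45), grid, adjusted=False)
                  for _ in range(5000)]
        res = pca_variance(curves, k=2)
        assert res.cumulative_fraction == pytest.approx(2 / 45, abs=0.02)

    def test_eigenvalues_match_covariance_diagonalisation(self, grid):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 1, (12, 45))
        curves = [make_curve(row, grid) for row in X]
        res = pca_variance(curves, k=3)
        want = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(res.variances[:12], want[:12], atol=1e-10)

    def test_variances_non_increasing(self, grid):
        rng = np.random.default_rng(18)
        curves = [make_curve(rng.uniform(0, 1, 45), grid) for _ in range(8)]
        res = pca_variance(curves)
        assert np.all(np.diff(res.variances) <= 1e-12)
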