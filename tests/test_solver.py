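import numpy as np
import pytest
from scipy.optimize import minimize

from rssm import operators as op
from rssm.evaluation import pearson_correlation
from rssm.model import RSSMParams, lipschitz_bounds, objective
from rssm.solver import floor_threshold, pgd_step, solve, solve_ablation
from rssm.synthetic import SyntheticSpec, simulate_image


class TestFloorThreshold:
    def test_strict_below_zeroed_boundary_kept(self):
        out = floor_threshold(np.array([2.9, 3.0, 5.0]), 3.0)
        assert np.array_equal(out, [0.0, 3.0, 5.0])

    def test_zeros_fixed(self):
        assert np.all(floor_threshold(np.zeros((4, 4)), 3.0) == 0)

    def test_zero_threshold_identity_on_nonnegative(self, rng):
        V = np.maximum(rng.normal(size=(5, 5)), 0)
        assert np.array_equal(floor_threshold(V, 0.0), V)


class TestPgdStep:
    def test_origin_is_fixed_point(self):
        Z = np.zeros((6, 6))
        p = RSSMParams()
        Ls, LB = lipschitz_bounds(p)
        Is, B = pgd_step(Z, Z, Z, p, Ls, LB)
        assert np.all(Is == 0) and np.all(B == 0)

    def test_identity_above_floor_at_stationarity(self):
        # exact data fit, constant foreground above floor, no curvature
        Is = np.full((8, 8), 5.0)
        B = np.full((8, 8), 10.0)
        Y = Is + B
        p = RSSMParams()
        Ls, LB = lipschitz_bounds(p)
        Is2, _ = pgd_step(Y, Is, B, p, Ls, LB)
        assert np.allclose(Is2, Is)

    def test_first_step_reduces_objective_on_bright_pixel(self,
                                                          bright_pixel_image):
        from rssm.initializer import initialize
        Y = bright_pixel_image
        p = RSSMParams()
        Is, B = initialize(Y)
        Ls, LB = lipschitz_bounds(p)
        before = objective(Y, Is, B, p)
        Is2, B2 = pgd_step(Y, Is, B, p, Ls, LB)
        assert objective(Y, Is2, B2, p) < before


class TestSolve:
    def test_constant_image_all_background(self):
        Y = np.full((32, 32), 50.0)
        dec, rep = solve(Y)
        assert rep.converged
        assert np.all(dec.foreground == 0)
        assert np.allclose(dec.background, 50.0)

    def test_conservation_and_nonnegativity(self, rng):
        Y = rng.uniform(0, 40, size=(16, 16))
        dec, _ = solve(Y)
        assert np.all(dec.foreground >= 0)
        assert np.all(dec.background >= 0)
        # residual is defined as Y - Is - B, so the three components carry
        # the input exactly
        assert np.array_equal(dec.residual,
                              Y - dec.foreground - dec.background)
        assert np.allclose(Y, dec.foreground + dec.background + dec.residual,
                           rtol=0, atol=1e-10)

    def test_noiseless_rectangle_recovery(self):
        spec = SyntheticSpec(delta=15, mean_filter=1, noise_range=0,
                             n_images=1, seed=1)
        img, _, truth = simulate_image(spec, 0)
        dec, _ = solve(img)
        r = pearson_correlation(dec.foreground.ravel(), truth.ravel())
        assert r >= 0.9

    def test_deterministic(self, rng):
        Y = rng.uniform(0, 30, size=(12, 12))
        a, _ = solve(Y)
        b, _ = solve(Y)
        assert np.array_equal(a.foreground, b.foreground)
        assert np.array_equal(a.background, b.background)

    def test_trace_length_matches_iterations(self, rng):
        Y = rng.uniform(0, 30, size=(12, 12))
        _, rep = solve(Y)
        assert len(rep.objective_trace) == rep.iterations + 1
        assert rep.iterations <= RSSMParams().max_iter

    def test_rejects_empty_and_3d(self):
        with pytest.raises(ValueError):
            solve(np.zeros((0, 4)))
        with pytest.raises(ValueError):
            solve(np.zeros((2, 3, 3)))


class TestSoftProx:
    """The soft mode is the exact proximal map, so classical PGD theory
    applies: monotone descent and agreement with an independent solver."""

    def test_objective_trace_nonincreasing(self):
        p = RSSMParams(prox_mode="soft")
        for seed in range(10):
            Y = np.random.default_rng(seed).uniform(0, 20, size=(16, 16))
            _, rep = solve(Y, p)
            t = rep.objective_trace
            assert np.all(np.diff(t) <= 1e-9 * np.maximum(t[:-1], 1.0))

    # extents >= k1 + 1 so the background penalty is active; below that the
    # problem has a degenerate valley (B can absorb Y for free) along which
    # first-order methods creep sublinearly
    @pytest.mark.parametrize("shape", [(6, 6), (8, 8)])
    def test_matches_bound_constrained_oracle(self, shape, rng):
        """Under Is, B >= 0 the L1 term is linear, so the whole objective is
        smooth and L-BFGS-B solves it to high precision independently."""
        Y = rng.uniform(0, 12, size=shape)
        # the 1/LB = 1/901 background step makes convergence slow; a large
        # iteration budget is needed to reach the oracle's precision
        p = RSSMParams(prox_mode="soft", max_iter=25000, tol=1e-12)
        dec, _ = solve(Y, p)
        ours = objective(Y, dec.foreground, dec.background, p)

        n = Y.size

        def fun(z):
            Is = z[:n].reshape(shape)
            B = z[n:].reshape(shape)
            r = Y - Is - B
            f = (0.5 * np.sum(r * r) + p.lambda1 * Is.sum()
                 + 0.5 * p.lambda2 * op.smooth_penalty(Is, p.k0)
                 + 0.5 * p.lambda3 * op.smooth_penalty(B, p.k1))
            gI = (Is + B - Y + p.lambda1
                  + p.lambda2 * (op.gram_apply(Is, p.k0, 0)
                                 + op.gram_apply(Is, p.k0, 1)))
            gB = (Is + B - Y
                  + p.lambda3 * (op.gram_apply(B, p.k1, 0)
                                 + op.gram_apply(B, p.k1, 1)))
            return f, np.concatenate([gI.ravel(), gB.ravel()])

        res = minimize(fun, np.zeros(2 * n), jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * n),
                       options={"maxiter": 20000, "ftol": 1e-15,
                                "gtol": 1e-12})
        oracle = res.fun
        assert abs(ours - oracle) / max(abs(oracle), 1.0) < 1e-3


class TestAblation:
    def test_modes_return_valid_decompositions(self, rng):
        Y = rng.uniform(0, 30, size=(16, 16))
        for mode in ("no_sparse", "no_smooth"):
            dec, _ = solve_ablation(Y, mode=mode)
            assert np.all(dec.foreground >= 0)
            assert np.all(dec.background >= 0)
            assert np.array_equal(dec.residual,
                                  Y - dec.foreground - dec.background)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            solve_ablation(np.zeros((4, 4)), mode="no_everything")

    def test_no_sparse_keeps_noise_full_model_removes_it(self):
        """Without the sparsity/threshold step, background noise survives
        in the foreground estimate; the full model suppresses it."""
        spec = SyntheticSpec(delta=15, n_images=1, seed=7)
        img, mask, _ = simulate_image(spec, 0)
        full, _ = solve(img)
        nos, _ = solve_ablation(img, mode="no_sparse")
        fp_full = np.count_nonzero(full.foreground[~mask])
        fp_nos = np.count_nonzero(nos.foreground[~mask])
        assert fp_nos > fp_full

    def test_full_model_beats_ablations_at_moderate_contrast(self):
        """At delta=15 the combined model tracks the true profile better
        than either single-term variant (the two-term synergy)."""
        spec = SyntheticSpec(delta=15, n_images=2, seed=3)
        (r0, r1), _ = spec.rect
        row = (r0 + r1 - 1) // 2
        scores = {"full": [], "no_sparse": [], "no_smooth": []}
        for i in range(2):
            img, _, truth = simulate_image(spec, i)
            scores["full"].append(pearson_correlation(
                solve(img)[0].foreground[row], truth[row]))
            for mode in ("no_sparse", "no_smooth"):
                scores[mode].append(pearson_correlation(
                    solve_ablation(img, mode=mode)[0].foreground[row],
                    truth[row]))
        full = np.mean(scores["full"])
        assert full > np.mean(scores["no_sparse"])
        assert full > np.mean(scores["no_smooth"])
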