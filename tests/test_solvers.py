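"""Projection solvers: slab projection, AMS iterations, superiorization."""

import numpy as np
import pytest
from scipy import optimize

from letopt.solvers import (
    AMSParams,
    SuperiorizationParams,
    ams_iteration,
    ams_sweep,
    feasibility_seek,
    gradient_chi2,
    objective_chi2,
    project_interval_row,
    superiorize,
    weighted_residual,
)

from conftest import make_planted


class TestParameterDomains:
    @pytest.mark.parametrize("lam", [0.0, -0.5, 2.0001, 2.5])
    def test_relaxation_outside_unit_interval_of_two_rejected(self, lam):
        with pytest.raises(ValueError, match="0 < lambda <= 2"):
            AMSParams(relaxation=lam)

    def test_relaxation_boundary_two_accepted(self):
        assert AMSParams(relaxation=2.0).relaxation == 2.0

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.2])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            SuperiorizationParams(alpha=alpha)

    @pytest.mark.parametrize("eta", [0.0, 1.0, 2.0])
    def test_eta_domain(self, eta):
        with pytest.raises(ValueError, match="eta"):
            SuperiorizationParams(eta=eta)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            AMSParams(mode="parallel")


class TestProjectIntervalRow:
    def test_interior_point_unmoved(self):
        d = project_interval_row(np.array([0.5, 7.0]), np.array([1.0, 0.0]), 0.0, 1.0)
        np.testing.assert_array_equal(d, 0.0)

    def test_known_halfspace_projection(self):
        d = project_interval_row(np.array([1.0, 1.0]), np.array([1.0, 1.0]), -np.inf, 1.0)
        np.testing.assert_allclose(d, [-0.5, -0.5])

    def test_projection_lands_on_boundary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=4)
            x = rng.normal(size=4) * 5
            lo, hi = -1.0, 1.0
            d = project_interval_row(x, a, lo, hi)
            t = a @ (x + d)
            if a @ x > hi:
                assert t == pytest.approx(hi)
            elif a @ x < lo:
                assert t == pytest.approx(lo)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            project_interval_row(np.ones(3), np.zeros(3), 0.0, 1.0)


class TestAmsIteration:
    def test_feasible_point_is_fixed(self):
        sc, x_star, _ = make_planted(0)
        out = ams_iteration(x_star, sc, AMSParams())
        np.testing.assert_allclose(out, x_star)

    def test_single_constraint_reduces_to_exact_projection(self):
        sc, _, _ = make_planted(1, n_vox=1, n_beam=4)
        x = np.abs(np.random.default_rng(2).normal(size=4)) * 10
        stepped = ams_iteration(x, sc, AMSParams(relaxation=1.0))
        a = np.asarray(sc.A.todense()).ravel()
        d = project_interval_row(x, a, sc.lower[0], sc.upper[0])
        np.testing.assert_allclose(stepped, np.maximum(x + d, 0.0))

    @pytest.mark.parametrize("lam", [0.5, 1.0, 1.9])
    def test_fejer_monotone_towards_planted_point(self, lam):
        sc, x_star, x0 = make_planted(3)
        x = x0.copy()
        dist = np.linalg.norm(x - x_star)
        for _ in range(200):
            x = ams_iteration(x, sc, AMSParams(relaxation=lam))
            new = np.linalg.norm(x - x_star)
            assert new <= dist + 1e-12
            dist = new

    def test_no_constraints_rejected(self):
        sc, _, _ = make_planted(0)
        sc.A = sc.A[:0]
        with pytest.raises(ValueError, match="no constraints"):
            ams_iteration(np.ones(10), sc)


class TestCyclicSweep:
    def test_feasible_point_is_fixed(self):
        sc, x_star, _ = make_planted(4)
        np.testing.assert_allclose(ams_sweep(x_star, sc), x_star)

    def test_sweep_reduces_residual(self):
        sc, _, x0 = make_planted(5)
        r0 = weighted_residual(x0, sc)
        r1 = weighted_residual(ams_sweep(x0, sc), sc)
        assert r1 < r0


class TestFeasibilitySeek:
    def test_feasible_start_returns_unchanged_after_zero_iterations(self):
        sc, x_star, _ = make_planted(6)
        x, diag = feasibility_seek(x_star, sc)
        np.testing.assert_array_equal(x, x_star)
        assert diag["iterations"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_instances_converge(self, seed):
        sc, _, x0 = make_planted(seed)
        x, diag = feasibility_seek(x0, sc, AMSParams(max_iterations=500, tol=1e-7))
        assert diag["residual"] < 1e-6
        assert np.all(x >= 0)

    def test_inconsistent_system_terminates_quietly(self):
        sc, _, x0 = make_planted(7)
        # contradictory copies of row 0
        sc.lower[0], sc.upper[0] = 5.0, 6.0
        sc.lower[1], sc.upper[1] = 0.0, 0.1
        sc.A = sc.A.tolil()
        sc.A[1] = sc.A[0]
        sc.A = sc.A.tocsr()
        sc.row_norm_sq = np.asarray(sc.A.multiply(sc.A).sum(axis=1)).ravel()
        x, diag = feasibility_seek(x0, sc, AMSParams(max_iterations=50))
        assert diag["iterations"] == 50
        assert diag["residual"] > 0
        assert np.isfinite(diag["residuals"]).all()

    def test_negative_start_rejected(self):
        sc, _, _ = make_planted(8)
        with pytest.raises(ValueError, match="nonnegative"):
            feasibility_seek(-np.ones(10), sc)

    def test_residual_history_recorded_every_iteration(self):
        sc, _, x0 = make_planted(9)
        _, diag = feasibility_seek(x0, sc, AMSParams(max_iterations=30, tol=0.0))
        assert len(diag["residuals"]) == diag["iterations"] + 1


class TestObjective:
    def test_zero_when_references_met(self):
        sc, x_star, _ = make_planted(10)
        sc.reference = sc.A @ x_star
        assert objective_chi2(x_star, sc) == pytest.approx(0.0)
        np.testing.assert_allclose(gradient_chi2(x_star, sc), 0.0, atol=1e-12)

    def test_hand_computed_value(self):
        sc, _, _ = make_planted(11, n_vox=1, n_beam=1)
        sc.A.data[:] = 1.0
        sc.row_norm_sq[:] = 1.0
        sc.weight[:] = 2.0
        sc.reference[:] = 74.0
        assert objective_chi2(np.array([73.0]), sc) == pytest.approx(2.0)

    def test_linear_in_weights(self):
        sc, _, x0 = make_planted(12)
        assert objective_chi2(x0, sc, 2 * sc.weight) == pytest.approx(
            2 * objective_chi2(x0, sc)
        )

    def test_missing_reference_rejected(self):
        sc, _, x0 = make_planted(13)
        sc.reference[3] = np.nan
        with pytest.raises(ValueError, match="reference"):
            objective_chi2(x0, sc)
        with pytest.raises(ValueError, match="reference"):
            gradient_chi2(x0, sc)

    def test_gradient_matches_central_differences(self):
        sc, _, x0 = make_planted(14, n_vox=20, n_beam=3)
        g = gradient_chi2(x0, sc)
        fd = optimize.approx_fprime(x0, lambda y: objective_chi2(y, sc), 1e-6)
        assert np.abs(g - fd).max() / np.abs(g).max() < 1e-5

    def test_gradient_sign_flips_far_above_references(self):
        sc, x_star, _ = make_planted(15, n_vox=20, n_beam=3)
        below = gradient_chi2(0.0 * x_star, sc)
        above = gradient_chi2(100.0 * x_star, sc)
        assert np.all(below < 0)
        assert np.all(above > 0)


class TestSuperiorize:
    def test_vanishing_alpha_recovers_feasibility_seeking(self):
        sc, _, x0 = make_planted(16)
        ams = AMSParams(max_iterations=200)
        xa, _ = feasibility_seek(x0, sc, ams)
        xs, _ = superiorize(x0, sc, ams, SuperiorizationParams(alpha=1e-6))
        assert np.abs(xa - xs).max() < 1e-6

    def test_zero_gradient_everywhere_matches_feasibility_seeking(self):
        sc, x_star, _ = make_planted(17)
        sc.reference = sc.A @ x_star
        ams = AMSParams(max_iterations=50)
        xa, _ = feasibility_seek(x_star, sc, ams)
        xs, diag = superiorize(x_star, sc, ams, SuperiorizationParams())
        np.testing.assert_allclose(xa, xs)
        assert np.all(diag["betas"] == 0.0)

    def test_objective_non_inferior_over_seeds(self):
        wins = 0
        for seed in range(20):
            sc, _, x0 = make_planted(seed)
            ams = AMSParams(max_iterations=200)
            xa, _ = feasibility_seek(x0, sc, ams)
            xs, _ = superiorize(x0, sc, ams, SuperiorizationParams())
            wins += objective_chi2(xs, sc) <= objective_chi2(xa, sc)
        assert wins >= 19

    def test_perturbations_do_not_break_feasibility(self):
        """Perturbation resilience: the superiorized run ends within 10x of
        the plain feasibility-seeking residual on the same instance."""
        for seed in (0, 1, 2):
            sc, _, x0 = make_planted(seed)
            ams = AMSParams(max_iterations=200)
            _, da = feasibility_seek(x0, sc, ams)
            _, ds = superiorize(x0, sc, ams, SuperiorizationParams())
            assert ds["residual"] <= 10 * max(da["residual"], 1e-9)

    def test_chi2_trace_reported_at_original_weights(self):
        sc, _, x0 = make_planted(18)
        x, diag = superiorize(x0, sc, AMSParams(max_iterations=20), SuperiorizationParams())
        assert diag["chi2"][-1] == pytest.approx(objective_chi2(x, sc))

    def test_iterates_stay_nonnegative(self):
        sc, _, x0 = make_planted(19)
        x, _ = superiorize(x0, sc, AMSParams(max_iterations=100), SuperiorizationParams(alpha=0.9))
        assert np.all(x >= 0)


def test_slab_projection_matches_constrained_least_squares_oracle():
    """project_interval_row against a numerical QP oracle on random
    10-dimensional instances."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        a = rng.normal(size=10)
        while np.linalg.norm(a) < 1e-6:
            a = rng.normal(size=10)
        x = rng.normal(size=10) * 3
        lo = rng.normal()
        hi = lo + abs(rng.normal()) + 0.1
        d = project_interval_row(x, a, lo, hi)
        res = optimize.minimize(
            lambda y: 0.5 * np.sum((y - x) ** 2),
            x,
            jac=lambda y: y - x,
            constraints=[
                {"type": "ineq", "fun": lambda y: a @ y - lo, "jac": lambda y: a},
                {"type": "ineq", "fun": lambda y: hi - a @ y, "jac": lambda y: -a},
            ],
            method="SLSQP",
            options={"ftol": 1e-16, "maxiter": 200},
        )
        assert np.abs(x + d - res.x).max() < 1e-8
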