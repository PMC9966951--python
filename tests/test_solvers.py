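import numpy as np
import pytest
import scipy.special

from connreg import (
    RegularizedSoftmax,
    RegularizerSpec,
    SolverOptions,
    apply_as_layer,
    energy,
    entropic_softmax,
    lambert_w,
    solve_fixed_point,
    solve_pfb,
    subgradient_p,
    std_term,
    connectivity_term,
)
from connreg.solvers import pfb_step

from conftest import brute_force_inner_product


class TestEntropicSoftmax:
    def test_symmetric_scores_give_uniform(self):
        o = np.zeros((3, 3, 2))
        assert np.allclose(entropic_softmax(o, 1.0), 0.5)

    def test_two_class_closed_form(self):
        o = np.zeros((1, 1, 2))
        o[0, 0] = [1.0, 0.0]
        u = entropic_softmax(o, 1.0)[0, 0]
        e = np.e
        assert u[0] == pytest.approx(e / (e + 1.0), abs=1e-12)
        assert u[0] == pytest.approx(0.73106, abs=5e-6)

    def test_small_epsilon_approaches_argmax(self):
        o = np.zeros((1, 1, 2))
        o[0, 0] = [1.0, 0.0]
        u = entropic_softmax(o, 1e-3)[0, 0]
        assert abs(u[0] - 1.0) < 1e-9 and abs(u[1]) < 1e-9

    def test_overflow_safety(self):
        o = np.zeros((1, 1, 2))
        o[0, 0] = [2000.0, -2000.0]
        u = entropic_softmax(o, 1.0)
        assert np.all(np.isfinite(u))
        assert np.allclose(u.sum(axis=2), 1.0)


class TestLambertW:
    def test_fixed_points(self):
        assert float(lambert_w(0.0)) == 0.0
        assert float(lambert_w(np.e)) == pytest.approx(1.0, abs=1e-12)

    def test_newton_oracle_at_one(self):
        # independent Newton solve of w e^w = 1
        w = 0.5
        for _ in range(50):
            w -= (w * np.exp(w) - 1.0) / (np.exp(w) * (1.0 + w))
        assert float(lambert_w(1.0)) == pytest.approx(w, abs=1e-12)
        assert float(lambert_w(1.0)) == pytest.approx(0.567143, abs=1e-6)

    def test_defining_identity_over_wide_range(self):
        x = np.concatenate(([0.0], np.logspace(-6, 6, 999)))
        w = lambert_w(x)
        resid = np.abs(w * np.exp(w) - x.astype(np.longdouble))
        assert float(resid.max()) < 1e-10

    def test_matches_scipy_principal_branch(self):
        x = np.logspace(-3, 4, 50)
        w = np.asarray(lambert_w(x), dtype=float)
        ref = scipy.special.lambertw(x).real
        assert np.allclose(w, ref, rtol=1e-12, atol=1e-13)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lambert_w(-0.5)


class TestSubgradient:
    def test_zero_weights_give_zero(self, rng):
        u = entropic_softmax(rng.normal(size=(5, 5, 3)), 1.0)
        assert np.all(subgradient_p(u, RegularizerSpec()) == 0)

    def test_half_field_annihilates_std_part(self):
        u = np.full((6, 6, 2), 0.5)
        p = subgradient_p(u, RegularizerSpec(lambda_std=1.0))
        assert np.allclose(p, 0.0, atol=1e-14)

    def test_matches_term_by_term_stencil_oracle(self, rng):
        u = entropic_softmax(rng.normal(size=(6, 6, 2)), 1.0)
        spec = RegularizerSpec(lambda_std=0.3, lambda_dir=(0.1, 0.05, 0.2, 0.07))
        p = subgradient_p(u, spec)
        from connreg import convolve

        for c in range(2):
            expected = spec.lambda_std * convolve(1.0 - 2.0 * u[:, :, c], spec.gaussian)
            if c in spec.fg_channels(2):
                for lam, kern in zip(spec.lambda_dir, spec.directional):
                    expected += lam * convolve(-2.0 * u[:, :, c], kern)
            assert np.allclose(p[:, :, c], expected, atol=1e-12)


class TestEnergy:
    def test_uniform_field_closed_form(self):
        o = np.zeros((4, 5, 3))
        u = np.full((4, 5, 3), 1.0 / 3.0)
        spec = RegularizerSpec(epsilon=2.0)
        assert energy(o, u, spec) == pytest.approx(2.0 * 20 * np.log(1.0 / 3.0), abs=1e-10)

    def test_softmax_minimizes_unregularized_energy(self, rng):
        o = rng.normal(size=(4, 4, 2))
        spec = RegularizerSpec(epsilon=0.7)
        u_star = entropic_softmax(o, 0.7)
        e_star = energy(o, u_star, spec)
        for _ in range(20):
            v = rng.random((4, 4, 2))
            v /= v.sum(axis=2, keepdims=True)
            assert energy(o, v, spec) >= e_star - 1e-12

    def test_matches_kernel_module_terms(self, rng):
        o = rng.normal(size=(6, 6, 2))
        u = entropic_softmax(o, 1.0)
        spec = RegularizerSpec(lambda_std=0.2, lambda_dir=(0.1, 0.0, 0.0, 0.05))
        ent = float(np.sum(u * np.log(u)))
        expected = float(np.sum(-o * u)) + spec.epsilon * ent
        expected += spec.lambda_std * std_term(u, spec.gaussian)
        expected += spec.lambda_dir[0] * connectivity_term(u, spec.directional[0], (1,))
        expected += spec.lambda_dir[3] * connectivity_term(u, spec.directional[3], (1,))
        assert energy(o, u, spec) == pytest.approx(expected, abs=1e-10)


class TestSolvers:
    def test_unregularized_fixed_point_returns_softmax_immediately(self, rng):
        o = rng.normal(size=(8, 8, 2))
        u, trace = solve_fixed_point(o, RegularizerSpec())
        assert trace.iterations == 1 and trace.converged
        assert trace.residuals[0] == 0.0
        assert np.allclose(u, entropic_softmax(o, 1.0), atol=1e-15)

    @pytest.mark.parametrize("solver", [solve_fixed_point, solve_pfb])
    def test_reduction_to_softmax(self, rng, solver):
        for _ in range(20):
            o = rng.normal(size=(16, 16, 2)) * 2.0
            u, trace = solver(o, RegularizerSpec())
            assert trace.converged
            assert np.max(np.abs(u - entropic_softmax(o, 1.0))) < 1e-6

    def test_huge_epsilon_gives_uniform(self, rng):
        o = rng.normal(size=(6, 6, 3))
        u, _ = solve_fixed_point(o, RegularizerSpec(epsilon=1e6, lambda_std=0.1))
        assert np.allclose(u, 1.0 / 3.0, atol=1e-6)

    def test_convergence_within_ten_iterations_on_fixture(self, line_features, std_spec):
        u_fp, tr_fp = solve_fixed_point(line_features, std_spec)
        u_pf, tr_pf = solve_pfb(line_features, std_spec)
        assert tr_fp.converged and tr_fp.iterations <= 10
        assert tr_pf.converged and tr_pf.iterations <= 10

    def test_simplex_feasibility(self, line_features, std_spec):
        for solver in (solve_fixed_point, solve_pfb):
            u, _ = solver(line_features, std_spec)
            assert u.min() >= 0 and u.max() <= 1
            assert np.max(np.abs(u.sum(axis=2) - 1.0)) < 1e-9

    def test_solver_agreement(self, line_features):
        spec = RegularizerSpec(lambda_std=0.1, lambda_dir=(0.05, 0.05, 0.02, 0.0))
        u1, _ = solve_fixed_point(line_features, spec, SolverOptions(tol=1e-10, max_iter=300))
        u2, _ = solve_pfb(
            line_features, spec, SolverOptions(method="pfb", tol=1e-10, max_iter=300)
        )
        assert np.max(np.abs(u1 - u2)) < 1e-4

    def test_energy_descent_gaussian_only(self, rng):
        for _ in range(20):
            o = rng.normal(size=(10, 10, 2)) * 1.5
            spec = RegularizerSpec(lambda_std=float(rng.uniform(0.01, 0.5)))
            _, trace = solve_fixed_point(o, spec)
            diffs = np.diff(trace.energies)
            assert np.all(diffs <= 1e-10)

    def test_pfb_preprojection_output_strictly_positive(self, line_features, std_spec):
        u0 = np.exp(line_features / std_spec.epsilon - 1.0)
        raw = pfb_step(line_features, u0, std_spec, tau=0.1)
        assert np.all(raw > 0)

    def test_nonconvergence_reported_not_raised(self, line_features, std_spec):
        u, trace = solve_fixed_point(
            line_features, std_spec, SolverOptions(max_iter=1, tol=1e-14)
        )
        assert not trace.converged and trace.iterations == 1

    def test_foreground_expansion_monotone_in_directional_weights(self, line_features):
        counts = []
        for lam in (0.0, 0.05, 0.1):
            spec = RegularizerSpec(lambda_std=0.1, lambda_dir=(lam, lam, lam, lam))
            u, trace = solve_fixed_point(line_features, spec)
            assert trace.converged
            counts.append(int(np.sum(u[:, :, 1] >= 0.5)))
        assert counts[0] <= counts[1] <= counts[2]


class TestApplyAsLayer:
    def test_single_unroll_no_regularization_is_softmax(self, rng):
        o = rng.normal(size=(5, 5, 2))
        u = apply_as_layer(o, RegularizerSpec(), unroll=1)
        assert np.allclose(u, entropic_softmax(o, 1.0), atol=1e-15)

    def test_matches_fixed_point_truncated_at_same_depth(self, line_features, std_spec):
        k = 3
        u_layer = apply_as_layer(line_features, std_spec, unroll=k)
        u_solver, _ = solve_fixed_point(
            line_features, std_spec, SolverOptions(max_iter=k, tol=1e-300)
        )
        assert np.array_equal(u_layer, u_solver)

    def test_deep_unroll_reaches_converged_solution(self, line_features, std_spec):
        u_layer = apply_as_layer(line_features, std_spec, unroll=10)
        u_conv, trace = solve_fixed_point(line_features, std_spec)
        assert trace.converged
        assert np.max(np.abs(u_layer - u_conv)) < 1e-6


class TestModelAPI:
    def test_fit_returns_results_with_summary(self, line_features):
        res = RegularizedSoftmax(line_features, lambda_std=0.1).fit()
        assert res.converged
        assert res.probabilities.shape == line_features.shape
        text = res.summary()
        assert "iterations" in text and "lambda_std" in text
        assert res.mask().dtype == bool

    def test_spec_kwargs_and_object_are_exclusive(self, line_features):
        with pytest.raises(ValueError):
            RegularizedSoftmax(line_features, RegularizerSpec(), lambda_std=0.1)

    def test_config_round_trip(self):
        spec = RegularizerSpec(lambda_std=0.2, lambda_dir=(0.1, 0.0, 0.3, 0.0), epsilon=0.5)
        spec2 = RegularizerSpec.from_config(spec.to_config())
        assert spec2.to_config() == spec.to_config()
        opts = SolverOptions(method="pfb", tau=0.25, max_iter=7)
        assert SolverOptions.from_config(opts.to_config()) == opts
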