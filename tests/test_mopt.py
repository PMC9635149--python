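"""Multi-objective machinery: preferences, standardization, min-norm, trainers."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpareto.mopt import (
    StandardizationBounds,
    TrainConfig,
    active_set,
    apply_update,
    constraint_values,
    evaluate_candidate,
    min_norm_init,
    min_norm_main,
    min_norm_point,
    pareto_mtl_minimize,
    preference_vectors,
    record_bounds,
    scalarization_minimize,
    scalarized_loss,
    standardize,
    train_candidate,
    train_extremes,
)
from scpareto.nn import SGD, Tensor
from scpareto.vae import compute_library_prior


class TestPreferenceVectors:
    def test_endpoints_and_unit_norm(self):
        prefs = preference_vectors(10)
        np.testing.assert_allclose(prefs[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(prefs[-1], [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(prefs, axis=1), 1.0)

    def test_k3_midpoint(self):
        np.testing.assert_allclose(preference_vectors(3)[1],
                                   [np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_angles_strictly_increasing(self):
        prefs = preference_vectors(7)
        angles = np.arctan2(prefs[:, 1], prefs[:, 0])
        assert np.all(np.diff(angles) > 0)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            preference_vectors(1)


class TestStandardization:
    @pytest.mark.parametrize("value,lo,hi,expected",
                             [(2.0, 2.0, 5.0, 0.0), (5.0, 2.0, 5.0, 1.0),
                              (4.25, 2.0, 5.0, 0.75), (6.5, 2.0, 5.0, 1.5)])
    def test_linear_map_not_clamped(self, value, lo, hi, expected):
        assert standardize(value, lo, hi) == pytest.approx(expected)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            standardize(1.0, 3.0, 3.0)
        with pytest.raises(ValueError):
            StandardizationBounds(U_min=1.0, U_max=1.0, V_min=0.0, V_max=1.0)


class TestConstraintsAndActiveSet:
    def test_own_index_zero_and_origin_all_zero(self):
        prefs = preference_vectors(4)
        g = constraint_values(np.array([0.3, 0.8]), 2, prefs)
        assert g[2] == pytest.approx(0.0)
        np.testing.assert_allclose(
            constraint_values(np.zeros(2), 1, prefs), 0.0)

    def test_k2_symmetric_point(self):
        prefs = np.array([[1.0, 0.0], [0.0, 1.0]])
        g = constraint_values(np.array([1.0, 1.0]), 0, prefs)
        np.testing.assert_allclose(g, [0.0, 0.0], atol=1e-12)

    def test_threshold_scan(self):
        g = np.array([-0.2, 0.0, 0.3])
        np.testing.assert_array_equal(active_set(g, 0.1), [1, 2])
        np.testing.assert_array_equal(active_set(g, np.inf), [0, 1, 2])

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            active_set(np.zeros(3), 0.0)


class TestMinNorm:
    def test_single_vector(self):
        sol = min_norm_point([np.array([2.0, -1.0])])
        assert sol.coeffs == pytest.approx([1.0])
        np.testing.assert_allclose(sol.d, [2.0, -1.0])

    def test_opposite_vectors_cancel(self):
        g = np.array([1.0, 3.0])
        sol = min_norm_point([g, -g])
        np.testing.assert_allclose(sol.coeffs, [0.5, 0.5])
        np.testing.assert_allclose(sol.d, 0.0, atol=1e-12)

    def test_two_vector_analytic_case(self):
        sol = min_norm_point([np.array([1.0, 0.0]), np.array([0.0, 2.0])])
        np.testing.assert_allclose(sol.coeffs, [0.8, 0.2])
        assert sol.norm_sq == pytest.approx(0.8)

    def test_matches_simplex_grid_oracle(self):
        """Exact solver vs exhaustive simplex grid on random 3-vector sets."""
        rng = np.random.default_rng(0)
        step = 1e-3
        a1, a2 = np.meshgrid(np.arange(0, 1 + step, step),
                             np.arange(0, 1 + step, step))
        keep = a1 + a2 <= 1.0 + 1e-12
        a1, a2 = a1[keep], a2[keep]
        a3 = 1.0 - a1 - a2
        for _ in range(100):
            V = rng.standard_normal((3, 2))
            d = (a1[:, None] * V[0] + a2[:, None] * V[1] + a3[:, None] * V[2])
            oracle = float(np.min(np.einsum("ij,ij->i", d, d)))
            sol = min_norm_point(list(V))
            assert abs(sol.norm_sq - oracle) < 1e-4

    def test_init_excludes_zero_gradients(self):
        sol = min_norm_init([np.zeros(3), np.array([1.0, 0.0, 0.0])])
        np.testing.assert_allclose(sol.d, [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            min_norm_init([])

    def test_main_reduces_to_mgda_without_constraints(self):
        gu, gv = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        sol = min_norm_main(gu, gv, [np.zeros(2)])
        assert sol.coeffs[0] == pytest.approx(0.8)
        assert sol.coeffs[1] == pytest.approx(0.2)

    def test_main_identical_objectives(self):
        v = np.array([0.3, -0.7])
        sol = min_norm_main(v, v, [])
        np.testing.assert_allclose(sol.d, v)

    def test_main_all_zero_is_stationary(self):
        sol = min_norm_main(np.zeros(4), np.zeros(4), [np.zeros(4)])
        assert sol.converged and np.all(sol.d == 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=6), st.integers(0, 10_000))
    def test_direction_is_convex_combination(self, m, seed):
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((m, 4))
        sol = min_norm_point(list(V))
        assert sol.coeffs.min() >= -1e-12
        assert sol.coeffs.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(sol.d, sol.coeffs @ V, atol=1e-10)


class TestApplyUpdateAndScalarization:
    def test_plain_sgd_exact_and_reversible(self):
        p = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        opt = SGD([p], lr=0.1)
        d = np.array([0.5, -0.5])
        apply_update([p], d, opt)
        np.testing.assert_allclose(p.data, [0.95, 2.05])
        apply_update([p], -d, opt)
        np.testing.assert_allclose(p.data, [1.0, 2.0])
        apply_update([p], np.zeros(2), opt)
        np.testing.assert_allclose(p.data, [1.0, 2.0])

    def test_non_finite_direction_rejected(self):
        p = Tensor(np.zeros(2), requires_grad=True)
        with pytest.raises(FloatingPointError):
            apply_update([p], np.array([np.nan, 0.0]), SGD([p], lr=0.1))

    @pytest.mark.parametrize("lam,expected", [(1.0, 0.5), (0.0, 0.2),
                                              (1 / 11, 0.5 / 11 + 2 / 11)])
    def test_scalarized_loss(self, lam, expected):
        assert scalarized_loss(0.5, 0.2, lam) == pytest.approx(expected)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scalarized_loss(0.5, 0.2, 1.5)


def _quadratic_toy(w):
    L = np.array([(w[0] - 1) ** 2 + w[1] ** 2, w[0] ** 2 + (w[1] - 1) ** 2])
    J = np.array([[2 * (w[0] - 1), 2 * w[1]], [2 * w[0], 2 * (w[1] - 1)]])
    return L, J


class TestAnalyticToy:
    def test_candidates_reach_their_sectors(self):
        K = 5
        prefs = preference_vectors(K)
        for k in range(K):
            w = pareto_mtl_minimize(_quadratic_toy, np.array([0.5, 0.5]), k, K,
                                    steps=400, lr=0.05, init_steps=40)
            L, _ = _quadratic_toy(w)
            g = constraint_values(L, k, prefs)
            assert g.max() <= 1e-3          # inside the preference sector
            assert abs(w.sum() - 1.0) < 0.02  # on the analytic front ω1+ω2=1

    @pytest.mark.parametrize("lam", [0.2, 0.5, 0.9])
    def test_scalarization_closed_form_minimizer(self, lam):
        w = scalarization_minimize(_quadratic_toy, np.zeros(2), lam,
                                   steps=3000, lr=0.05)
        np.testing.assert_allclose(w, [lam, 1 - lam], atol=1e-6)


class TestTrainers:
    def test_bounds_are_trace_extrema_and_models_returned(
            self, small_dataset, tiny_train_config):
        ds, _ = small_dataset
        bounds, u_vae, (v_vae, v_mine) = record_bounds(ds, tiny_train_config)
        assert bounds.U_max > bounds.U_min
        assert bounds.V_max > bounds.V_min
        assert v_mine is not None

    def test_candidate_trace_deterministic(self, small_dataset,
                                           tiny_train_config):
        ds, _ = small_dataset
        bounds = StandardizationBounds(U_min=50.0, U_max=150.0,
                                       V_min=-0.05, V_max=0.3)
        runs = [train_candidate(ds, tiny_train_config, bounds,
                                method="pareto_mtl", k=1) for _ in range(2)]
        t0 = np.array([r[1:] for r in runs[0].trace])
        t1 = np.array([r[1:] for r in runs[1].trace])
        np.testing.assert_array_equal(t0, t1)

    def test_scalarization_candidate_trains(self, small_dataset,
                                            tiny_train_config):
        ds, _ = small_dataset
        bounds = StandardizationBounds(U_min=50.0, U_max=150.0,
                                       V_min=-0.05, V_max=0.3)
        cand = train_candidate(ds, tiny_train_config, bounds,
                               method="scalarization", lam=0.5)
        assert len(cand.trace) > 0

    def test_v_extreme_encoder_frozen_during_decoder_fit(
            self, small_dataset, tiny_train_config):
        ds, _ = small_dataset
        prior = compute_library_prior(ds)
        _, u_vae, (v_vae, v_mine) = record_bounds(ds, tiny_train_config,
                                                  prior=prior)
        phi_before = [p.data.copy() for p in v_vae.encoder_parameters()]
        _, v_ext = train_extremes(ds, tiny_train_config, prior=prior,
                                  pretrained=(u_vae, (v_vae, v_mine)))
        for before, p in zip(phi_before, v_ext.vae.encoder_parameters()):
            np.testing.assert_array_equal(before, p.data)

    def test_evaluation_never_mutates_weights(self, small_dataset,
                                              tiny_train_config):
        ds, _ = small_dataset
        prior = compute_library_prior(ds)
        bounds, u_vae, _ = record_bounds(ds, tiny_train_config, prior=prior)
        from scpareto.mopt import ParetoCandidate

        cand = ParetoCandidate(tag="U_extreme", vae=u_vae, mine=None,
                               trace=[(0,)])
        before = [p.data.copy() for p in u_vae.parameters()]
        evaluate_candidate(cand, ds, tiny_train_config, bounds, prior,
                           split="train", seed=1)
        for b, p in zip(before, u_vae.parameters()):
            np.testing.assert_array_equal(b, p.data)
        assert "train" in cand.raw and "train" in cand.standardized
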