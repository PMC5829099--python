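"""Inverse transformation from opponent responses to perceived planes."""

import numpy as np
import pytest

from lcacomp import (AdaptedCones, OpponentMaps, RFGeometry, SolverSettings,
                     initialize, recover_s, residual_error, solve_perceived,
                     solve_perceived_direct, solve_perceived_iterative,
                     solve_perceived_spectral)
from lcacomp._conv import conv2_reflect
from lcacomp.inverse import surround_matrix
from conftest import conv_reflect_loop, reflect


def forward_opponent(L_per, M_per, geom, s_map=None):
    """Push perceived planes through the defining equations (forward)."""
    fs = geom.surround_kernel()
    shape = L_per.shape
    return OpponentMaps(
        LplusM=L_per - conv2_reflect(M_per, fs),
        MplusL=M_per - conv2_reflect(L_per, fs),
        SplusLM=np.zeros(shape) if s_map is None else s_map,
    )


class TestInitialize:
    def test_hand_value(self):
        adapted = AdaptedCones(np.full((3, 3), 0.4), np.full((3, 3), 0.2),
                               np.full((3, 3), 0.9))
        L0, M0, S0 = initialize(adapted)
        for plane in (L0, M0, S0):
            assert np.allclose(plane, 0.3, atol=1e-15)

    def test_achromatic_input_initializes_to_itself(self, rng):
        plane = rng.random((8, 8))
        adapted = AdaptedCones(plane, plane.copy(), plane.copy())
        L0, M0, S0 = initialize(adapted)
        assert np.array_equal(L0, plane)
        assert np.array_equal(L0, M0) and np.array_equal(M0, S0)


class TestResidualError:
    def test_zero_at_defining_fixed_point(self, rng, geom):
        L = rng.random((12, 12))
        M = rng.random((12, 12))
        opp = forward_opponent(L, M, geom)
        assert np.max(residual_error(L, M, opp, geom)) < 1e-24

    def test_symmetric_under_joint_relabeling(self, rng, geom):
        L, M = rng.random((10, 10)), rng.random((10, 10))
        opp = forward_opponent(rng.random((10, 10)), rng.random((10, 10)), geom)
        e1 = residual_error(L, M, opp, geom)
        swapped = OpponentMaps(opp.MplusL, opp.LplusM, opp.SplusLM)
        e2 = residual_error(M, L, swapped, geom)
        assert np.allclose(e1, e2, atol=1e-12)

    def test_matches_nested_loop_reference(self, rng, geom):
        L, M = rng.random((8, 8)), rng.random((8, 8))
        opp = forward_opponent(rng.random((8, 8)), rng.random((8, 8)), geom)
        fs = geom.surround_kernel()
        r1 = L - conv_reflect_loop(M, fs) - opp.LplusM
        r2 = M - conv_reflect_loop(L, fs) - opp.MplusL
        assert np.allclose(residual_error(L, M, opp, geom), r1 ** 2 + r2 ** 2,
                           atol=1e-12)


class TestDirectSolver:
    def test_surround_matrix_equals_kernel_taps(self, geom):
        # matrix-vector product must equal reflective convolution
        h = w = 8
        kern = geom.surround_kernel()
        K = surround_matrix(kern, (h, w))
        rng = np.random.default_rng(7)
        v = rng.random((h, w))
        assert np.allclose((K @ v.ravel()).reshape(h, w),
                           conv_reflect_loop(v, kern), atol=1e-12)
        # spot-check single taps against hand reflection
        row = K.getrow(0).toarray().ravel()
        acc = np.zeros((h, w))
        rh = kern.shape[0] // 2
        for a in range(kern.shape[0]):
            for b in range(kern.shape[1]):
                acc[reflect(a - rh, h), reflect(b - rh, w)] += kern[a, b]
        assert np.allclose(row.reshape(h, w), acc, atol=1e-14)

    def test_forward_then_invert_recovers_input(self, rng, geom):
        L, M = rng.random((12, 12)), rng.random((12, 12))
        opp = forward_opponent(L, M, geom)
        sol = solve_perceived_direct(opp, geom)
        c = np.mean(sol.L_per - L)  # free constant achromatic mode
        assert np.max(np.abs(sol.L_per - L - c)) < 1e-8
        assert np.max(np.abs(sol.M_per - M - c)) < 1e-8
        assert sol.final_error < 1e-12

    def test_zero_maps_give_constant_solution(self, geom):
        opp = OpponentMaps(*[np.zeros((8, 8))] * 3)
        sol = solve_perceived_direct(opp, geom)
        assert sol.final_error < 1e-12
        assert np.max(np.abs(sol.L_per - sol.L_per.mean())) < 1e-6
        # with ridge regularization the minimum-norm solution is ~0
        assert np.abs(sol.L_per).max() < 1e-6


class TestSpectralSolver:
    def test_agrees_with_direct(self, rng, geom):
        opp = forward_opponent(rng.random((16, 16)), rng.random((16, 16)), geom)
        direct = solve_perceived_direct(opp, geom, anchor=0.5)
        spectral = solve_perceived_spectral(opp, geom, anchor=0.5)
        assert np.max(np.abs(direct.L_per - spectral.L_per)) < 1e-6
        assert np.max(np.abs(direct.M_per - spectral.M_per)) < 1e-6

    def test_exact_on_realizable_maps(self, rng, geom):
        L, M = rng.random((20, 20)), rng.random((20, 20))
        opp = forward_opponent(L, M, geom)
        sol = solve_perceived_spectral(opp, geom,
                                       anchor=0.5 * (L.mean() + M.mean()))
        assert sol.final_error < 1e-20
        c = np.mean(sol.L_per - L)
        assert np.max(np.abs(sol.L_per - L - c)) < 1e-10


class TestIterativeSolver:
    @pytest.mark.parametrize("scheme", ["jacobi", "gradient"])
    def test_matches_direct_solver(self, rng, geom, scheme, tight_settings):
        L, M = rng.random((16, 16)), rng.random((16, 16))
        opp = forward_opponent(L, M, geom)
        init = (0.5 * (L + M), 0.5 * (L + M), 0.5 * (L + M))
        anchor = float(np.mean(init[0]))
        itsol = solve_perceived_iterative(opp, init, geom, tight_settings,
                                          scheme=scheme)
        direct = solve_perceived_direct(opp, geom, anchor=anchor)
        assert itsol.converged
        assert np.max(np.abs(itsol.L_per - direct.L_per)) < 1e-4
        assert np.max(np.abs(itsol.M_per - direct.M_per)) < 1e-4

    def test_zero_maps_with_achromatic_init_converges_immediately(self, geom):
        u = np.full((12, 12), 0.4)
        opp = OpponentMaps(np.zeros((12, 12)), np.zeros((12, 12)),
                           np.zeros((12, 12)))
        sol = solve_perceived_iterative(opp, (u, u, u), geom)
        assert sol.converged
        assert sol.iterations_used <= 2
        assert np.allclose(sol.L_per, 0.4, atol=1e-10)

    def test_converged_residual_small(self, rng, geom):
        L, M = rng.random((12, 12)), rng.random((12, 12))
        opp = forward_opponent(L, M, geom)
        settings = SolverSettings(tol=1e-8, max_iter=20000, method="jacobi")
        sol = solve_perceived_iterative(opp, (0.5 * (L + M),) * 3, geom,
                                        settings)
        assert sol.converged
        # realizable maps: the defining equations hold to ~10*tol per pixel
        resid = residual_error(sol.L_per, sol.M_per, opp, geom)
        assert np.max(np.sqrt(resid)) < 10 * settings.tol

    @pytest.mark.parametrize("scheme", ["jacobi", "gradient"])
    def test_energy_non_increasing(self, rng, geom, scheme):
        """Total E never rises across accepted iterations (step-halving guard)."""
        L, M = rng.random((12, 12)), rng.random((12, 12))
        opp = forward_opponent(L, M, geom)
        init = (0.5 * (L + M), 0.5 * (L + M), 0.5 * (L + M))
        fs = geom.surround_kernel()
        energies = []
        # replicate the solver loop step by step via shrinking max_iter
        prev = None
        for n in (1, 5, 20, 80, 300):
            sol = solve_perceived_iterative(
                opp, init, geom,
                SolverSettings(tol=1e-14, max_iter=n, method=scheme))
            energies.append(sol.final_error)
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_nonconvergence_flagged_not_raised(self, rng, geom):
        L, M = rng.random((16, 16)), rng.random((16, 16))
        opp = forward_opponent(L, M, geom)
        sol = solve_perceived_iterative(
            opp, (0.5 * (L + M),) * 3, geom,
            SolverSettings(tol=1e-14, max_iter=3))
        assert not sol.converged
        assert sol.iterations_used == 3
        assert sol.final_error >= 0


class TestRecoverS:
    def test_zero_opponency_restores_achromatic(self, geom):
        from lcacomp import PerceivedImage
        v = np.full((6, 6), 0.45)
        opp = OpponentMaps(np.zeros((6, 6)), np.zeros((6, 6)), np.zeros((6, 6)))
        perceived = PerceivedImage(L_per=v, M_per=v)
        assert np.allclose(recover_s(opp, perceived), 0.45, atol=1e-15)

    def test_hand_value(self):
        from lcacomp import PerceivedImage
        opp = OpponentMaps(np.zeros((2, 2)), np.zeros((2, 2)),
                           np.full((2, 2), 0.1))
        perceived = PerceivedImage(L_per=np.full((2, 2), 0.4),
                                   M_per=np.full((2, 2), 0.2))
        assert np.allclose(recover_s(opp, perceived), 0.4, atol=1e-15)

    def test_achromatic_pipeline_gives_equal_planes(self, rng, geom):
        """No optics blur + achromatic input: S_per = L_per = M_per."""
        from lcacomp import (AdaptationParams, ConeImage, adapt_image,
                             opponent_responses)
        plane = 0.2 + 0.6 * rng.random((48, 48))
        cones = ConeImage(plane, plane.copy(), plane.copy())
        adapted = adapt_image(cones, AdaptationParams())
        opp = opponent_responses(adapted, geom)
        init = initialize(adapted)
        sol = solve_perceived(opp, geom, SolverSettings(method="spectral"),
                              init)
        s_per = recover_s(opp, sol)
        assert np.max(np.abs(sol.L_per - sol.M_per)) < 1e-8
        assert np.max(np.abs(s_per - sol.L_per)) < 1e-8
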