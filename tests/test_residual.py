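"""Residual-stress boundary-value problem: solvers, profiles, recovery."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from arterymech import (
    draw_parameter_set,
    fixture,
    recover_opening_angle,
    relative_error_profiles,
    residual_stress_profile,
    solve_stress_free,
    solve_unloaded,
    wall_residual,
)
from arterymech.geometry import close_map
from arterymech.residual import ConvergenceError, InconsistentPairError


def shooting_oracle(sector, c):
    """Independent Runge–Kutta oracle for the homogeneous fibre-free ring.

    Integrates dσ_rr/dr = 2c(λ_θ² − λ_r²)/r with σ_rr(r_i) = 0 along the
    closing map and finds the inner radius making σ_rr(r_o) = 0.
    """
    k = sector.k

    def rhs(r, y, r_i):
        R = np.sqrt(k * (r * r - r_i * r_i) + sector.R_i**2)
        lam_t = k * r / R
        return [2.0 * c * (lam_t**2 - lam_t**-2) / r]

    def outer_sigma(r_i):
        r_o = close_map(sector.R_o, sector, r_i)
        sol = solve_ivp(rhs, (r_i, r_o), [0.0], args=(r_i,),
                        rtol=1e-12, atol=1e-14, dense_output=True)
        return sol, r_o

    def resid(r_i):
        sol, r_o = outer_sigma(r_i)
        return sol.y[0, -1]

    root = brentq(resid, 0.3 * sector.R_i, sector.R_o, xtol=1e-12)
    sol, r_o = outer_sigma(root)
    return root, sol


class TestWallResidual:
    def test_alpha_zero_is_exactly_zero(self, rabbit):
        sector = rabbit.sector.with_alpha(0.0)
        assert wall_residual(sector, sector.R_i, rabbit.materials) == pytest.approx(0.0, abs=1e-15)

    def test_root_matches_shooting_oracle(self, toy_neo_hookean):
        sector, mats = toy_neo_hookean
        oracle_root, _ = shooting_oracle(sector, c=1.0)
        annulus, _ = solve_unloaded(sector, mats, n_nodes=101)
        assert annulus.r_i == pytest.approx(oracle_root, abs=1e-8)

    def test_quadrature_refinement_converged(self, rabbit_annulus):
        from arterymech.residual import _inverse_residual
        ann, mats = rabbit_annulus.annulus, rabbit_annulus.materials
        v40 = _inverse_residual(ann, 160.0, 1.4, mats, order=40)
        v80 = _inverse_residual(ann, 160.0, 1.4, mats, order=80)
        assert v40 == pytest.approx(v80, rel=1e-10, abs=1e-13)

    def test_rejects_bad_candidate(self, rabbit):
        with pytest.raises(ValueError):
            wall_residual(rabbit.sector, -0.1, rabbit.materials)


class TestSolveUnloaded:
    def test_alpha_zero_identity(self, rabbit):
        sector = rabbit.sector.with_alpha(0.0)
        annulus, state = solve_unloaded(sector, rabbit.materials, n_nodes=51)
        assert annulus.r_i == sector.R_i
        assert np.allclose(state.s_tt, 0.0, atol=1e-12)
        assert np.allclose(state.s_rr, 0.0, atol=1e-12)

    def test_traction_free_surfaces(self, rabbit):
        c_m = rabbit.materials["media"].c
        _, state = solve_unloaded(rabbit.sector, rabbit.materials)
        assert abs(state.s_rr[0]) < 1e-8 * c_m
        assert abs(state.s_rr[-1]) < 1e-8 * c_m

    def test_equilibrium_residual_small(self, rabbit):
        _, state = solve_unloaded(rabbit.sector, rabbit.materials, n_nodes=401)
        assert state.equilibrium_residual() < 1e-4

    def test_round_trip_with_inverse(self, rabbit):
        annulus, _ = solve_unloaded(rabbit.sector, rabbit.materials, n_nodes=51)
        sector, _ = solve_stress_free(annulus, rabbit.sector.alpha, rabbit.materials,
                                      n_nodes=51)
        assert sector.R_i == pytest.approx(rabbit.sector.R_i, abs=1e-6)
        assert sector.R_m == pytest.approx(rabbit.sector.R_m, abs=1e-6)
        assert sector.R_o == pytest.approx(rabbit.sector.R_o, abs=1e-6)

    def test_inverse_pair_identity_over_draws(self):
        for seed in range(25):
            draw = draw_parameter_set(seed)
            annulus, _ = solve_unloaded(draw.sector, draw.materials, n_nodes=21)
            sector, _ = solve_stress_free(annulus, draw.alpha, draw.materials, n_nodes=21)
            assert sector.R_i == pytest.approx(draw.sector.R_i, abs=1e-6)


class TestSolveStressFree:
    def test_alpha_zero_identity(self, rabbit_annulus):
        sector, state = solve_stress_free(rabbit_annulus.annulus, 0.0,
                                          rabbit_annulus.materials, n_nodes=51)
        assert sector.R_i == rabbit_annulus.annulus.r_i
        assert np.allclose(state.s_tt, 0.0, atol=1e-12)

    def test_rejects_loaded_annulus(self, rabbit_annulus):
        from arterymech import ClosedAnnulus
        ann = rabbit_annulus.annulus
        loaded = ClosedAnnulus(ann.r_i, ann.r_m, ann.r_o, p_lumen=1.0)
        with pytest.raises(ValueError):
            solve_stress_free(loaded, 40.0, rabbit_annulus.materials)

    def test_opening_grows_inner_radius(self, rabbit_annulus):
        # the released sector must have a larger inner radius than the ring
        prev = rabbit_annulus.annulus.r_i
        for alpha in (40.0, 120.0, 200.0):
            sector, _ = solve_stress_free(rabbit_annulus.annulus, alpha,
                                          rabbit_annulus.materials, n_nodes=21)
            assert sector.R_i > prev
            prev = sector.R_i


class TestResidualStressProfile:
    def test_matches_shooting_oracle_pointwise(self, toy_neo_hookean):
        sector, mats = toy_neo_hookean
        oracle_root, oracle_sol = shooting_oracle(sector, c=1.0)
        annulus, state = solve_unloaded(sector, mats, n_nodes=101)
        inner = state.radii > annulus.r_i + 1e-12
        oracle_srr = oracle_sol.sol(state.radii[inner])[0]
        assert np.max(np.abs(state.s_rr[inner] - oracle_srr)) < 1e-8

    def test_circumferential_sign_pattern(self, rabbit):
        # closing the 160-degree sector compresses the inner media rim and
        # stretches the adventitia outer rim
        _, state = solve_unloaded(rabbit.sector, rabbit.materials)
        assert state.s_tt[0] < 0.0
        assert state.s_tt[-1] > 0.0

    def test_interface_node_duplicated(self, rabbit):
        _, state = solve_unloaded(rabbit.sector, rabbit.materials, n_nodes=401)
        assert len(state) == 402
        dup = np.where(np.diff(state.radii) == 0.0)[0]
        assert len(dup) == 1
        i = dup[0]
        assert state.layer_id[i] == "media" and state.layer_id[i + 1] == "adventitia"
        # sigma_rr continuous across the interface, sigma_tt jumps
        assert state.s_rr[i] == state.s_rr[i + 1]
        assert abs(state.s_tt[i] - state.s_tt[i + 1]) > 1e-3

    def test_peak_hoop_stress_monotone_in_alpha(self, rabbit):
        peaks = []
        for alpha in (0.0, 40.0, 80.0, 120.0, 160.0, 200.0):
            sector, _ = solve_stress_free(
                fixture("rabbit_omega_r").annulus, alpha, rabbit.materials, n_nodes=101)
            _, state = solve_unloaded(sector, rabbit.materials, n_nodes=101)
            peaks.append(np.max(np.abs(state.s_tt)))
        assert all(b >= a - 1e-12 for a, b in zip(peaks, peaks[1:]))

    def test_inconsistent_pair_rejected(self, rabbit):
        from arterymech import ClosedAnnulus
        bad = ClosedAnnulus(0.9, 1.1, 1.25)
        with pytest.raises(InconsistentPairError):
            residual_stress_profile(rabbit.sector, bad, rabbit.materials, n_nodes=51)

    def test_fibre_free_equivalence_at_axial_beta(self, rabbit_annulus):
        # beta = 90: in-plane fibre component vanishes, so the computation
        # must coincide exactly with k1 = 0
        from arterymech import HGOLayer
        mats = rabbit_annulus.materials
        axial = {n: HGOLayer(c=m.c, k1=m.k1, k2=m.k2, beta=90.0, name=n)
                 for n, m in mats.items()}
        free = {n: HGOLayer(c=m.c, k1=0.0, k2=m.k2, beta=m.beta, name=n)
                for n, m in mats.items()}
        s_axial, _ = solve_stress_free(rabbit_annulus.annulus, 160.0, axial, n_nodes=21)
        s_free, _ = solve_stress_free(rabbit_annulus.annulus, 160.0, free, n_nodes=21)
        assert s_axial.R_i == s_free.R_i

    def test_fibre_free_equivalence_beyond_30_degrees(self, rabbit_annulus):
        # fibres at beta >= 30 require lam_t > 1/cos(30) = 1.155 to engage,
        # which these residual states never reach: identical to fibre-free
        from arterymech import HGOLayer
        mats = rabbit_annulus.materials
        free = {n: HGOLayer(c=m.c, k1=0.0, k2=m.k2, beta=m.beta, name=n)
                for n, m in mats.items()}
        s_free, _ = solve_stress_free(rabbit_annulus.annulus, 200.0, free, n_nodes=21)
        for beta in (30.0, 60.0):
            tilted = {n: HGOLayer(c=m.c, k1=m.k1, k2=m.k2, beta=beta, name=n)
                      for n, m in mats.items()}
            s_b, _ = solve_stress_free(rabbit_annulus.annulus, 200.0, tilted, n_nodes=21)
            assert s_b.R_i == pytest.approx(s_free.R_i, abs=1e-12)

    def test_adventitia_thickness_grows_with_alpha(self, rabbit_annulus):
        # normalized stress-free adventitia thickness increases with opening
        # angle for any common fibre angle
        from arterymech import HGOLayer
        mats = rabbit_annulus.materials
        for beta in (0.0, 15.0, 90.0):
            common = {n: HGOLayer(c=m.c, k1=m.k1, k2=m.k2, beta=beta, name=n)
                      for n, m in mats.items()}
            t_prev = -np.inf
            for alpha in (0.0, 50.0, 100.0, 150.0, 200.0):
                sec, _ = solve_stress_free(rabbit_annulus.annulus, alpha, common,
                                           n_nodes=21)
                t_a = sec.T_a / rabbit_annulus.annulus.t_a
                assert t_a > t_prev - 1e-12
                t_prev = t_a


class TestRelativeError:
    def test_identical_states_zero(self, rabbit):
        _, state = solve_unloaded(rabbit.sector, rabbit.materials, n_nodes=51)
        assert relative_error_profiles(state, state) == 0.0

    def test_homogeneity(self, rabbit):
        import copy
        _, ref = solve_unloaded(rabbit.sector, rabbit.materials, n_nodes=51)
        test = copy.deepcopy(ref)
        test.s_rr = 1.01 * ref.s_rr
        test.s_tt = 1.01 * ref.s_tt
        assert relative_error_profiles(test, ref) == pytest.approx(0.01, rel=1e-10)

    def test_zero_reference_rejected(self, rabbit):
        sector = rabbit.sector.with_alpha(0.0)
        _, zero = solve_unloaded(sector, rabbit.materials, n_nodes=51)
        with pytest.raises(ZeroDivisionError):
            relative_error_profiles(zero, zero)


class TestRecoverOpeningAngle:
    def test_self_consistency(self, rabbit_annulus):
        sector, prof = solve_stress_free(rabbit_annulus.annulus, 160.0,
                                         rabbit_annulus.materials, n_nodes=101)
        rec = recover_opening_angle(prof, rabbit_annulus.annulus,
                                    rabbit_annulus.materials)
        assert rec == pytest.approx(160.0, abs=0.5)

    def test_zero_profile_maps_to_zero_angle(self, rabbit_annulus):
        sector, prof = solve_stress_free(rabbit_annulus.annulus, 0.0,
                                         rabbit_annulus.materials, n_nodes=51)
        assert recover_opening_angle(prof, rabbit_annulus.annulus,
                                     rabbit_annulus.materials) == 0.0
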