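"""Arc sampling, polynomial potentials, grid Schrödinger solver, NQE."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh_tridiagonal

from hbridge import (ModelArcBackend, ModelPotentialParams, SolverSettings,
                     VibrationalSolution, arc_positions, characterize_model,
                     extract_snapshots, fit_potential, nqe_report,
                     solve_bound_states, thermal_expectation)
from hbridge.constants import (AMU_ME, BOHR_A, HARTREE_CM1, HARTREE_KCAL,
                               KB_KCAL)
from hbridge.nqe import arc_position_count

from conftest import single_frame_trajectory


def fd_reference_levels(potential, settings, n_grid=3000, n_states=5):
    """Independent dense-matrix second-order finite-difference solver."""
    dx = (settings.d_hi - settings.d_lo) / (n_grid + 1)
    grid = settings.d_lo + dx * np.arange(1, n_grid + 1)
    v_h = np.asarray(potential(grid), float) / HARTREE_KCAL
    dx_b = dx / BOHR_A
    m = settings.mass * AMU_ME
    t = 1.0 / (2.0 * m * dx_b ** 2)
    diag = v_h + 2.0 * t
    evals, evecs = eigh_tridiagonal(
        diag, np.full(n_grid - 1, -t), select="i",
        select_range=(0, n_states - 1))
    mean_r = (evecs ** 2 * grid[:, None]).sum(axis=0)
    return evals * HARTREE_CM1, evals * HARTREE_KCAL, mean_r


class TestExtractSnapshots:
    def test_constant_interval_indices(self, gas_params):
        from hbridge import SimulationSettings, embed_trajectory, \
            simulate_bridges
        run = simulate_bridges(gas_params, SimulationSettings(
            seed=5, production_length=0.025, n_equilibration_steps=100))
        traj = embed_trajectory(run)   # 101 frames at 0.25 fs
        assert traj.n_frames == 101
        snaps = extract_snapshots(traj, _bridge(), 5)
        assert [s.frame_index for s in snaps] == [0, 25, 50, 75, 100]
        assert snaps[2].time == pytest.approx(traj.times[50])

    def test_single_snapshot_takes_last_frame(self, short_traj):
        snaps = extract_snapshots(short_traj, _bridge(), 1)
        assert snaps[0].frame_index == short_traj.n_frames - 1

    def test_invalid_counts(self, short_traj):
        with pytest.raises(ValueError):
            extract_snapshots(short_traj, _bridge(), 0)
        with pytest.raises(ValueError):
            extract_snapshots(short_traj, _bridge(), short_traj.n_frames + 1)


def _bridge():
    from hbridge import BridgeDefinition
    return BridgeDefinition(0, 1, 2)


class TestArcPositions:
    def test_colinear_degenerates_to_segment(self):
        D = np.array([0.0, 0.0, 0.0])
        A = np.array([2.55, 0.0, 0.0])
        H = np.array([1.05, 0.0, 0.0])
        pos, dists = arc_positions(D, H, A)
        np.testing.assert_allclose(np.linalg.norm(pos - D, axis=1), dists,
                                   atol=1e-12)
        np.testing.assert_allclose(pos[:, 1:], 0.0, atol=1e-12)
        assert dists[0] == pytest.approx(0.80)
        assert dists[-1] == pytest.approx(2.55 - 0.80)

    def test_points_lie_on_circumcircle(self):
        D = np.array([0.1, -0.2, 0.3])
        H = np.array([0.95, 0.35, 0.42])
        A = np.array([2.4, 0.3, 0.1])
        pos, dists = arc_positions(D, H, A)
        # oracle: circumcenter from the linear equidistance system
        mats = np.array([2 * (H - D), 2 * (A - D),
                         np.cross(H - D, A - D)])
        rhs = np.array([H @ H - D @ D, A @ A - D @ D,
                        np.cross(H - D, A - D) @ D])
        center = np.linalg.solve(mats, rhs)
        radius = np.linalg.norm(D - center)
        radii = np.linalg.norm(pos - center, axis=1)
        assert np.abs(radii - radius).max() < 1e-9
        np.testing.assert_allclose(np.linalg.norm(pos - D, axis=1), dists,
                                   atol=1e-9)

    def test_count_rule_within_printed_bounds(self):
        assert arc_position_count(2.55) == 19
        for d_OO in np.arange(2.35, 2.7501, 0.01):
            assert 16 <= arc_position_count(d_OO) <= 20
        assert arc_position_count(2.35) == 16
        assert arc_position_count(2.75) == 20

    def test_coincident_points_rejected(self):
        p = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            arc_positions(p, p, np.array([2.5, 0, 0]))


class TestFitPotential:
    def test_degree9_data_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=10)
        d = np.linspace(0.8, 1.8, 20)
        u = (d - 1.3) / 0.5
        e = np.polynomial.polynomial.polyval(u, coeffs)
        pot = fit_potential(d, e)
        assert pot.rms_residual < 1e-10
        np.testing.assert_allclose(pot(d), e, atol=1e-8)

    def test_constant_energies_fit_exactly(self):
        d = np.linspace(0.8, 1.8, 20)
        pot = fit_potential(d, np.full(20, 3.3))
        assert pot.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert pot(1.234) == pytest.approx(3.3)

    def test_quadratic_wall_confines_below_sampled_range(self):
        d = np.linspace(0.80, 1.75, 19)
        e = 20.0 * (d - 1.1) ** 2
        pot = fit_potential(d, e, kappa=200.0)
        assert pot(0.7) >= pot(0.80)
        assert pot(0.7) == pytest.approx(pot(0.80) + 200.0 * 0.10 ** 2,
                                         abs=1e-6)
        # continuity at the boundary
        assert pot(0.80 - 1e-9) == pytest.approx(pot(0.80), abs=1e-6)

    def test_too_few_points_suggests_lower_degree(self):
        d = np.linspace(0.8, 1.8, 8)
        with pytest.raises(ValueError, match="lower the degree"):
            fit_potential(d, np.zeros(8), degree=9)


class TestSolver:
    def test_particle_in_a_box_levels(self):
        settings = SolverSettings()
        sol = solve_bound_states(lambda d: np.zeros_like(d), settings)
        L = (settings.d_hi - settings.d_lo) / BOHR_A
        m = settings.mass * AMU_ME
        n = np.arange(1, 4)
        exact = (n ** 2 * np.pi ** 2 / (2 * m * L ** 2)) * HARTREE_CM1
        np.testing.assert_allclose(sol.energies_cm1[:3], exact, rtol=1e-3)

    def test_harmonic_fundamental_3000_cm1(self):
        settings = SolverSettings()
        omega = 3000.0 / HARTREE_CM1
        m = settings.mass * AMU_ME
        k_kcal = m * omega ** 2 * HARTREE_KCAL / BOHR_A ** 2
        sol = solve_bound_states(
            lambda d: 0.5 * k_kcal * (d - 1.35) ** 2, settings)
        gap = sol.energies_cm1[1] - sol.energies_cm1[0]
        assert gap == pytest.approx(3000.0, abs=0.1)

    def test_morse_levels_match_closed_form(self):
        settings = SolverSettings()
        D_kcal, a, re = 30.0, 2.0, 1.2
        D = D_kcal / HARTREE_KCAL
        a_b = a * BOHR_A
        m = settings.mass * AMU_ME
        omega = a_b * np.sqrt(2 * D / m)
        n = np.arange(3)
        exact = (omega * (n + 0.5) - (omega * (n + 0.5)) ** 2 / (4 * D))
        sol = solve_bound_states(
            lambda d: D_kcal * (1 - np.exp(-a * (d - re))) ** 2, settings)
        np.testing.assert_allclose(sol.energies_cm1[:3],
                                   exact * HARTREE_CM1, atol=1.0)

    def test_grid_doubling_converged(self):
        pot = lambda d: 30.0 * (1 - np.exp(-2.0 * (d - 1.2))) ** 2
        e400 = solve_bound_states(pot, SolverSettings(n_grid=400)).energies_cm1[:3]
        e800 = solve_bound_states(pot, SolverSettings(n_grid=800)).energies_cm1[:3]
        assert np.abs(e400 - e800).max() < 0.01

    def test_agrees_with_finite_difference_oracle(self):
        pot = lambda d: 30.0 * (1 - np.exp(-2.0 * (d - 1.2))) ** 2
        settings = SolverSettings()
        sol = solve_bound_states(pot, settings)
        fd_cm1, _, fd_r = fd_reference_levels(pot, settings)
        assert np.abs(sol.energies_cm1[:3] - fd_cm1[:3]).max() < 1.0
        assert np.abs(sol.mean_r[:3] - fd_r[:3]).max() < 1e-4

    def test_normalization_and_ordering(self):
        pot = lambda d: 30.0 * (1 - np.exp(-2.0 * (d - 1.2))) ** 2
        sol = solve_bound_states(pot, SolverSettings())
        dx = sol.grid[1] - sol.grid[0]
        norms = (sol.wavefunctions ** 2).sum(axis=1) * dx
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        assert np.all(np.diff(sol.energies_kcal) >= 0)

    def test_nonconfining_potential_warns(self):
        with pytest.warns(UserWarning, match="confine"):
            solve_bound_states(lambda d: -1e6 * d, SolverSettings())

    def test_nan_potential_rejected(self):
        with pytest.raises(ValueError, match="not finite"):
            solve_bound_states(lambda d: np.full_like(d, np.nan),
                               SolverSettings())


def _fake_solution(energies_kcal, mean_r, n_levels=2, temperature=295.0):
    n = len(energies_kcal)
    return VibrationalSolution(
        grid=np.linspace(0.7, 2.0, 4),
        energies_kcal=np.asarray(energies_kcal, float),
        energies_cm1=np.asarray(energies_kcal, float) / HARTREE_KCAL
        * HARTREE_CM1,
        wavefunctions=np.zeros((n, 4)),
        mean_r=np.asarray(mean_r, float),
        settings=SolverSettings(n_levels=n_levels, temperature=temperature),
    )


class TestThermalExpectation:
    def test_harmonic_thermal_mean_is_the_minimum(self):
        # symmetric well centred mid-domain: every state has <r> = minimum
        settings = SolverSettings()
        omega = 3000.0 / HARTREE_CM1
        m = settings.mass * AMU_ME
        k_kcal = m * omega ** 2 * HARTREE_KCAL / BOHR_A ** 2
        sol = solve_bound_states(
            lambda d: 0.5 * k_kcal * (d - 1.35) ** 2, settings)
        r, _ = thermal_expectation(sol)
        assert r == pytest.approx(1.35, abs=1e-9)

    def test_large_gap_reduces_to_ground_state(self):
        sol = _fake_solution([0.0, 50.0, 100.0], [1.02, 1.40, 1.50],
                             n_levels=3)
        r, w = thermal_expectation(sol)
        assert r == pytest.approx(1.02, abs=1e-6)
        assert w[0] == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_two_level_boltzmann_case(self):
        gap = KB_KCAL * 295.0 * np.log(2.0)
        sol = _fake_solution([0.0, gap], [1.0, 1.3])
        r, w = thermal_expectation(sol)
        assert r == pytest.approx((2 * 1.0 + 1 * 1.3) / 3, abs=1e-9)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_invariant_under_energy_shift(self):
        a = _fake_solution([0.0, 0.5, 1.2], [1.0, 1.2, 1.4], n_levels=3)
        b = _fake_solution([7.0, 7.5, 8.2], [1.0, 1.2, 1.4], n_levels=3)
        assert thermal_expectation(a)[0] == pytest.approx(
            thermal_expectation(b)[0], abs=1e-12)

    def test_zero_temperature_is_ground_state_only(self):
        sol = _fake_solution([0.0, 0.01], [1.0, 1.3])
        r, w = thermal_expectation(sol, temperature=0.0)
        assert r == 1.0 and w[0] == 1.0

    def test_requesting_more_levels_than_states_fails(self):
        sol = _fake_solution([0.0, 1.0], [1.0, 1.3])
        with pytest.raises(ValueError):
            thermal_expectation(sol, levels=5)


class TestNqePipeline:
    def test_report_has_one_row_per_snapshot(self, short_traj, gas_params):
        report = nqe_report(short_traj,
                            _six_atom_bridge(), ModelArcBackend(gas_params),
                            n_snapshots=5)
        assert len(report) == 5
        assert set(report.columns) >= {"d_OO_A", "classical_d_DH_A",
                                       "quantum_r_A"}
        assert report["n_scan_points"].between(16, 20).all()

    def test_symmetric_double_well_quantum_mean_near_midpoint(
            self, solid_params):
        # ZPE comparable to the barrier: the quantum proton sits much
        # closer to the bridge midpoint than the classical minimum
        R = 2.55
        ch = characterize_model(solid_params, R)
        traj = single_frame_trajectory(ch.r_min_deep, R)
        report = nqe_report(traj, _bridge(), ModelArcBackend(solid_params),
                            n_snapshots=1)
        mid = R / 2
        q_off = abs(report.loc[0, "quantum_r_A"] - mid)
        cl_off = abs(ch.r_min_deep - mid)
        assert q_off < cl_off
        assert q_off < 0.02   # symmetric potential: <r> essentially centred

    def test_pt_configuration_quantum_shift_toward_donor(self, gas_params):
        # acceptor-biased surface, proton in the PT minimum (d_DH > 1.5 Å):
        # quantum <r> moves to lower donor-proton distances
        p = gas_params.replace(D_d=gas_params.D_a, D_a=gas_params.D_d)
        R = 2.55
        ch = characterize_model(p, R)
        assert ch.r_min_deep > 1.5
        traj = single_frame_trajectory(ch.r_min_deep, R)
        report = nqe_report(traj, _bridge(), ModelArcBackend(p),
                            n_snapshots=1)
        assert report.loc[0, "quantum_r_A"] < report.loc[0, "classical_d_DH_A"]

    def test_pipeline_matches_dense_fd_reference(self, solid_params):
        # same fitted potential solved by the independent FD oracle
        R = 2.55
        ch = characterize_model(solid_params, R)
        traj = single_frame_trajectory(ch.r_min_deep, R)
        snaps = extract_snapshots(traj, _bridge(), 1)
        pos, dists = arc_positions(snaps[0].donor, snaps[0].proton,
                                   snaps[0].acceptor)
        energies = ModelArcBackend(solid_params).profile_energies(
            snaps[0], pos, dists)
        pot = fit_potential(dists, energies)
        settings = SolverSettings()
        sol = solve_bound_states(pot, settings)
        r_dvr, _ = thermal_expectation(sol)
        fd_cm1, fd_kcal, fd_r = fd_reference_levels(pot, settings)
        w = np.exp(-(fd_kcal[:3] - fd_kcal[0]) / (KB_KCAL * 295.0))
        r_fd = float((w / w.sum()) @ fd_r[:3])
        assert r_dvr == pytest.approx(r_fd, abs=1e-3)

    def test_report_deterministic(self, short_traj, gas_params):
        a = nqe_report(short_traj, _six_atom_bridge(),
                       ModelArcBackend(gas_params), n_snapshots=3)
        b = nqe_report(short_traj, _six_atom_bridge(),
                       ModelArcBackend(gas_params), n_snapshots=3)
        pd.testing.assert_frame_equal(a, b)


def _six_atom_bridge():
    from hbridge import BridgeDefinition
    return BridgeDefinition(0, 1, 2, label="O8-HBP1...O1")
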