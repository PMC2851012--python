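import numpy as np
import pytest

from cvdom import _kernels
from cvdom.boundary import uniform_detectors
from cvdom.medium import MediumMap, OpticalProperties, build_grid
from cvdom.quadrature import make_ordinates
from cvdom.solver import (NonConvergenceError, SolverConfig, TransportProblem,
                          fluence_matrix, run_steady, run_transient,
                          sweep_quadrant)
from cvdom.sources import Source, make_cw_source, make_pulse_source


def strip_sweep_oracle(nx, ny, mu_t, A, B, C_area, inflow_w, alpha):
    """Independently coded scalar face recurrence for one (+,+) ordinate."""
    I = np.zeros((nx, ny))
    fy = np.zeros(nx)
    for j in range(ny):
        fx = inflow_w
        for i in range(nx):
            Ip = (A * fx + B * fy[i]) / (A + B + C_area * mu_t)
            I[i, j] = Ip
            fx = (Ip - (1 - alpha) * fx) / alpha
            fy[i] = (Ip - (1 - alpha) * fy[i]) / alpha
    return I


class TestSweep:
    @pytest.mark.parametrize("alpha", [0.5, 1.0])
    def test_strip_matches_scalar_recurrence(self, alpha):
        # pure-absorber strip: the sweep reduces to a scalar linear
        # recurrence, reproduced here to machine precision
        nx, ny, mu_a = 30, 2, 0.8
        grid = build_grid(nx * 0.1, ny * 0.1, 0.1, 0.1)
        o = make_ordinates(16)
        m = int(o.quadrant_ordinates(1, 1)[0])
        I_new = np.zeros((nx, ny, o.M))
        vol = np.zeros_like(I_new)
        in_x = np.zeros((ny, o.M))
        in_x[:, m] = 0.7
        in_y = np.zeros((nx, o.M))
        out_x = np.zeros((ny, o.M))
        out_y = np.zeros((nx, o.M))
        mu_t = np.full((nx, ny), mu_a)
        _kernels.sweep_ordinates(I_new, vol, mu_t, o.xi, o.eta,
                                 np.array([m]), 1, 1, alpha, 0.1, 0.1, 0.0,
                                 in_x, in_y, out_x, out_y)
        A = 0.1 * abs(o.xi[m]) / alpha
        B = 0.1 * abs(o.eta[m]) / alpha
        oracle = strip_sweep_oracle(nx, ny, mu_a, A, B, 0.01, 0.7, alpha)
        assert np.abs(I_new[:, :, m] - oracle).max() <= 1e-15 * oracle.max()

    def test_zero_everything_stays_zero(self, small_problem):
        p = small_problem
        I = p.zero_field()
        faces = p.zero_faces()
        out = sweep_quadrant(p, (1, 1), I, faces, active=[False])
        assert np.all(out == 0)

    def test_vacuum_propagates_boundary_value_unattenuated(self):
        # mu_a = mu_s = 0: the face recurrence passes the upstream value
        # through every cell of the characteristic unchanged
        grid = build_grid(1.0, 0.2, 0.1, 0.1)
        o = make_ordinates(16)
        m = int(o.quadrant_ordinates(1, 1)[0])
        I_new = np.zeros((10, 2, o.M))
        vol = np.zeros_like(I_new)
        in_x = np.zeros((2, o.M))
        in_x[:, m] = 1.3
        in_y = np.zeros((10, o.M))
        in_y[:, m] = 1.3
        out_x = np.zeros((2, o.M))
        out_y = np.zeros((10, o.M))
        _kernels.sweep_ordinates(I_new, vol, np.zeros((10, 2)), o.xi, o.eta,
                                 np.array([m]), 1, 1, 0.5, 0.1, 0.1, 0.0,
                                 in_x, in_y, out_x, out_y)
        assert np.allclose(I_new[:, :, m], 1.3)
        assert np.allclose(out_y[:, m], 1.3)

    def test_absorber_geometric_decay_along_sweep(self):
        # with upwind closure (faces = cell values) and dark transverse
        # inflow, the decay per cell along x is exactly A / (A + B + dV mu_a)
        # (the transverse term B leaks to the north faces even when dark)
        grid = build_grid(1.0, 0.2, 0.1, 0.1)
        o = make_ordinates(16)
        m = int(o.quadrant_ordinates(1, 1)[0])
        alpha, mu_a = 1.0, 4.0
        I_new = np.zeros((10, 2, o.M))
        in_x = np.zeros((2, o.M))
        in_x[:, m] = 1.0
        args = (np.zeros_like(I_new), np.full((10, 2), mu_a), o.xi, o.eta,
                np.array([m]), 1, 1, alpha, 0.1, 0.1, 0.0,
                in_x, np.zeros((10, o.M)), np.zeros((2, o.M)),
                np.zeros((10, o.M)))
        _kernels.sweep_ordinates(I_new, *args)
        A = 0.1 * abs(o.xi[m]) / alpha
        B = 0.1 * abs(o.eta[m]) / alpha
        factor = A / (A + B + 0.01 * mu_a)
        ratios = I_new[1:, 0, m] / I_new[:-1, 0, m]
        assert np.allclose(ratios, factor)


class TestSteady:
    def test_zero_source_converges_immediately(self, small_problem):
        p = TransportProblem(small_problem.medium, 16, [], [], SolverConfig())
        res = run_steady(p)
        assert res.iterations == 1
        assert np.all(res.I == 0)

    def test_fluence_matrix_weights(self, ords16):
        I = np.zeros((3, 3, 16))
        I[1, 1, :] = 2.0          # isotropic radiance in one cell
        phi = fluence_matrix(I, ords16)
        assert phi[1, 1] == pytest.approx(4 * np.pi)
        assert phi[0, 0] == 0.0
        I2 = np.zeros((3, 3, 16))
        I2[0, 2, 5] = 3.0          # single ordinate
        assert fluence_matrix(I2, ords16)[0, 2] == \
            pytest.approx(ords16.w[5] * 3.0)

    def test_energy_balance_closes(self, small_problem):
        res = run_steady(small_problem)
        eb = res.energy_balance()
        assert eb.injected > 0
        assert eb.residual_fraction < 1e-8

    def test_symmetric_pair_gives_symmetric_fluence(self, scattering_medium):
        o = make_ordinates(16)
        m = 3
        mm = int(o.mirror_x[m])
        sA = Source("cw", "bottom", 0.475, 0.020, ordinate=m)
        sB = Source("cw", "bottom", 0.525, 0.020, ordinate=mm)
        p = TransportProblem(scattering_medium, o, [sA, sB], [], SolverConfig())
        phi = run_steady(p).fluence
        assert np.abs(phi - phi[::-1, :]).max() <= 1e-10 * phi.max()

    def test_steady_independent_of_route(self, scattering_medium):
        # the directly iterated steady equations and the time-marched route
        # (finite dt) settle on the same field
        p = TransportProblem(scattering_medium, 16,
                             [make_cw_source("bottom", 0.5)], [],
                             SolverConfig(dt=1e-12))
        direct = run_steady(p)
        marched = run_steady(p, dt=1e-12)
        rel = np.abs(marched.I - direct.I) / np.maximum(direct.I.max() * 1e-9,
                                                        np.abs(direct.I))
        assert rel.max() < 1e-4

    def test_nonconvergence_reports_history(self, scattering_medium):
        p = TransportProblem(scattering_medium, 16,
                             [make_cw_source("bottom", 0.5)], [],
                             SolverConfig(max_inner_iters=3))
        with pytest.raises(NonConvergenceError) as err:
            run_steady(p)
        assert len(err.value.eps_history) == 3

    def test_grid_refinement_first_order_or_better(self):
        # transmitted power through the top side under grid halving: the
        # observed convergence order of the upwind scheme is >= 1
        vals = []
        for dx in (0.1, 0.05, 0.025):
            grid = build_grid(1.0, 1.0, dx, dx)
            med = MediumMap.homogeneous(grid, OpticalProperties(1.0, 3.0, 0.0),
                                        n_m=1.4)
            p = TransportProblem(med, 16, [make_cw_source("bottom", 0.5)], [],
                                 SolverConfig(alpha=1.0))
            vals.append(run_steady(p).energy_balance().transmitted)
        e1, e2 = abs(vals[0] - vals[1]), abs(vals[1] - vals[2])
        order = np.log2(e1 / e2)
        assert order >= 0.9


class TestTransient:
    def test_zero_duration_run_is_empty(self, small_problem):
        res = run_transient(small_problem, t_max=0.0)
        assert res.times_s.size == 0
        assert res.detector_series.shape == (0, 5)

    def test_pure_absorber_energy_decays_monotonically(self):
        # impulse in, no scattering: the discrete energy audit
        # sum_cells w_m I dV must decrease at every step after the pulse
        grid = build_grid(1.0, 1.0, 0.1, 0.1)
        med = MediumMap.homogeneous(grid, OpticalProperties(5.0, 0.0, 0.0),
                                    n_m=1.4)
        p = TransportProblem(med, 16, [make_pulse_source("bottom", 0.5)], [],
                             SolverConfig(alpha=1.0))
        energies = []
        res = run_transient(p, t_max=100e-13,
                            snapshot_times=tuple(k * 1e-13 for k in range(1, 101)))
        for t in sorted(res.snapshots):
            energies.append(res.snapshots[t].sum())
        energies = np.array(energies)
        # the three-level scheme needs a few steps to forget the
        # backward-Euler startup; after that the budget decays strictly
        assert np.all(np.diff(energies[5:]) < 0)
        assert energies[-1] < 0.5 * energies.max()

    def test_monotone_approach_to_steady(self):
        # under CW drive the inter-step relative change is eventually
        # decreasing and reaches the requested stopping tolerance
        grid = build_grid(0.5, 0.5, 0.05, 0.05)
        med = MediumMap.homogeneous(grid, OpticalProperties(1.0, 5.0, 0.0),
                                    n_m=1.4)
        p = TransportProblem(med, 16, [make_cw_source("bottom", 0.25)], [],
                             SolverConfig())
        res = run_transient(p, t_max=30000e-13, stop_at_steady=True,
                            stop_tol=1e-6)
        changes = np.array(res.step_changes)
        assert res.final_step_change <= 1e-6
        tail = changes[len(changes) // 2:]
        assert np.all(np.diff(tail) < 0)  # monotone decrease in the tail

    def test_cw_long_time_matches_steady(self, scattering_medium):
        p = TransportProblem(scattering_medium, 16,
                             [make_cw_source("bottom", 0.5)],
                             uniform_detectors("top", scattering_medium.grid, 3),
                             SolverConfig())
        tr = run_transient(p, t_max=6000e-13)
        st = run_steady(p)
        rel = np.abs(tr.field.I_curr - st.I) / np.maximum(np.abs(st.I), 1e-300)
        assert rel.max() < 1e-4

    def test_snapshot_times_recorded(self, small_problem):
        res = run_transient(small_problem, t_max=10e-13,
                            snapshot_times=(3e-13, 7e-13))
        assert set(res.snapshots) == {3e-13, 7e-13}
        assert res.snapshots[3e-13].shape == (20, 20)

    def test_sor_rho_one_plain_iteration_same_fixed_point(self, scattering_medium):
        p1 = TransportProblem(scattering_medium, 16,
                              [make_cw_source("bottom", 0.5)], [],
                              SolverConfig(rho=1.0, tol=1e-10))
        p2 = TransportProblem(scattering_medium, 16,
                              [make_cw_source("bottom", 0.5)], [],
                              SolverConfig(rho=1.1, tol=1e-10))
        a, b = run_steady(p1), run_steady(p2)
        assert np.allclose(a.I, b.I, rtol=1e-6, atol=1e-20)
        assert b.iterations <= a.iterations  # over-relaxation accelerates

    def test_negativity_reported_not_clipped(self, scattering_medium):
        # diamond interpolation near the collimated beam produces negative
        # intermediate radiances; they must be reported, never zeroed
        p = TransportProblem(scattering_medium, 16,
                             [make_cw_source("bottom", 0.5)], [],
                             SolverConfig(alpha=0.5))
        res = run_steady(p)
        assert res.n_negative > 0
        assert res.min_radiance < 0
        assert (res.I < 0).sum() == res.n_negative
        p_up = TransportProblem(scattering_medium, 16,
                                [make_cw_source("bottom", 0.5)], [],
                                SolverConfig(alpha=1.0))
        assert run_steady(p_up).n_negative == 0


class TestSolverConfig:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.2}, {"rho": 0.5}, {"rho": 2.0},
        {"tol": 0.0}, {"dt": -1e-13},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
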