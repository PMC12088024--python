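"""Flow solver: analytic oracles, invariances, boundary handling."""

import numpy as np
import pytest

from archflow import fem
from archflow.mesh import from_p1, structured_tube_mesh, tag_tube_caps
from archflow.solver import (BoundarySpec, FluidProperties, PressureWaveform,
                             SolverError, TimeSteppingSpec, boundary_flux,
                             diagnostics, sample_line, simulate, steady_solve)
from conftest import DP, L_TUBE, R_TUBE, poiseuille_axial


class TestPressureWaveform:
    def test_sinusoid_periodicity(self):
        w = PressureWaveform.sinusoid(10.0, 5.0, period=0.4, phase=0.3)
        t = np.linspace(0, 0.4, 13)
        np.testing.assert_allclose(w(t), w(t + 0.4), atol=1e-12)

    def test_sampled_interpolation(self):
        w = PressureWaveform(samples=np.array([[0.0, 1.0], [0.5, 3.0],
                                               [1.0, 1.0]]))
        assert w(0.25) == pytest.approx(2.0)
        assert w(1.25) == pytest.approx(2.0)   # periodic extension
        assert w.period == pytest.approx(1.0)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        tab = pd.DataFrame({"t_s": [0.0, 0.2, 0.4], "p_Pa": [1.0, 2.0, 1.0]})
        tab.to_csv(tmp_path / "w.csv", index=False)
        w = PressureWaveform.from_csv(tmp_path / "w.csv")
        assert w(0.1) == pytest.approx(1.5)

    @pytest.mark.parametrize("bad", [
        dict(period=0.0),
        dict(samples=np.array([[0.0, 1.0]])),
        dict(samples=np.array([[0.0, 1.0], [0.0, 2.0]])),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            PressureWaveform(**bad)


class TestSpecs:
    def test_fluid_validation(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)
        assert FluidProperties().kinematic_viscosity == pytest.approx(
            3.71e-3 / 1060.0)

    @pytest.mark.parametrize("bad", [dict(dt=0), dict(n_cycles=0),
                                     dict(convection="magic")])
    def test_timestepping_validation(self, bad):
        with pytest.raises(ValueError):
            TimeSteppingSpec(**bad)


class TestHydrostatic:
    def test_equal_pressures_give_rest(self, tube_mesh_coarse, fluid):
        bcs = BoundarySpec(pressures={
            "inlet": PressureWaveform.constant(5.0),
            "outlet": PressureWaveform.constant(5.0)})
        sol = steady_solve(tube_mesh_coarse, fluid, bcs, convection="none")
        assert np.abs(sol.u).max() < 1e-12
        np.testing.assert_allclose(sol.p[0], 5.0, atol=1e-8)
        assert sol.p[0].std() < 1e-8 if sol.p.ndim == 2 else True

    def test_zero_pressure_gives_zero_field(self, tube_mesh_coarse, fluid):
        bcs = BoundarySpec(pressures={
            "inlet": PressureWaveform.constant(0.0),
            "outlet": PressureWaveform.constant(0.0)})
        sol = steady_solve(tube_mesh_coarse, fluid, bcs, convection="none")
        assert np.abs(sol.u).max() == 0.0


class TestPoiseuille:
    def test_velocity_profile(self, poiseuille_coarse):
        sol = poiseuille_coarse
        uex = poiseuille_axial(sol.verts_m)
        err = np.linalg.norm(sol.u[0][:, 2] - uex) / np.linalg.norm(uex)
        assert err < 0.05
        assert np.abs(sol.u[0][:, :2]).max() < 0.05 * uex.max()

    def test_flow_rate(self, poiseuille_coarse):
        Rm, Lm = R_TUBE * 1e-3, L_TUBE * 1e-3
        Qex = np.pi * Rm ** 4 * DP / (8 * 3.71e-3 * Lm)
        Q = boundary_flux(poiseuille_coarse,
                          poiseuille_coarse.mesh.tag_of("outlet"))[0]
        assert Q == pytest.approx(Qex, rel=0.05)

    def test_steady_matches_transient_limit(self, tube_mesh_coarse, fluid,
                                            poiseuille_bcs,
                                            poiseuille_coarse):
        ts = TimeSteppingSpec(dt=0.05, n_cycles=2)
        sol = simulate(tube_mesh_coarse, fluid, poiseuille_bcs, ts)
        scale = np.abs(poiseuille_coarse.u[0]).max()
        # viscous time scale R^2/nu ~ 1 ms << dt: final state is steady
        assert np.abs(sol.u[-1] - poiseuille_coarse.u[0]).max() < 1e-3 * scale

    def test_kinetic_energy_bounded(self, tube_mesh_coarse, fluid,
                                    poiseuille_bcs):
        sol = simulate(tube_mesh_coarse, fluid, poiseuille_bcs,
                       TimeSteppingSpec(dt=0.05, n_cycles=1))
        ke = (sol.u ** 2).sum(axis=(1, 2))
        assert np.isfinite(ke).all()
        assert ke.max() <= 1.05 * ke[-1] + 1e-30

    def test_picard_agrees_with_stokes_at_low_re(self, tube_mesh_coarse,
                                                 fluid, poiseuille_bcs,
                                                 poiseuille_coarse):
        sol = steady_solve(tube_mesh_coarse, fluid, poiseuille_bcs,
                           convection="picard")
        scale = np.abs(poiseuille_coarse.u[0]).max()
        assert np.abs(sol.u[0] - poiseuille_coarse.u[0]).max() < 1e-3 * scale


class TestDiagnostics:
    def test_mass_conservation(self, poiseuille_coarse):
        d = diagnostics(poiseuille_coarse)
        assert d.mass_imbalance.max() < 1e-3

    def test_zero_flow_all_fluxes_zero(self, tube_mesh_coarse, fluid):
        bcs = BoundarySpec(pressures={
            "inlet": PressureWaveform.constant(0.0),
            "outlet": PressureWaveform.constant(0.0)})
        sol = steady_solve(tube_mesh_coarse, fluid, bcs, convection="none")
        d = diagnostics(sol)
        for q in d.fluxes.values():
            assert np.abs(q).max() == 0.0

    def test_reynolds_scales_linearly(self, poiseuille_coarse):
        d1 = diagnostics(poiseuille_coarse)
        doubled = type(poiseuille_coarse)(
            mesh=poiseuille_coarse.mesh, fluid=poiseuille_coarse.fluid,
            times=poiseuille_coarse.times, u=2 * poiseuille_coarse.u,
            p=2 * poiseuille_coarse.p)
        d2 = diagnostics(doubled)
        np.testing.assert_allclose(d2.reynolds, 2 * d1.reynolds, rtol=1e-12)


class TestSampleLine:
    def test_parabolic_profile_center_is_2x_sectional_mean(
            self, poiseuille_coarse):
        Rm = R_TUBE * 1e-3
        _, mag = sample_line(poiseuille_coarse, (0, 0, L_TUBE / 2),
                             (0, 0, L_TUBE / 2 + 1e-9), 2)
        area = np.pi * Rm ** 2
        Q = boundary_flux(poiseuille_coarse,
                          poiseuille_coarse.mesh.tag_of("outlet"))[0]
        assert mag[0] == pytest.approx(2 * Q / area, rel=0.05)

    def test_wall_line_near_zero(self, poiseuille_coarse):
        # chord near the wall: no-slip keeps |u| small
        x = 0.97 * R_TUBE
        _, mag = sample_line(poiseuille_coarse, (x, 0, 0.3), (x, 0, 0.7), 9)
        umax = np.abs(poiseuille_coarse.u[0]).max()
        assert mag.max() < 0.15 * umax

    def test_outside_point_raises(self, poiseuille_coarse):
        with pytest.raises(SolverError, match="outside"):
            sample_line(poiseuille_coarse, (0, 0, -0.5), (0, 0, 0.5), 5)


class TestReflectionEquivariance:
    def test_mirrored_mesh_gives_mirrored_solution(self, fluid,
                                                   poiseuille_bcs):
        m = structured_tube_mesh(R_TUBE, L_TUBE, h=R_TUBE / 3,
                                 axial_h=L_TUBE / 6)
        sol = steady_solve(m, fluid, poiseuille_bcs, convection="none")
        verts_m = m.vertices[:m.n_p1] * np.array([-1.0, 1.0, 1.0])
        mm = from_p1(verts_m, m.cells[:, :4], element_size=m.element_size)
        mm = tag_tube_caps(mm, (0, 0, 1), 0.0, L_TUBE)
        sol_m = steady_solve(mm, fluid, poiseuille_bcs, convection="none")
        scale = np.abs(sol.u[0]).max()
        np.testing.assert_allclose(sol_m.u[0][:, 2], sol.u[0][:, 2],
                                   atol=1e-8 * scale)
        np.testing.assert_allclose(sol_m.u[0][:, 0], -sol.u[0][:, 0],
                                   atol=1e-8 * scale)


class TestErrors:
    def test_uncovered_boundary_detected(self, tube_mesh_coarse, fluid):
        bcs = BoundarySpec(pressures={
            "inlet": PressureWaveform.constant(DP)})  # outlet forgotten
        with pytest.raises(SolverError, match="outlet"):
            steady_solve(tube_mesh_coarse, fluid, bcs)

    def test_untagged_mesh_rejected(self, fluid, poiseuille_bcs):
        m = structured_tube_mesh(R_TUBE, L_TUBE, h=R_TUBE / 2,
                                 axial_h=L_TUBE / 4)
        m.facet_names = {}
        with pytest.raises(SolverError, match="tag"):
            steady_solve(m, fluid, poiseuille_bcs)
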