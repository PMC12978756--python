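"""Reduced tube solver vs closed-form oracles (Poiseuille, Womersley)."""

import numpy as np
import pytest

from pulsarch.cardiac_waveform import WaveformParams
from pulsarch.rheology import default_registry
from pulsarch.synthetic_data import (
    WomersleyReference,
    womersley_profile,
    womersley_wall_shear,
)
from pulsarch.tube_solver import (
    RadialGrid,
    reynolds_number,
    skin_friction,
    solve_pulsatile_tube,
    solve_steady_tube,
    wall_shear_stress,
)

from conftest import newtonian

REG = default_registry()


class TestSteadySolve:
    MU, UBAR, R = 0.0035, 0.2, 0.01

    def test_poiseuille_velocity_and_gradient(self):
        prof = solve_steady_tube(self.R, newtonian(self.MU), mean_velocity=self.UBAR, nr=101)
        assert prof.centerline_velocity() == pytest.approx(2 * self.UBAR, rel=1e-3)
        assert prof.dpdx == pytest.approx(-8 * self.MU * self.UBAR / self.R**2, rel=1e-3)
        # nodal shape is the exact parabola (finite-volume fluxes exact)
        parab = prof.centerline_velocity() * (1 - (prof.grid.r / self.R) ** 2)
        np.testing.assert_allclose(prof.u, parab, atol=1e-12)

    def test_poiseuille_wall_shear(self):
        prof = solve_steady_tube(self.R, newtonian(self.MU), mean_velocity=self.UBAR, nr=101)
        assert wall_shear_stress(prof, newtonian(self.MU)) == pytest.approx(
            4 * self.MU * self.UBAR / self.R, rel=1e-3
        )

    def test_prescribed_gradient_mode_matches_closed_form(self):
        dpdx = -11.2
        prof = solve_steady_tube(self.R, newtonian(self.MU), dpdx=dpdx, nr=51)
        assert prof.mean_velocity() == pytest.approx(
            -dpdx * self.R**2 / (8 * self.MU), rel=1e-3
        )

    def test_mean_constraint_satisfied_to_machine_precision(self):
        for cond in ("anemic", "diabetic"):
            prof = solve_steady_tube(0.006, REG[cond], mean_velocity=0.15, nr=64)
            assert prof.mean_velocity() == pytest.approx(0.15, rel=1e-12)

    def test_driving_mode_exclusivity(self):
        with pytest.raises(ValueError):
            solve_steady_tube(0.01, newtonian(0.0035))
        with pytest.raises(ValueError):
            solve_steady_tube(0.01, newtonian(0.0035), mean_velocity=0.1, dpdx=-10.0)


class TestPulsatileSolve:
    def womersley_case(self):
        return WomersleyReference(
            radius=0.0125, density=1060.0, viscosity=0.0035,
            amplitude=4000.0, omega=4 * np.pi,
        )

    def test_womersley_velocity_and_wss(self):
        """Newtonian oscillatory solve vs the Bessel-function solution."""
        ref = self.womersley_case()
        nr = 201
        r = np.linspace(0.0, ref.radius, nr)
        profiles = solve_pulsatile_tube(
            radius=ref.radius, rheology=newtonian(ref.viscosity),
            dpdx_fn=ref.dpdx, period=ref.period, nr=nr, dt=ref.period / 2000,
            n_cycles=2, u0=womersley_profile(ref, r, 0.0), store="last_cycle",
        )
        v_errs, wss_num, wss_exact = [], [], []
        for p in profiles[::20]:
            exact = womersley_profile(ref, r, p.t)
            v_errs.append(np.linalg.norm(p.u - exact) / np.linalg.norm(exact))
            wss_num.append(wall_shear_stress(p, newtonian(ref.viscosity)))
            wss_exact.append(womersley_wall_shear(ref, p.t))
        assert max(v_errs) < 0.01
        wss_num, wss_exact = np.asarray(wss_num), np.asarray(wss_exact)
        assert np.max(np.abs(wss_num - wss_exact)) / wss_exact.max() < 0.02

    def test_grid_refinement_error_decreases(self):
        ref = self.womersley_case()
        errs = []
        for nr in (51, 101, 201):
            r = np.linspace(0.0, ref.radius, nr)
            profiles = solve_pulsatile_tube(
                radius=ref.radius, rheology=newtonian(ref.viscosity),
                dpdx_fn=ref.dpdx, period=ref.period, nr=nr, dt=ref.period / 1000,
                n_cycles=1, u0=womersley_profile(ref, r, 0.0), store="last_cycle",
            )
            errs.append(
                max(
                    np.linalg.norm(p.u - womersley_profile(ref, r, p.t))
                    / np.linalg.norm(womersley_profile(ref, r, p.t))
                    for p in profiles[::100]
                )
            )
        assert errs[0] > errs[1] > errs[2]

    def test_flow_constraint_every_step(self):
        wf = WaveformParams()
        profiles = solve_pulsatile_tube(
            radius=0.0125, rheology=REG["healthy1"], waveform=wf,
            nr=41, dt=wf.period / 200, n_cycles=1, store="all",
        )
        from pulsarch.cardiac_waveform import inlet_velocity

        for p in profiles:
            assert p.mean_velocity() == pytest.approx(
                inlet_velocity(p.t, wf), rel=1e-8, abs=1e-12
            )

    def test_newtonian_limit_independent_of_carreau_constants(self):
        """With equal plateaus, lam and k must not matter (1e-10)."""
        wf = WaveformParams()
        common = dict(
            radius=0.01, waveform=wf, nr=33, dt=wf.period / 100, n_cycles=1,
            store="last_cycle",
        )
        a = solve_pulsatile_tube(rheology=newtonian(0.004, lam=1.0, k=0.5), **common)
        b = solve_pulsatile_tube(rheology=newtonian(0.004, lam=77.0, k=0.11), **common)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.u, pb.u, rtol=1e-10)
            assert pa.dpdx == pytest.approx(pb.dpdx, rel=1e-10)

    def test_steady_driving_recovers_poiseuille(self):
        """Zero-amplitude waveform: pulsatile march sits on the steady solution."""
        wf = WaveformParams(amplitude=0.0, diastolic_level=0.2)
        mu = 0.0035
        profiles = solve_pulsatile_tube(
            radius=0.01, rheology=newtonian(mu), waveform=wf,
            nr=101, dt=wf.period / 200, n_cycles=2, store="last_cycle",
        )
        p = profiles[-1]
        assert p.centerline_velocity() == pytest.approx(0.4, rel=1e-3)
        assert p.dpdx == pytest.approx(-8 * mu * 0.2 / 0.01**2, rel=1e-3)
        assert wall_shear_stress(p, newtonian(mu)) == pytest.approx(
            4 * mu * 0.2 / 0.01, rel=1e-3
        )

    def test_shear_thinning_blunts_the_profile(self):
        """Same driving: non-Newtonian centerline < Newtonian-at-mu0."""
        wf = WaveformParams()
        common = dict(radius=0.0125, waveform=wf, nr=61, dt=wf.period / 200, n_cycles=3,
                      store="last_cycle")
        thin = solve_pulsatile_tube(rheology=REG["healthy2"], **common)
        newt = solve_pulsatile_tube(rheology=newtonian(REG["healthy2"].mu0), **common)
        u_thin = np.mean([p.centerline_velocity() for p in thin])
        u_newt = np.mean([p.centerline_velocity() for p in newt])
        assert u_thin < u_newt

    def test_diabetic_needs_larger_peak_gradient_than_anemic(self):
        wf = WaveformParams()
        common = dict(radius=0.0125, waveform=wf, nr=61, dt=wf.period / 200, n_cycles=3,
                      store="last_cycle")
        peak = {}
        for cond in ("anemic", "diabetic"):
            profs = solve_pulsatile_tube(rheology=REG[cond], **common)
            peak[cond] = max(abs(p.dpdx) for p in profs)
        assert peak["diabetic"] > peak["anemic"]


class TestWallShearStress:
    def test_plug_profile_zero_stress(self):
        grid = RadialGrid(R=0.01, nr=33)
        from pulsarch.tube_solver import RadialProfile

        u = np.full(33, 0.2)
        u[-1] = 0.0  # no-slip node; interior plug
        prof = RadialProfile(grid=grid, u=u, t=0.0, dpdx=0.0)
        tau = wall_shear_stress(prof, newtonian(0.0035))
        # bounded by the jump resolved over one cell
        assert tau < 0.0035 * 2 * 0.2 / grid.dr
        u_smooth = np.full(33, 0.2)
        prof2 = RadialProfile(grid=grid, u=u_smooth, t=0.0, dpdx=0.0)
        assert wall_shear_stress(prof2, newtonian(0.0035)) < 1e-12


class TestDimensionlessNumbers:
    def test_skin_friction_reference_value(self):
        assert skin_friction(0.28, 1060.0, 0.2) == pytest.approx(0.0132075, rel=1e-4)

    def test_skin_friction_zero_stress(self):
        assert skin_friction(0.0, 1060.0, 0.3) == 0.0

    def test_skin_friction_quarters_when_vref_doubles(self):
        assert skin_friction(0.28, 1060.0, 0.4) == pytest.approx(
            skin_friction(0.28, 1060.0, 0.2) / 4.0
        )

    def test_reynolds_reference_value(self):
        assert reynolds_number(1060.0, 0.5, 0.025, 0.0035) == pytest.approx(
            3785.714, rel=1e-4
        )

    def test_reynolds_scalings(self):
        base = reynolds_number(1060.0, 0.5, 0.025, 0.0035)
        assert reynolds_number(1060.0, 0.5, 0.025, 0.007) == pytest.approx(base / 2)
        assert reynolds_number(1060.0, 0.5, 0.05, 0.0035) > base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            skin_friction(0.28, 1060.0, 0.0)
        with pytest.raises(ValueError):
            reynolds_number(-1.0, 0.5, 0.025, 0.0035)
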