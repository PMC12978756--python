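"""Quick oracle self-checks backing ``pulsarch validate``.

Each check compares a solver path against an independent closed form
at modest resolution; the full test suite runs the same comparisons
more thoroughly.
"""

from __future__ import annotations

import numpy as np

from .cardiac_waveform import WaveformParams, inlet_velocity, mean_inlet_velocity
from .metrics import helicity_field
from .rheology import RheologyParams, default_registry, effective_viscosity
from .synthetic_data import (
    WomersleyReference,
    abc_field,
    womersley_profile,
)
from .tube_solver import solve_pulsatile_tube, solve_steady_tube, wall_shear_stress
from .windkessel import estimate_parameters, initial_state, step


def _newtonian(mu: float) -> RheologyParams:
    return RheologyParams(name="newtonian", k=0.5, lam=1.0, mu0=mu, mu_inf=mu)


def check_rheology() -> tuple[bool, str]:
    reg = default_registry()
    mu0 = effective_viscosity(0.0, reg["diabetic"])
    ok = abs(mu0 - 0.8592) < 1e-15
    return ok, f"diabetic zero-shear plateau = {mu0:.4f} Pa*s"


def check_waveform() -> tuple[bool, str]:
    wf = WaveformParams()
    ok = abs(inlet_velocity(0.35, wf) - 0.1) < 1e-15
    mean = mean_inlet_velocity(wf)
    ok = ok and abs(mean - 0.21235) < 1e-3
    return ok, f"plateau 0.1 m/s, cycle mean {mean:.4f} m/s"


def check_windkessel() -> tuple[bool, str]:
    params = estimate_parameters(13332.0, 1e-4, 1.0)
    state = initial_state(params, Pc0=0.0, Q0=1e-4)
    for _ in range(20000):
        state = step(state, 1e-4, params, dt=0.01)
    target = params.Rtot * 1e-4
    err = abs(state.P - target) / target
    return err < 1e-3, f"steady-state pressure error {err:.2e}"


def check_poiseuille() -> tuple[bool, str]:
    mu, ubar, R = 0.0035, 0.2, 0.01
    prof = solve_steady_tube(R, _newtonian(mu), mean_velocity=ubar, nr=51)
    tau = wall_shear_stress(prof, _newtonian(mu))
    err = abs(tau - 4 * mu * ubar / R) / (4 * mu * ubar / R)
    return err < 1e-3, f"steady wall-shear error {err:.2e}"


def check_womersley() -> tuple[bool, str]:
    ref = WomersleyReference(
        radius=0.0125, density=1060.0, viscosity=0.0035, amplitude=4000.0,
        omega=4.0 * np.pi,
    )
    nr, ncheck = 101, 400
    r = np.linspace(0.0, ref.radius, nr)
    profiles = solve_pulsatile_tube(
        radius=ref.radius,
        rheology=_newtonian(ref.viscosity),
        dpdx_fn=ref.dpdx,
        period=ref.period,
        nr=nr,
        dt=ref.period / ncheck,
        n_cycles=1,
        u0=womersley_profile(ref, r, 0.0),
        store="all",
    )
    p = profiles[ncheck // 2 - 1]
    exact = womersley_profile(ref, r, p.t)
    err = np.linalg.norm(p.u - exact) / np.linalg.norm(exact)
    return err < 0.05, f"oscillatory-flow L2 error {err:.2e} at coarse resolution"


def check_helicity() -> tuple[bool, str]:
    fld = abc_field(32)
    H = helicity_field(fld, periodic=True)
    speed2 = fld.u**2 + fld.v**2 + fld.w**2
    err = float(np.max(np.abs(H - speed2)) / np.max(speed2))
    return err < 0.02, f"Beltrami helicity error {err:.2e}"


def run_all_checks() -> list[tuple[str, bool, str]]:
    checks = [
        ("rheology plateau", check_rheology),
        ("inlet waveform", check_waveform),
        ("windkessel steady state", check_windkessel),
        ("steady tube vs Poiseuille", check_poiseuille),
        ("pulsatile tube vs Womersley", check_womersley),
        ("helicity vs Beltrami", check_helicity),
    ]
    out = []
    for name, fn in checks:
        try:
            ok, detail = fn()
        except Exception as exc:  # pragma: no cover - defensive
            ok, detail = False, f"raised {exc!r}"
        out.append((name, ok, detail))
    return out
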