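"""Axisymmetric pulsatile tube flow with shear-rate-dependent viscosity.

Reduced-order stand-in for the 3D arch: rigid-wall, fully developed
axisymmetric flow, where the convective term vanishes identically and
the axial momentum balance reduces to

    rho du/dt = -dp/dx + (1/r) d/dr ( r mu(|du/dr|) du/dr ),

with no-slip at the wall and symmetry at the axis. The solver
prescribes the cross-section mean velocity (the cardiac waveform) and
recovers the uniform axial pressure gradient as an extra unknown;
alternatively a pressure gradient can be prescribed directly (used
against the analytic oscillatory-flow oracle).

Discretization: node-centered uniform radial grid, finite-volume
fluxes at faces (exact for steady Poiseuille at any resolution),
theta-scheme time stepping (trapezoidal by default, with a fully
implicit first step; theta=1 gives backward Euler), and Picard
(lagged-viscosity) iteration for the nonlinearity. The bordered
system (nodal velocities + dp/dx) is solved with two tridiagonal
solves per Picard pass: u = u_b - dpdx*u_c with the mean-velocity
constraint fixing dpdx.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .cardiac_waveform import WaveformParams, inlet_velocity
from .rheology import RheologyParams, effective_viscosity

__all__ = [
    "RadialGrid",
    "RadialProfile",
    "ConvergenceError",
    "solve_steady_tube",
    "solve_pulsatile_tube",
    "wall_shear_stress",
    "skin_friction",
    "reynolds_number",
]


class ConvergenceError(RuntimeError):
    """Picard iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, history: Sequence[float]):
        super().__init__(message)
        self.history = list(history)


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centered radial grid, r[0] = 0 to r[nr-1] = R."""

    R: float
    nr: int

    def __post_init__(self) -> None:
        if self.R <= 0.0:
            raise ValueError("radius must be positive")
        if self.nr < 16:
            raise ValueError("need at least 16 radial nodes")

    @property
    def r(self) -> np.ndarray:
        return np.linspace(0.0, self.R, self.nr)

    @property
    def dr(self) -> float:
        return self.R / (self.nr - 1)

    @property
    def mean_weights(self) -> np.ndarray:
        """Trapezoid weights w with w @ u = cross-section mean of u.

        mean = (2/R^2) * integral of u(r) r dr over [0, R].
        """
        r = self.r
        w = np.full(self.nr, self.dr)
        w[0] = w[-1] = 0.5 * self.dr
        return (2.0 / self.R**2) * w * r


@dataclass(frozen=True)
class RadialProfile:
    """Axial velocity profile at one time level plus its pressure gradient."""

    grid: RadialGrid
    u: np.ndarray      # m/s at the grid nodes
    t: float           # s
    dpdx: float        # Pa/m (uniform axial pressure gradient)

    def mean_velocity(self) -> float:
        return float(self.grid.mean_weights @ self.u)

    def centerline_velocity(self) -> float:
        return float(self.u[0])


def _face_viscosity(u: np.ndarray, dr: float, rheology: RheologyParams) -> np.ndarray:
    """Effective viscosity at the nr-1 faces from |du/dr| face gradients."""
    shear = np.abs(np.diff(u)) / dr
    return np.asarray(effective_viscosity(shear, rheology), dtype=float)


def _apply_operator(grid: RadialGrid, nu_face: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Apply the diffusion operator L u = (1/r) d/dr(r nu du/dr) at the
    nr-1 non-wall nodes (finite-volume form, wall value included in u)."""
    nr, dr = grid.nr, grid.dr
    n = nr - 1
    r_face = (np.arange(nr - 1) + 0.5) * dr
    vol = grid.r[:n] * dr
    vol[0] = dr * dr / 8.0
    flux = r_face * nu_face * np.diff(u) / dr
    out = np.empty(n)
    out[0] = flux[0] / vol[0]
    out[1:] = (flux[1:] - flux[:-1]) / vol[1:]
    return out


def _assemble_tridiag(
    grid: RadialGrid,
    mu_face: np.ndarray,
    rho_over_dt: float,
) -> np.ndarray:
    """Banded matrix (ab form) for the interior+axis unknowns u[0..nr-2].

    Row j encodes rho_over_dt*u_j - (1/Vol_j)*(F_{j+1/2} - F_{j-1/2})
    with fluxes F = r_f * mu_f * (u_{j+1}-u_j)/dr; the wall value
    u[nr-1] = 0 is eliminated. rho_over_dt = 0 gives the steady
    operator, which stays regular thanks to the Dirichlet wall row.
    """
    nr, dr = grid.nr, grid.dr
    n = nr - 1  # unknowns u[0..nr-2]
    r_face = (np.arange(nr - 1) + 0.5) * dr
    # control volumes: axis cell [0, dr/2]: dr^2/8; interior node j: r_j*dr
    vol = grid.r[:n] * dr
    vol[0] = dr * dr / 8.0
    cond = r_face * mu_face / dr  # conductance of each face

    lower = np.zeros(n)
    diag = np.full(n, rho_over_dt)
    upper = np.zeros(n)
    # axis node: only east face
    diag[0] += cond[0] / vol[0]
    upper[0] = -cond[0] / vol[0]
    j = np.arange(1, n)
    diag[j] += (cond[j] + cond[j - 1]) / vol[j]
    upper[j[:-1]] = -cond[j[:-1]] / vol[j[:-1]]   # east neighbours for j=1..n-2
    lower[j] = -cond[j - 1] / vol[j]
    # last unknown j = n-1 couples east to the wall (u=0): no upper entry.

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return ab


def _solve_constrained(
    grid: RadialGrid,
    mu_face: np.ndarray,
    rho_over_dt: float,
    rhs_time: np.ndarray,
    target_mean: float,
) -> tuple[np.ndarray, float]:
    """One linear pass: solve for (u, dpdx) with mean(u) = target_mean.

    The momentum rows read A u = rhs_time - dpdx/rho_units; writing
    u = u_b - dpdx*u_c with A u_b = rhs_time, A u_c = 1/rho_units,
    the mean constraint fixes dpdx. rhs entries are in acceleration
    units (m/s^2) after dividing momentum by rho.
    """
    ab = _assemble_tridiag(grid, mu_face, rho_over_dt)
    n = grid.nr - 1
    ones = np.ones(n)
    u_b = solve_banded((1, 1), ab, rhs_time)
    u_c = solve_banded((1, 1), ab, ones)
    w = grid.mean_weights[:n]  # wall weight multiplies u=0
    mean_b = float(w @ u_b)
    mean_c = float(w @ u_c)
    dpdx_over_rho = (mean_b - target_mean) / mean_c
    u = np.empty(grid.nr)
    u[:n] = u_b - dpdx_over_rho * u_c
    u[-1] = 0.0
    return u, dpdx_over_rho


def _solve_prescribed(
    grid: RadialGrid,
    mu_face: np.ndarray,
    rho_over_dt: float,
    rhs_time: np.ndarray,
    dpdx_over_rho: float,
) -> np.ndarray:
    ab = _assemble_tridiag(grid, mu_face, rho_over_dt)
    n = grid.nr - 1
    u = np.empty(grid.nr)
    u[:n] = solve_banded((1, 1), ab, rhs_time - dpdx_over_rho)
    u[-1] = 0.0
    return u


def _picard(
    grid: RadialGrid,
    rheology: RheologyParams,
    u_guess: np.ndarray,
    rho_over_dt: float,
    rhs_time: np.ndarray,
    target_mean: float | None,
    dpdx: float | None,
    tol: float,
    max_iters: int,
    th: float = 1.0,
) -> tuple[np.ndarray, float, int]:
    """Lagged-viscosity iteration; returns (u, dpdx, n_iters).

    The caller passes the theta-divided system (diagonal shift
    1/(th*dt), right-hand side rhs_time/th); the source seen by that
    system is dpdx/(rho*th), hence the th factors below.
    """
    rho = rheology.density
    u = u_guess.copy()
    newtonian = rheology.mu0 == rheology.mu_inf
    history: list[float] = []
    for it in range(1, max_iters + 1):
        # momentum divided through by rho: kinematic face viscosities
        nu_face = _face_viscosity(u, grid.dr, rheology) / rho
        if target_mean is not None:
            u_new, dpdx_over_rho = _solve_constrained(
                grid, nu_face, rho_over_dt, rhs_time, target_mean
            )
            dpdx_new = dpdx_over_rho * rho * th
        else:
            assert dpdx is not None
            u_new = _solve_prescribed(
                grid, nu_face, rho_over_dt, rhs_time, dpdx / (rho * th)
            )
            dpdx_new = dpdx
        scale = max(np.max(np.abs(u_new)), 1e-300)
        res = float(np.max(np.abs(u_new - u)) / scale)
        history.append(res)
        u = u_new
        if newtonian or res < tol:
            return u, dpdx_new, it
    raise ConvergenceError(
        f"viscosity iteration did not reach tol={tol} in {max_iters} passes "
        f"(last residual {history[-1]:.3e})",
        history,
    )


def solve_steady_tube(
    radius: float,
    rheology: RheologyParams,
    mean_velocity: float | None = None,
    dpdx: float | None = None,
    nr: int = 101,
    tol: float = 1e-10,
    max_iters: int = 100,
) -> RadialProfile:
    """Steady fully developed profile, driven by mean velocity or dp/dx.

    For constant viscosity the finite-volume fluxes are exact for the
    parabolic solution, so Poiseuille is recovered nodally to rounding
    error at any resolution.
    """
    if (mean_velocity is None) == (dpdx is None):
        raise ValueError("specify exactly one of mean_velocity or dpdx")
    grid = RadialGrid(R=radius, nr=nr)
    if mean_velocity is not None:
        # start from the parabola with the right mean
        u0 = 2.0 * mean_velocity * (1.0 - (grid.r / radius) ** 2)
    else:
        u0 = (-dpdx / (4.0 * rheology.mu0)) * (radius**2 - grid.r**2)
    rhs = np.zeros(grid.nr - 1)
    u, dpdx_out, _ = _picard(
        grid, rheology, u0, 0.0, rhs, mean_velocity, dpdx, tol, max_iters
    )
    return RadialProfile(grid=grid, u=u, t=0.0, dpdx=dpdx_out)


def solve_pulsatile_tube(
    radius: float,
    rheology: RheologyParams,
    waveform: WaveformParams | None = None,
    nr: int = 101,
    dt: float | None = None,
    n_cycles: int = 8,
    dpdx_fn: Callable[[float], float] | None = None,
    period: float | None = None,
    u0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iters: int = 50,
    store: str = "last_cycle",
    theta: float = 0.5,
) -> list[RadialProfile]:
    """Time-march the pulsatile tube problem; returns stored profiles.

    Two driving modes:

    * waveform mode (default): the cross-section mean velocity is
      prescribed by ``waveform`` at each step and dp/dx is solved for.
      The march starts from the steady profile at the cycle-mean
      velocity unless ``u0`` is given, which shortens the viscous
      transient considerably.
    * prescribed-gradient mode: ``dpdx_fn(t)`` gives dp/dx and
      ``period`` the cycle length (oracle testing).

    ``theta`` selects the time scheme: 0.5 (default) is trapezoidal
    (second order, with a fully implicit first step), 1.0 is backward
    Euler. ``store`` is "last_cycle", "last_two_cycles" or "all".
    """
    if (waveform is None) == (dpdx_fn is None):
        raise ValueError("specify exactly one of waveform or dpdx_fn")
    if waveform is not None:
        period = waveform.period
    if period is None or period <= 0.0:
        raise ValueError("prescribed-gradient mode needs a positive period")
    if dt is None:
        dt = period / 1000.0
    if dt <= 0.0 or n_cycles < 1:
        raise ValueError("dt must be positive and n_cycles >= 1")
    if not (0.5 <= theta <= 1.0):
        raise ValueError("theta must lie in [0.5, 1]")
    grid = RadialGrid(R=radius, nr=nr)
    steps_per_cycle = int(round(period / dt))
    if abs(steps_per_cycle * dt - period) > 1e-9 * period:
        raise ValueError("dt must divide the period")
    n_steps = steps_per_cycle * n_cycles

    if u0 is not None:
        u = np.asarray(u0, dtype=float).copy()
        if u.shape != (nr,):
            raise ValueError("u0 must have nr entries")
    elif waveform is not None:
        from .cardiac_waveform import mean_inlet_velocity

        u = solve_steady_tube(
            radius, rheology, mean_velocity=mean_inlet_velocity(waveform), nr=nr
        ).u
    else:
        u = np.zeros(nr)

    first_stored = {
        "all": 0,
        "last_cycle": n_steps - steps_per_cycle,
        "last_two_cycles": n_steps - 2 * steps_per_cycle,
    }.get(store)
    if first_stored is None:
        raise ValueError(f"unknown store mode {store!r}")
    first_stored = max(first_stored, 0)

    rho = rheology.density
    profiles: list[RadialProfile] = []
    for step_i in range(1, n_steps + 1):
        t_old = (step_i - 1) * dt
        t_new = step_i * dt
        # fully implicit first step, theta-weighted afterwards; the
        # pressure-gradient source lives at the theta-point of the step
        # (implicit midpoint for theta = 1/2), which keeps second-order
        # accuracy without an explicit old-source term — an explicit
        # dp/dx term rings undamped after waveform slope breaks.
        th = 1.0 if step_i == 1 else theta
        rhs_time = u[: nr - 1] / dt
        if th < 1.0:
            nu_old = _face_viscosity(u, grid.dr, rheology) / rho
            rhs_time = rhs_time + (1.0 - th) * _apply_operator(grid, nu_old, u)
        if waveform is not None:
            target = inlet_velocity(t_new, waveform)
            u, dpdx_out, _ = _picard(
                grid, rheology, u, 1.0 / (th * dt), rhs_time / th,
                target, None, tol, max_iters, th,
            )
        else:
            g = float(dpdx_fn(t_old + th * dt))
            u, dpdx_out, _ = _picard(
                grid, rheology, u, 1.0 / (th * dt), rhs_time / th,
                None, g, tol, max_iters, th,
            )
        if step_i - 1 >= first_stored:
            profiles.append(RadialProfile(grid=grid, u=u.copy(), t=t_new, dpdx=dpdx_out))
    return profiles


def wall_shear_stress(profile: RadialProfile, rheology: RheologyParams) -> float:
    """Wall shear stress magnitude, Pa.

    One-sided second-order difference for du/dr at the wall (exact for
    parabolic profiles), with the effective viscosity evaluated at the
    wall shear rate.
    """
    grid, u = profile.grid, profile.u
    if grid.nr < 3:
        raise ValueError("need at least 3 near-wall nodes")
    dr = grid.dr
    if not np.isfinite(dr) or dr <= 0.0:
        raise ValueError("degenerate grid spacing")
    dudr_wall = (3.0 * u[-1] - 4.0 * u[-2] + u[-3]) / (2.0 * dr)
    shear = abs(dudr_wall)
    mu_w = effective_viscosity(shear, rheology)
    return float(mu_w * shear)


def skin_friction(tau_w: float, density: float, v_ref: float) -> float:
    """Skin-friction coefficient Cf = tau_w / (0.5 * rho * v_ref^2)."""
    if density <= 0.0 or v_ref <= 0.0:
        raise ValueError("density and reference velocity must be positive")
    return tau_w / (0.5 * density * v_ref**2)


def reynolds_number(density: float, v_peak: float, diameter: float, mu_ref: float) -> float:
    """Reynolds number rho*v*D/mu from peak velocity and vessel diameter."""
    if min(density, v_peak, diameter, mu_ref) <= 0.0:
        raise ValueError("all Reynolds inputs must be positive")
    return density * v_peak * diameter / mu_ref
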