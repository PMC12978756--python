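"""Closed-form reference flows and idealized network generators.

Everything the pipeline and its tests consume is generated here with
no external data: the oscillatory (Womersley) and steady (Poiseuille)
pipe-flow solutions that serve as solver oracles, the ABC Beltrami
field whose helicity equals its squared speed, solid-body rotation,
and the default four-branch arch network. All generators are
deterministic closed forms; regeneration is bitwise stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from . import windkessel
from .cardiac_waveform import WaveformParams, mean_inlet_velocity
from .metrics import GriddedField

__all__ = [
    "WomersleyReference",
    "womersley_profile",
    "womersley_mean_velocity",
    "poiseuille_profile",
    "abc_field",
    "solid_body_rotation_field",
    "make_default_network",
]


@dataclass(frozen=True)
class WomersleyReference:
    """Oscillatory pipe flow driven by dp/dx = -amplitude*cos(omega*t).

    The complex solution is
        u(r, t) = Re{ c * (1 - J0(k r)/J0(k R)) * exp(i omega t) },
    with c = -i*amplitude/(rho*omega) and k^2 = -i*omega*rho/mu. The
    Womersley number alpha = R*sqrt(omega*rho/mu) measures pulsatility;
    as alpha -> 0 the profile approaches quasi-steady Poiseuille with
    the instantaneous pressure gradient.
    """

    radius: float       # m
    density: float      # kg/m^3
    viscosity: float    # Pa·s (constant)
    amplitude: float    # Pa/m, pressure-gradient amplitude
    omega: float        # rad/s

    def __post_init__(self) -> None:
        if min(self.radius, self.density, self.viscosity, self.omega) <= 0.0:
            raise ValueError("radius, density, viscosity and omega must be positive")

    @property
    def alpha(self) -> float:
        """Womersley number R*sqrt(omega*rho/mu)."""
        return self.radius * math.sqrt(self.omega * self.density / self.viscosity)

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    def dpdx(self, t: float) -> float:
        return -self.amplitude * math.cos(self.omega * t)


def _womersley_complex(ref: WomersleyReference, r: np.ndarray) -> np.ndarray:
    k = np.sqrt(-1j * ref.omega * ref.density / ref.viscosity)
    c = -1j * ref.amplitude / (ref.density * ref.omega)
    return c * (1.0 - jv(0, k * r) / jv(0, k * ref.radius))


def womersley_profile(ref: WomersleyReference, r, t: float) -> np.ndarray:
    """Analytic axial velocity at radii ``r`` and time ``t`` (m/s).

    Depends on r only through r^2 (Bessel J0 is even), so the profile
    is axisymmetric; satisfies no-slip at r = R exactly.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(np.abs(r_arr) > ref.radius * (1.0 + 1e-12)):
        raise ValueError("radii must lie in [-R, R]")
    u_hat = _womersley_complex(ref, np.abs(r_arr))
    u = np.real(u_hat * np.exp(1j * ref.omega * t))
    return u if np.ndim(r) else float(u[0])


def womersley_wall_shear(ref: WomersleyReference, t: float) -> float:
    """Analytic wall shear stress magnitude at time t, Pa.

    du/dr = Re{ c k J1(k r)/J0(k R) e^{i omega t} } (J0' = -J1), so the
    wall value follows in closed form.
    """
    k = np.sqrt(-1j * ref.omega * ref.density / ref.viscosity)
    c = -1j * ref.amplitude / (ref.density * ref.omega)
    dudr = np.real(
        c * k * jv(1, k * ref.radius) / jv(0, k * ref.radius) * np.exp(1j * ref.omega * t)
    )
    return float(abs(ref.viscosity * dudr))


def womersley_mean_velocity(ref: WomersleyReference, t: float) -> float:
    """Analytic cross-section mean of the oscillatory profile at time t.

    Uses the Bessel identity  integral of J0(k r) r dr = R J1(k R)/k,
    giving  mean = Re{ c (1 - 2 J1(kR)/(kR J0(kR))) e^{i omega t} }.
    """
    k = np.sqrt(-1j * ref.omega * ref.density / ref.viscosity)
    c = -1j * ref.amplitude / (ref.density * ref.omega)
    kR = k * ref.radius
    mean_hat = c * (1.0 - 2.0 * jv(1, kR) / (kR * jv(0, kR)))
    return float(np.real(mean_hat * np.exp(1j * ref.omega * t)))


def poiseuille_profile(radius: float, viscosity: float, dpdx: float, r) -> np.ndarray:
    """Steady parabolic profile u(r) = (-dpdx/(4 mu)) (R^2 - r^2)."""
    if viscosity <= 0.0 or radius <= 0.0:
        raise ValueError("radius and viscosity must be positive")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > radius * (1.0 + 1e-12)):
        raise ValueError("radii must lie in [-R, R]")
    u = (-dpdx / (4.0 * viscosity)) * (radius**2 - r_arr**2)
    return u if np.ndim(r) else float(u)


def _periodic_axes(n: int) -> np.ndarray:
    # [0, 2*pi) sampled without the duplicate endpoint -> exactly periodic
    return np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)


def abc_field(n: int, A: float = 1.0, B: float = 1.0, C: float = 1.0) -> GriddedField:
    """Arnold–Beltrami–Childress flow on the periodic cube [0, 2*pi)^3.

    u = A sin z + C cos y, v = B sin x + A cos z, w = C sin y + B cos x.
    Divergence-free with curl equal to the field itself, so the
    pointwise helicity equals |u|^2 — the standard helicity oracle.
    """
    if n < 8:
        raise ValueError("need at least 8 points per axis")
    ax = _periodic_axes(n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return GriddedField(
        spacing=(ax[1], ax[1], ax[1]),
        u=A * np.sin(z) + C * np.cos(y),
        v=B * np.sin(x) + A * np.cos(z),
        w=C * np.sin(y) + B * np.cos(x),
    )


def solid_body_rotation_field(n: int, omega: float = 1.0, extent: float = 1.0) -> GriddedField:
    """Rigid rotation about the z axis: u = (-omega*y, omega*x, 0).

    Velocity is everywhere perpendicular to the (constant, axial)
    vorticity, so the helicity vanishes identically.
    """
    if n < 3:
        raise ValueError("need at least 3 points per axis")
    ax = np.linspace(-extent, extent, n)
    h = ax[1] - ax[0]
    x, y, _ = np.meshgrid(ax, ax, ax, indexing="ij")
    zeros = np.zeros_like(x)
    return GriddedField(spacing=(h, h, h), u=-omega * y, v=omega * x, w=zeros)


# Default arch network dimensions (m) and mean-flow fractions.
# The branch split (brachiocephalic 0.15, left carotid 0.075, left
# subclavian 0.075, descending aorta 0.70) and the radii are documented
# package defaults at adult-aorta scale, not literature-verbatim values.
DEFAULT_INLET_RADIUS = 0.0125
DEFAULT_BRANCHES = (
    ("O1 brachiocephalic", 0.006, 0.15),
    ("O2 left carotid", 0.004, 0.075),
    ("O3 left subclavian", 0.004, 0.075),
    ("O4 descending aorta", 0.0105, 0.70),
)


def make_default_network(
    waveform: WaveformParams | None = None,
    mean_pressure: float = windkessel.DEFAULT_MEAN_PRESSURE,
    tau: float = windkessel.DEFAULT_TAU,
):
    """Idealized four-outlet arch network with estimated RCR outlets.

    Windkessel constants per branch come from the 5%/95% resistance
    split at the given mean pressure, with the branch mean flow taken
    from the waveform cycle average and the branch flow fraction.
    """
    from .arch_pipeline import ArchNetwork, BranchSpec

    wf = waveform if waveform is not None else WaveformParams()
    v_mean = mean_inlet_velocity(wf)
    Q_in_mean = v_mean * math.pi * DEFAULT_INLET_RADIUS**2
    branches = []
    for name, radius, frac in DEFAULT_BRANCHES:
        wk = windkessel.estimate_parameters(
            mean_pressure=mean_pressure, mean_flow=frac * Q_in_mean, tau=tau
        )
        branches.append(
            BranchSpec(name=name, radius=radius, flow_fraction=frac, windkessel=wk)
        )
    return ArchNetwork(inlet_radius=DEFAULT_INLET_RADIUS, branches=tuple(branches))
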