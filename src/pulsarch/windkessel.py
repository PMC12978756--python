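"""Three-element Windkessel (RCR) outlet model.

Each outlet is terminated by a proximal resistance R1 in series with a
parallel distal resistance R2 / compliance C pair. The outlet pressure
is P(t) = Pc(t) + R1*Q(t), where the capacitor pressure obeys

    C dPc/dt = Q(t) - Pc/R2.

The discrete update is backward Euler with beta = R2*C/dt:

    P_new = [beta*P + Q_new*(R2 + R1 + R1*beta) - R1*beta*Q] / (1 + beta)

equivalently Pc_new = (beta*Pc + R2*Q_new) / (1 + beta); the two forms
are algebraically identical. Note the dimensionless beta requires
dividing by dt (a product R2*C*dt would carry units of s^2); the
division makes the update the exact backward-Euler discretization of
the RCR ODE and unconditionally stable for any dt.

Parameters are estimated from a branch's mean pressure and mean flow:
Rtot = Pmean/Qmean, split 5%/95% proximal/distal, with compliance set
by the diastolic decay constant tau = R2*C (default 1.0 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "estimate_parameters",
    "step",
    "simulate",
]

#: Default branch mean pressure for parameter estimation, Pa (~100 mmHg).
DEFAULT_MEAN_PRESSURE = 13332.0
#: Default diastolic decay constant tau = R2*C, s.
DEFAULT_TAU = 1.0
#: Proximal share of the total resistance.
PROXIMAL_FRACTION = 0.05


@dataclass(frozen=True)
class WindkesselParams:
    """RCR constants: resistances in Pa·s/m^3, compliance in m^3/Pa."""

    R1: float
    R2: float
    C: float

    def __post_init__(self) -> None:
        if self.R1 <= 0.0 or self.R2 <= 0.0 or self.C <= 0.0:
            raise ValueError("R1, R2 and C must all be positive")

    @property
    def Rtot(self) -> float:
        return self.R1 + self.R2

    @property
    def tau(self) -> float:
        """Diastolic decay constant R2*C, s."""
        return self.R2 * self.C

    def to_dict(self) -> dict:
        return {"R1": self.R1, "R2": self.R2, "C": self.C}

    @classmethod
    def from_dict(cls, d) -> "WindkesselParams":
        return cls(R1=float(d["R1"]), R2=float(d["R2"]), C=float(d["C"]))


@dataclass(frozen=True)
class WindkesselState:
    """Outlet state: P = Pc + R1*Q holds at every accepted step."""

    P: float   # outlet pressure, Pa
    Pc: float  # capacitor pressure, Pa
    Q: float   # last applied flow, m^3/s
    t: float   # time, s


def estimate_parameters(
    mean_pressure: float = DEFAULT_MEAN_PRESSURE,
    mean_flow: float = 1e-4,
    tau: float = DEFAULT_TAU,
) -> WindkesselParams:
    """RCR constants from a branch's mean pressure and mean flow.

    Rtot = mean_pressure/mean_flow, R1 = 0.05*Rtot, R2 = 0.95*Rtot,
    C = tau/R2 (so C*R2 = tau exactly).
    """
    if mean_pressure <= 0.0 or mean_flow <= 0.0 or tau <= 0.0:
        raise ValueError("mean_pressure, mean_flow and tau must be positive")
    Rtot = mean_pressure / mean_flow
    R1 = PROXIMAL_FRACTION * Rtot
    R2 = (1.0 - PROXIMAL_FRACTION) * Rtot
    return WindkesselParams(R1=R1, R2=R2, C=tau / R2)


def initial_state(params: WindkesselParams, Pc0: float, Q0: float = 0.0, t0: float = 0.0) -> WindkesselState:
    """Consistent state with capacitor pressure Pc0 and flow Q0."""
    return WindkesselState(P=Pc0 + params.R1 * Q0, Pc=Pc0, Q=Q0, t=t0)


def step(
    state: WindkesselState,
    Q_new: float,
    params: WindkesselParams,
    dt: float,
    form: str = "pressure",
) -> WindkesselState:
    """Advance the outlet state one backward-Euler step of size dt.

    ``form`` selects the algebraic route: "pressure" applies the update
    directly to P; "capacitor" updates Pc and reconstructs P. The two
    are identical to rounding error and both keep P = Pc + R1*Q.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    beta = params.R2 * params.C / dt
    if form == "pressure":
        P_new = (
            beta * state.P
            + Q_new * (params.R2 + params.R1 + params.R1 * beta)
            - params.R1 * beta * state.Q
        ) / (1.0 + beta)
        Pc_new = P_new - params.R1 * Q_new
    elif form == "capacitor":
        Pc_new = (beta * state.Pc + params.R2 * Q_new) / (1.0 + beta)
        P_new = Pc_new + params.R1 * Q_new
    else:
        raise ValueError(f"unknown update form {form!r}")
    return WindkesselState(P=P_new, Pc=Pc_new, Q=Q_new, t=state.t + dt)


def simulate(
    times,
    flows,
    params: WindkesselParams,
    Pc0: float = DEFAULT_MEAN_PRESSURE,
    form: str = "pressure",
) -> pd.DataFrame:
    """Drive the outlet with a sampled flow series Q(t).

    ``times`` must be strictly increasing and uniformly spaced; the
    state starts at (times[0], flows[0]) with capacitor pressure Pc0
    and is stepped through the remaining samples. Returns a DataFrame
    with columns ``t_s``, ``P_Pa``, ``Pc_Pa``, ``Q_m3_per_s``.
    """
    t = np.asarray(times, dtype=float)
    Q = np.asarray(flows, dtype=float)
    if t.ndim != 1 or t.shape != Q.shape or t.size < 2:
        raise ValueError("times and flows must be 1-D arrays of equal length >= 2")
    dts = np.diff(t)
    if np.any(dts <= 0.0):
        raise ValueError("times must be strictly increasing")
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-9, atol=0.0):
        raise ValueError("time grid must be uniform")

    state = initial_state(params, Pc0=Pc0, Q0=Q[0], t0=t[0])
    P = np.empty_like(Q)
    Pc = np.empty_like(Q)
    P[0], Pc[0] = state.P, state.Pc
    beta = params.R2 * params.C / dt
    a = beta / (1.0 + beta)
    b = params.R2 / (1.0 + beta)
    if form == "capacitor":
        pc = state.Pc
        for i in range(1, t.size):
            pc = a * pc + b * Q[i]
            Pc[i] = pc
        P[1:] = Pc[1:] + params.R1 * Q[1:]
    else:
        for i in range(1, t.size):
            state = step(state, Q[i], params, dt, form=form)
            P[i], Pc[i] = state.P, state.Pc
    return pd.DataFrame({"t_s": t, "P_Pa": P, "Pc_Pa": Pc, "Q_m3_per_s": Q})
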