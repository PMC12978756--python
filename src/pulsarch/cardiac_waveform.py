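"""Pulsatile inlet waveform: piecewise sinusoid (systole) + plateau (diastole).

The cross-section mean inlet velocity over one 0.5 s cardiac cycle
(120 beats/min) is

    v(t) = amplitude * sin(angular_factor * (tau + phase_offset))   0 < tau <= systole_end
    v(t) = diastolic_level                                          systole_end < tau <= period

with tau the in-cycle time. The default constants (amplitude 0.5 m/s,
4*pi rad/s, 0.016 s phase offset, systole ending at 0.218 s, 0.1 m/s
diastolic plateau) make the waveform nearly continuous at both segment
junctions. The waveform extends periodically to all real t; in-cycle
time tau = 0 maps to the diastolic branch of the previous cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WaveformParams", "inlet_velocity", "mean_inlet_velocity", "waveform_trace"]


@dataclass(frozen=True)
class WaveformParams:
    """Constants of the piecewise inlet waveform (SI units)."""

    period: float = 0.5            # s
    systole_end: float = 0.218     # s, within the cycle
    amplitude: float = 0.5         # m/s
    diastolic_level: float = 0.1   # m/s
    phase_offset: float = 0.016    # s
    angular_factor: float = 4.0 * math.pi  # rad/s

    def __post_init__(self) -> None:
        if not (0.0 < self.systole_end < self.period):
            raise ValueError("need 0 < systole_end < period")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be non-negative")
        if self.diastolic_level < 0.0:
            raise ValueError("diastolic_level must be non-negative")

    def scaled(self, factor: float) -> "WaveformParams":
        """Waveform with velocities scaled by `factor` (same timing).

        The waveform is linear in (amplitude, diastolic_level), so
        scaling both rescales v(t) pointwise — used to convert the
        inlet mean velocity into a branch mean velocity.
        """
        if factor <= 0.0:
            raise ValueError("scale factor must be positive")
        return WaveformParams(
            period=self.period,
            systole_end=self.systole_end,
            amplitude=self.amplitude * factor,
            diastolic_level=self.diastolic_level * factor,
            phase_offset=self.phase_offset,
            angular_factor=self.angular_factor,
        )

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "systole_end": self.systole_end,
            "amplitude": self.amplitude,
            "diastolic_level": self.diastolic_level,
            "phase_offset": self.phase_offset,
            "angular_factor": self.angular_factor,
        }

    @classmethod
    def from_dict(cls, d) -> "WaveformParams":
        return cls(**{k: float(v) for k, v in d.items()})


def inlet_velocity(t, params: WaveformParams = WaveformParams()):
    """Inlet mean velocity v(t) in m/s; scalar or array t in seconds.

    Periodic in ``params.period``; any real t (including negative) is
    folded into the cycle. tau = 0 belongs to the diastolic branch.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time must be finite")
    if params.amplitude == 0.0:
        # degenerate constant waveform (no systolic ejection)
        v = np.full_like(t_arr, params.diastolic_level)
        return float(v) if np.ndim(t) == 0 else v
    tau = t_arr - params.period * np.floor(t_arr / params.period)
    in_systole = (tau > 0.0) & (tau <= params.systole_end)
    v = np.where(
        in_systole,
        params.amplitude * np.sin(params.angular_factor * (tau + params.phase_offset)),
        params.diastolic_level,
    )
    if np.ndim(t) == 0:
        return float(v)
    return v


def mean_inlet_velocity(params: WaveformParams = WaveformParams()) -> float:
    """Cycle-average of the inlet waveform, m/s (exact integral).

    The sinusoidal segment integrates in closed form,
    (A/w)[cos(w*phi) - cos(w*(Ts+phi))], and the plateau contributes
    diastolic_level*(T - Ts); for the default constants the mean is
    about 0.2124 m/s. Used to size Windkessel total resistances.
    """
    if params.amplitude == 0.0:
        return params.diastolic_level  # degenerate constant waveform
    A, w = params.amplitude, params.angular_factor
    Ts, T, phi = params.systole_end, params.period, params.phase_offset
    sin_part = (A / w) * (math.cos(w * phi) - math.cos(w * (Ts + phi)))
    plateau_part = params.diastolic_level * (T - Ts)
    return (sin_part + plateau_part) / T


def waveform_trace(
    params: WaveformParams, dt: float, n_cycles: int
) -> pd.DataFrame:
    """Uniformly sampled waveform over ``n_cycles`` periods.

    Samples at t = dt, 2*dt, ..., n_cycles*period (each cycle sampled
    on its half-open interval (0, T], matching the piecewise
    definition). Returns columns ``t_s`` and ``v_m_per_s``.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if dt >= params.period:
        raise ValueError("dt must be smaller than the period")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    n_per = int(round(params.period / dt))
    n = (
        n_per * n_cycles
        if abs(n_per * dt - params.period) < 1e-12 * params.period
        else int(math.floor(n_cycles * params.period / dt))
    )
    t = dt * np.arange(1, n + 1)
    return pd.DataFrame({"t_s": t, "v_m_per_s": inlet_velocity(t, params)})
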