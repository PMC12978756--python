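"""Idealized arch pipeline: four Windkessel-terminated branches.

The inlet waveform sets the volumetric inflow
Q_in(t) = v(t) * pi * R_inlet^2, which is split among the four outlet
branches by fixed mean-flow fractions (mass is conserved at the
junction exactly, by construction). Each branch carries its share as
fully developed pulsatile tube flow — yielding velocity profiles,
pressure gradients and wall shear stress — and feeds its flow into a
three-element Windkessel that returns the outlet pressure trace.
The reported cycle is the last of ``n_cycles``, after a periodicity
check against its predecessor.

The whole pipeline is deterministic: identical configurations produce
bitwise-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import windkessel as wk
from .cardiac_waveform import WaveformParams, inlet_velocity
from .metrics import (
    MetricSummary,
    SeverityBands,
    SeverityReport,
    classify,
    default_pressure_bands,
    default_wss_bands,
    summarize,
)
from .rheology import ConditionRegistry, default_registry
from .tube_solver import ConvergenceError, solve_pulsatile_tube, wall_shear_stress

__all__ = [
    "BranchSpec",
    "ArchNetwork",
    "NumericsConfig",
    "BranchResult",
    "ConditionReport",
    "PipelineConfig",
    "run_condition",
    "run_all",
]


@dataclass(frozen=True)
class BranchSpec:
    """One outlet branch: geometry, mean-flow share, RCR termination."""

    name: str
    radius: float
    flow_fraction: float
    windkessel: wk.WindkesselParams

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise ValueError(f"{self.name}: radius must be positive")
        if not (0.0 < self.flow_fraction < 1.0):
            raise ValueError(f"{self.name}: flow fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ArchNetwork:
    """Inlet plus four outlet branches; flow fractions sum to one."""

    inlet_radius: float
    branches: tuple[BranchSpec, ...]

    def __post_init__(self) -> None:
        if self.inlet_radius <= 0.0:
            raise ValueError("inlet radius must be positive")
        total = sum(b.flow_fraction for b in self.branches)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"flow fractions must sum to 1, got {total!r}")

    @property
    def inlet_area(self) -> float:
        return math.pi * self.inlet_radius**2


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization of the per-branch tube solves and RCR updates."""

    nr: int = 101
    dt: float | None = None       # s; None -> period/1000
    n_cycles: int = 8
    tol: float = 1e-8
    max_iters: int = 50
    Pc0: float = wk.DEFAULT_MEAN_PRESSURE

    def resolve_dt(self, period: float) -> float:
        return period / 1000.0 if self.dt is None else self.dt


@dataclass(frozen=True)
class BranchResult:
    """Last-cycle traces for one branch plus its periodicity residuals.

    ``trace`` columns: t_s, Q_m3_per_s, v_m_per_s (cross-section mean),
    P_Pa, Pc_Pa, wss_Pa, dpdx_Pa_per_m. ``periodicity`` maps quantity
    name to the relative L-infinity difference between the reported
    cycle and its predecessor.
    """

    spec: BranchSpec
    trace: pd.DataFrame
    periodicity: Mapping[str, float]


@dataclass(frozen=True)
class ConditionReport:
    """One blood condition's pipeline output.

    Summaries pool the last-cycle traces of all branches; severity
    reports apply the (illustrative) classification bands.
    """

    condition: str
    branches: tuple[BranchResult, ...]
    summaries: Mapping[str, MetricSummary]
    severity: Mapping[str, SeverityReport]

    def max_periodicity_residual(self) -> float:
        return max(
            res for b in self.branches for res in b.periodicity.values()
        )

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "summaries": {q: s.to_dict() for q, s in self.summaries.items()},
            "severity": {q: r.to_dict() for q, r in self.severity.items()},
            "periodicity_residuals": {
                b.spec.name: dict(b.periodicity) for b in self.branches
            },
            "branches": [
                {
                    "name": b.spec.name,
                    "radius_m": b.spec.radius,
                    "flow_fraction": b.spec.flow_fraction,
                    "windkessel": b.spec.windkessel.to_dict(),
                }
                for b in self.branches
            ],
            "note": "branch radii and flow fractions are package defaults unless configured",
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def traces_to_csv(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for b in self.branches:
            slug = b.spec.name.split()[0].lower()
            path = out / f"{self.condition}_{slug}_trace.csv"
            b.trace.to_csv(path, index=False)
            written.append(path)
        return written


def _rel_linf(last: np.ndarray, prev: np.ndarray) -> float:
    scale = float(np.max(np.abs(last)))
    if scale == 0.0:
        return float(np.max(np.abs(last - prev)))
    return float(np.max(np.abs(last - prev)) / scale)


def run_condition(
    condition: str,
    network: ArchNetwork,
    waveform: WaveformParams | None = None,
    numerics: NumericsConfig | None = None,
    registry: ConditionRegistry | None = None,
    wss_bands: SeverityBands | None = None,
    pressure_bands: SeverityBands | None = None,
) -> ConditionReport:
    """Simulate one blood condition through the arch network."""
    registry = registry if registry is not None else default_registry()
    waveform = waveform if waveform is not None else WaveformParams()
    numerics = numerics if numerics is not None else NumericsConfig()
    rheology = registry[condition]
    dt = numerics.resolve_dt(waveform.period)
    steps = int(round(waveform.period / dt))

    # full time grid for the Windkessel drive (t = 0 .. n_cycles*T)
    t_full = dt * np.arange(numerics.n_cycles * steps + 1)
    v_in_full = inlet_velocity(t_full, waveform)
    Q_in_full = v_in_full * network.inlet_area

    results = []
    for spec in network.branches:
        area = math.pi * spec.radius**2
        # branch mean velocity = fraction * Q_in / branch area
        factor = spec.flow_fraction * network.inlet_area / area
        try:
            profiles = solve_pulsatile_tube(
                radius=spec.radius,
                rheology=rheology,
                waveform=waveform.scaled(factor),
                nr=numerics.nr,
                dt=dt,
                n_cycles=numerics.n_cycles,
                tol=numerics.tol,
                max_iters=numerics.max_iters,
                store="last_two_cycles",
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"{condition}/{spec.name}: {err}", err.history
            ) from err
        prev_profiles, last_profiles = profiles[:steps], profiles[steps:]

        def cycle_arrays(cycle):
            return (
                np.array([p.t for p in cycle]),
                np.array([p.mean_velocity() for p in cycle]),
                np.array([wall_shear_stress(p, rheology) for p in cycle]),
                np.array([p.dpdx for p in cycle]),
            )

        t_last, v_last, wss_last, dpdx_last = cycle_arrays(last_profiles)
        _, v_prev, wss_prev, dpdx_prev = cycle_arrays(prev_profiles)

        Q_branch_full = spec.flow_fraction * Q_in_full
        p_df = wk.simulate(t_full, Q_branch_full, spec.windkessel, Pc0=numerics.Pc0)
        P_full = p_df["P_Pa"].to_numpy()
        P_last = P_full[-steps:]
        P_prev = P_full[-2 * steps : -steps]
        Q_last = Q_branch_full[-steps:]

        trace = pd.DataFrame(
            {
                "t_s": t_last,
                "Q_m3_per_s": Q_last,
                "v_m_per_s": v_last,
                "P_Pa": P_last,
                "Pc_Pa": p_df["Pc_Pa"].to_numpy()[-steps:],
                "wss_Pa": wss_last,
                "dpdx_Pa_per_m": dpdx_last,
            }
        )
        periodicity = {
            "v": _rel_linf(v_last, v_prev),
            "wss": _rel_linf(wss_last, wss_prev),
            "dpdx": _rel_linf(dpdx_last, dpdx_prev),
            "P": _rel_linf(P_last, P_prev),
        }
        results.append(BranchResult(spec=spec, trace=trace, periodicity=periodicity))

    pooled = {
        "pressure": np.concatenate([b.trace["P_Pa"].to_numpy() for b in results]),
        "velocity": np.concatenate([b.trace["v_m_per_s"].to_numpy() for b in results]),
        "wss": np.concatenate([b.trace["wss_Pa"].to_numpy() for b in results]),
    }
    summaries = {q: summarize(vals, quantity=q) for q, vals in pooled.items()}
    wss_b = wss_bands if wss_bands is not None else default_wss_bands()
    p_b = pressure_bands if pressure_bands is not None else default_pressure_bands()
    severity = {
        "wss": classify(summaries["wss"], wss_b),
        "pressure": classify(summaries["pressure"], p_b),
    }
    return ConditionReport(
        condition=condition,
        branches=tuple(results),
        summaries=summaries,
        severity=severity,
    )


def run_all(
    network: ArchNetwork,
    waveform: WaveformParams | None = None,
    numerics: NumericsConfig | None = None,
    registry: ConditionRegistry | None = None,
    conditions: tuple[str, ...] | None = None,
    **kwargs,
) -> tuple[dict[str, ConditionReport], pd.DataFrame]:
    """Run every registered condition; return reports + comparison table.

    The table has one row per (condition, quantity) with min/avg/max
    columns, mirroring the condition-by-condition bar comparisons.
    """
    registry = registry if registry is not None else default_registry()
    names = conditions if conditions is not None else tuple(registry.names())
    reports = {
        c: run_condition(c, network, waveform, numerics, registry, **kwargs)
        for c in names
    }
    rows = []
    for c, rep in reports.items():
        for q, s in rep.summaries.items():
            rows.append(
                {"condition": c, "quantity": q, "min": s.min, "avg": s.avg, "max": s.max}
            )
    return reports, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# configuration file support


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs, loadable from one YAML file."""

    registry: ConditionRegistry = field(default_factory=default_registry)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    network: ArchNetwork | None = None
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    wss_bands: SeverityBands = field(default_factory=default_wss_bands)
    pressure_bands: SeverityBands = field(default_factory=default_pressure_bands)
    mean_pressure: float = wk.DEFAULT_MEAN_PRESSURE
    tau: float = wk.DEFAULT_TAU

    def resolve_network(self) -> ArchNetwork:
        if self.network is not None:
            return self.network
        from .synthetic_data import make_default_network

        return make_default_network(
            waveform=self.waveform, mean_pressure=self.mean_pressure, tau=self.tau
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "rheology" in raw:
            cfg = replace(cfg, registry=ConditionRegistry.from_dict(raw["rheology"]))
        if "waveform" in raw:
            cfg = replace(cfg, waveform=WaveformParams.from_dict(raw["waveform"]))
        if "windkessel" in raw:
            blk = raw["windkessel"]
            cfg = replace(
                cfg,
                mean_pressure=float(blk.get("mean_pressure", cfg.mean_pressure)),
                tau=float(blk.get("tau", cfg.tau)),
            )
        if "numerics" in raw:
            blk = dict(raw["numerics"])
            cfg = replace(
                cfg,
                numerics=NumericsConfig(
                    nr=int(blk.get("nr", 101)),
                    dt=(float(blk["dt"]) if blk.get("dt") is not None else None),
                    n_cycles=int(blk.get("n_cycles", 8)),
                    tol=float(blk.get("tol", 1e-8)),
                    max_iters=int(blk.get("max_iters", 50)),
                    Pc0=float(blk.get("Pc0", wk.DEFAULT_MEAN_PRESSURE)),
                ),
            )
        if "network" in raw:
            blk = raw["network"]
            branches = []
            for b in blk["branches"]:
                if all(key in b for key in ("R1", "R2", "C")):
                    params = wk.WindkesselParams.from_dict(b)
                else:
                    # estimate from the configured mean pressure / flow share
                    from .cardiac_waveform import mean_inlet_velocity

                    q_mean = (
                        mean_inlet_velocity(cfg.waveform)
                        * math.pi
                        * float(blk["inlet_radius"]) ** 2
                        * float(b["flow_fraction"])
                    )
                    params = wk.estimate_parameters(cfg.mean_pressure, q_mean, cfg.tau)
                branches.append(
                    BranchSpec(
                        name=str(b["name"]),
                        radius=float(b["radius"]),
                        flow_fraction=float(b["flow_fraction"]),
                        windkessel=params,
                    )
                )
            cfg = replace(
                cfg,
                network=ArchNetwork(
                    inlet_radius=float(blk["inlet_radius"]), branches=tuple(branches)
                ),
            )
        return cfg

    def to_yaml(self, path) -> None:
        net = self.resolve_network()
        doc = {
            "rheology": self.registry.to_dict(),
            "waveform": self.waveform.to_dict(),
            "windkessel": {"mean_pressure": self.mean_pressure, "tau": self.tau},
            "numerics": {
                "nr": self.numerics.nr,
                "dt": self.numerics.dt,
                "n_cycles": self.numerics.n_cycles,
                "tol": self.numerics.tol,
                "max_iters": self.numerics.max_iters,
                "Pc0": self.numerics.Pc0,
            },
            "network": {
                "inlet_radius": net.inlet_radius,
                "branches": [
                    {
                        "name": b.name,
                        "radius": b.radius,
                        "flow_fraction": b.flow_fraction,
                        **b.windkessel.to_dict(),
                    }
                    for b in net.branches
                ],
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
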