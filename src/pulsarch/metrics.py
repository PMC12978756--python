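"""Field diagnostics and severity classification.

Helicity density H = u . (curl u) quantifies the alignment of velocity
and vorticity — the signature of helical/swirling flow in curved
vessels. It is evaluated pointwise on structured grids with
second-order differences (central inside, one-sided at boundaries, or
periodic wrapping for periodic analytic fields).

Scalar summaries (min/avg/max) of pressure, velocity and wall shear
stress feed an illustrative traffic-light severity classification.
Only the physiologic band for time-averaged WSS, 0.4–1.5 Pa, is an
established literature value; the remaining cutpoints are package
defaults, labelled "illustrative" in every report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GriddedField",
    "MetricSummary",
    "SeverityBands",
    "SeverityReport",
    "helicity_field",
    "summarize",
    "classify",
    "default_wss_bands",
    "default_pressure_bands",
    "MMHG_PA",
]

#: Pascals per mmHg.
MMHG_PA = 133.322

_SEVERITY_RANK = {"green": 0, "yellow": 1, "red": 2}


@dataclass(frozen=True)
class GriddedField:
    """Structured 3D velocity field (and optional pressure).

    ``u``, ``v``, ``w`` are arrays of identical shape ``(nx, ny, nz)``
    sampled on a uniform grid with spacings ``spacing = (dx, dy, dz)``.
    """

    spacing: tuple[float, float, float]
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        shp = self.u.shape
        if self.v.shape != shp or self.w.shape != shp:
            raise ValueError("u, v, w must share one shape")
        if self.p is not None and self.p.shape != shp:
            raise ValueError("p must match the velocity shape")
        if len(shp) != 3:
            raise ValueError("expected 3-D component arrays")
        if any(h <= 0.0 for h in self.spacing):
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape

    # --- plain-text I/O -------------------------------------------------

    def to_vtk(self, path) -> None:
        """Write as a legacy ASCII VTK structured-points file."""
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        lines = [
            "# vtk DataFile Version 3.0",
            "pulsarch gridded field",
            "ASCII",
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx} {ny} {nz}",
            "ORIGIN 0 0 0",
            f"SPACING {dx:.17g} {dy:.17g} {dz:.17g}",
            f"POINT_DATA {nx * ny * nz}",
            "VECTORS velocity double",
        ]
        # VTK structured points iterate x fastest
        flat = np.stack(
            [c.transpose(2, 1, 0).ravel() for c in (self.u, self.v, self.w)], axis=1
        )
        lines += [" ".join(f"{x:.17g}" for x in row) for row in flat]
        if self.p is not None:
            lines += [
                "SCALARS pressure double 1",
                "LOOKUP_TABLE default",
            ]
            lines += [f"{x:.17g}" for x in self.p.transpose(2, 1, 0).ravel()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vtk(cls, path) -> "GriddedField":
        tokens_by_line = [ln.split() for ln in Path(path).read_text().splitlines()]
        dims = spacing = None
        i = 0
        vel = None
        pres = None
        while i < len(tokens_by_line):
            tok = tokens_by_line[i]
            if not tok:
                i += 1
                continue
            key = tok[0].upper()
            if key == "DIMENSIONS":
                dims = tuple(int(x) for x in tok[1:4])
            elif key == "SPACING":
                spacing = tuple(float(x) for x in tok[1:4])
            elif key == "VECTORS":
                n = dims[0] * dims[1] * dims[2]
                nums: list[float] = []
                i += 1
                while len(nums) < 3 * n:
                    nums.extend(float(x) for x in tokens_by_line[i])
                    i += 1
                vel = np.asarray(nums).reshape(n, 3)
                continue
            elif key == "SCALARS":
                n = dims[0] * dims[1] * dims[2]
                i += 2  # skip LOOKUP_TABLE
                nums = []
                while len(nums) < n:
                    nums.extend(float(x) for x in tokens_by_line[i])
                    i += 1
                pres = np.asarray(nums)
                continue
            i += 1
        if dims is None or spacing is None or vel is None:
            raise ValueError(f"{path}: not a structured-points velocity file")
        nx, ny, nz = dims

        def unflat(a):
            return a.reshape(nz, ny, nx).transpose(2, 1, 0)

        return cls(
            spacing=spacing,
            u=unflat(vel[:, 0]),
            v=unflat(vel[:, 1]),
            w=unflat(vel[:, 2]),
            p=unflat(pres) if pres is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        I, J, K = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        cols = {
            "x_m": (I * dx).ravel(),
            "y_m": (J * dy).ravel(),
            "z_m": (K * dz).ravel(),
            "u_m_per_s": self.u.ravel(),
            "v_m_per_s": self.v.ravel(),
            "w_m_per_s": self.w.ravel(),
        }
        if self.p is not None:
            cols["p_Pa"] = self.p.ravel()
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class MetricSummary:
    """min/avg/max of one reported quantity."""

    quantity: str
    min: float
    avg: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.avg <= self.max):
            raise ValueError(f"{self.quantity}: need min <= avg <= max")

    def to_dict(self) -> dict:
        return {"quantity": self.quantity, "min": self.min, "avg": self.avg, "max": self.max}


def _gradient_axis(a: np.ndarray, h: float, axis: int, periodic: bool) -> np.ndarray:
    if periodic:
        return (np.roll(a, -1, axis=axis) - np.roll(a, 1, axis=axis)) / (2.0 * h)
    return np.gradient(a, h, axis=axis, edge_order=2)


def helicity_field(fld: GriddedField, periodic: bool = False) -> np.ndarray:
    """Pointwise helicity density H = u.(curl u) on the grid.

    Second-order central differences inside the domain and one-sided
    second-order at boundaries; with ``periodic=True`` all derivatives
    wrap (appropriate for fields sampled on a periodic cell).
    """
    if min(fld.shape) < 3:
        raise ValueError("grid must be at least 3 points in every axis")
    dx, dy, dz = fld.spacing
    d = _gradient_axis
    wy = d(fld.w, dy, 1, periodic)
    vz = d(fld.v, dz, 2, periodic)
    uz = d(fld.u, dz, 2, periodic)
    wx = d(fld.w, dx, 0, periodic)
    vx = d(fld.v, dx, 0, periodic)
    uy = d(fld.u, dy, 1, periodic)
    return fld.u * (wy - vz) + fld.v * (uz - wx) + fld.w * (vx - uy)


def summarize(values, quantity: str = "value") -> MetricSummary:
    """Exact min/mean/max of a non-empty finite array."""
    a = np.asarray(values, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("cannot summarize an empty array")
    if not np.all(np.isfinite(a)):
        raise ValueError("values must be finite")
    return MetricSummary(
        quantity=quantity, min=float(a.min()), avg=float(a.mean()), max=float(a.max())
    )


@dataclass(frozen=True)
class BandSpec:
    """Ordered edges plus one category per interval (len(edges)+1).

    A value exactly on an edge is assigned to whichever adjacent
    category has the lower severity (conservative boundary rule).
    """

    edges: tuple[float, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.edges) + 1:
            raise ValueError("need one category per interval")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        unknown = set(self.categories) - set(_SEVERITY_RANK)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    def category(self, value: float) -> str:
        i = int(np.searchsorted(self.edges, value, side="left"))
        if i < len(self.edges) and value == self.edges[i]:
            lo, hi = self.categories[i], self.categories[i + 1]
            return lo if _SEVERITY_RANK[lo] <= _SEVERITY_RANK[hi] else hi
        return self.categories[i]


@dataclass(frozen=True)
class SeverityBands:
    """Per-metric band specs for one quantity (keys: min, avg, max)."""

    quantity: str
    bands: Mapping[str, BandSpec] = field(default_factory=dict)
    note: str = "illustrative"

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "note": self.note,
            "bands": {
                m: {"edges": list(b.edges), "categories": list(b.categories)}
                for m, b in self.bands.items()
            },
        }


@dataclass(frozen=True)
class SeverityReport:
    """Traffic-light category per metric plus the value that produced it."""

    quantity: str
    entries: Mapping[str, tuple[str, float]]  # metric -> (category, value)
    bands: SeverityBands

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "classification": {
                m: {"category": cat, "value": val} for m, (cat, val) in self.entries.items()
            },
            "bands": self.bands.to_dict(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def default_wss_bands() -> SeverityBands:
    """Default WSS bands, Pa.

    The 0.4–1.5 Pa green band for the cycle-average is the literature
    physiologic range; the max (>1.5 Pa borderline, >4.5 Pa high) and
    min (<0.05 Pa borderline) cutpoints are illustrative defaults.
    """
    return SeverityBands(
        quantity="wss",
        bands={
            "avg": BandSpec(edges=(0.4, 1.5), categories=("yellow", "green", "red")),
            "max": BandSpec(edges=(1.5, 4.5), categories=("green", "yellow", "red")),
            "min": BandSpec(edges=(0.05,), categories=("yellow", "green")),
        },
    )


def default_pressure_bands() -> SeverityBands:
    """Default pressure bands, Pa, mapped from blood-pressure norms.

    min ~ diastolic (60–90 mmHg normal), max ~ systolic (90–140 mmHg
    normal, above 140 flagged high), avg ~ mean arterial pressure
    (70–105 mmHg). All cutpoints are illustrative defaults.
    """
    return SeverityBands(
        quantity="pressure",
        bands={
            "min": BandSpec(
                edges=(60 * MMHG_PA, 90 * MMHG_PA),
                categories=("yellow", "green", "yellow"),
            ),
            "max": BandSpec(
                edges=(90 * MMHG_PA, 140 * MMHG_PA),
                categories=("yellow", "green", "red"),
            ),
            "avg": BandSpec(
                edges=(70 * MMHG_PA, 105 * MMHG_PA),
                categories=("yellow", "green", "yellow"),
            ),
        },
    )


def classify(summary: MetricSummary, bands: SeverityBands) -> SeverityReport:
    """Map a metric summary onto its severity bands.

    Deterministic; a value exactly on a band edge goes to the
    lower-severity side.
    """
    if bands.quantity != summary.quantity:
        raise ValueError(
            f"bands are for {bands.quantity!r}, summary is {summary.quantity!r}"
        )
    entries = {}
    for metric, spec in bands.bands.items():
        value = getattr(summary, metric)
        entries[metric] = (spec.category(value), value)
    return SeverityReport(quantity=summary.quantity, entries=entries, bands=bands)
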