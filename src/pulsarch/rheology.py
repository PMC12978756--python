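"""Shear-thinning blood rheology: the Carreau effective-viscosity law.

Blood is shear-thinning: its apparent viscosity falls from a zero-shear
plateau ``mu0`` to an infinite-shear plateau ``mu_inf`` as the local
shear rate grows. The transition is governed by a time constant
``lam`` (the reciprocal of the shear rate where thinning sets in) and a
power-law index ``k`` < 1:

    mu_eff(g) = mu_inf + (mu0 - mu_inf) * (1 + (lam*g)^2)^((k-1)/2)

Four parameter sets are registered, representing anemic blood (low
hematocrit, low viscosity), diabetic blood (high hematocrit, strongly
elevated zero-shear viscosity) and two healthy donors. Hematocrit is
stored as descriptive metadata only; it does not enter the law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RheologyParams",
    "ConditionRegistry",
    "default_registry",
    "effective_viscosity",
    "shear_rate_magnitude",
    "viscosity_curve",
]

#: Clamp on lam*shear_rate before squaring, to keep the exp/log
#: evaluation finite; beyond this the law has reached mu_inf to well
#: below double precision.
_LAM_GAMMA_MAX = 1e15

#: Common blood density, kg/m^3 (used for all registered conditions).
BLOOD_DENSITY = 1060.0


@dataclass(frozen=True)
class RheologyParams:
    """One blood condition's Carreau constants plus metadata.

    Parameters
    ----------
    name : str
        Condition label.
    k : float
        Power-law index (dimensionless, 0 < k < 1 for shear-thinning).
    lam : float
        Time constant, s.
    mu0 : float
        Zero-shear viscosity, Pa·s.
    mu_inf : float
        Infinite-shear viscosity, Pa·s.
    hematocrit : float
        Red-cell volume fraction in [0, 1]; metadata only.
    density : float
        Blood density, kg/m^3.
    """

    name: str
    k: float
    lam: float
    mu0: float
    mu_inf: float
    hematocrit: float = 0.45
    density: float = BLOOD_DENSITY

    def __post_init__(self) -> None:
        if not (self.mu0 >= self.mu_inf > 0.0):
            raise ValueError(
                f"{self.name}: need mu0 >= mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if self.lam <= 0.0:
            raise ValueError(f"{self.name}: time constant lam must be positive")
        if not (0.0 < self.k < 1.0):
            raise ValueError(f"{self.name}: power-law index k must lie in (0, 1)")
        if not (0.0 <= self.hematocrit <= 1.0):
            raise ValueError(f"{self.name}: hematocrit must lie in [0, 1]")
        if self.density <= 0.0:
            raise ValueError(f"{self.name}: density must be positive")

    def to_dict(self) -> dict:
        """Plain-dict form used by the YAML/JSON config round-trip."""
        return {
            "k": self.k,
            "lambda": self.lam,
            "mu0": self.mu0,
            "mu_inf": self.mu_inf,
            "hematocrit": self.hematocrit,
            "density": self.density,
        }

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "RheologyParams":
        return cls(
            name=name,
            k=float(d["k"]),
            lam=float(d["lambda"]),
            mu0=float(d["mu0"]),
            mu_inf=float(d["mu_inf"]),
            hematocrit=float(d.get("hematocrit", 0.45)),
            density=float(d.get("density", BLOOD_DENSITY)),
        )


# Registered blood conditions. Hematocrit: anemic 25%, diabetic 65%,
# both healthy donors about 45%.
_CONDITION_TABLE = {
    "anemic": dict(k=0.33, lam=12.448, mu_inf=0.00257, mu0=0.0178, hematocrit=0.25),
    "diabetic": dict(k=0.39, lam=103.09, mu_inf=0.00802, mu0=0.8592, hematocrit=0.65),
    "healthy1": dict(k=0.48, lam=39.418, mu_inf=0.00345, mu0=0.0161, hematocrit=0.45),
    "healthy2": dict(k=0.3568, lam=3.313, mu_inf=0.0035, mu0=0.056, hematocrit=0.45),
}


@dataclass(frozen=True)
class ConditionRegistry:
    """Mapping from condition label to :class:`RheologyParams`."""

    conditions: Mapping[str, RheologyParams] = field(default_factory=dict)

    def __getitem__(self, name: str) -> RheologyParams:
        try:
            return self.conditions[name]
        except KeyError:
            raise KeyError(
                f"unknown blood condition {name!r}; known: {sorted(self.conditions)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.conditions

    def names(self) -> list[str]:
        return list(self.conditions)

    def to_dict(self) -> dict:
        return {name: p.to_dict() for name, p in self.conditions.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionRegistry":
        return cls({name: RheologyParams.from_dict(name, block) for name, block in d.items()})


def default_registry() -> ConditionRegistry:
    """The four registered blood conditions, validated at construction."""
    reg = ConditionRegistry(
        {name: RheologyParams(name=name, **row) for name, row in _CONDITION_TABLE.items()}
    )
    assert len(reg.conditions) == 4
    return reg


def _check_shear_rate(shear_rate) -> np.ndarray:
    g = np.asarray(shear_rate, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    if np.any(g < 0.0):
        raise ValueError("shear rate must be non-negative")
    return g


def effective_viscosity(shear_rate, params: RheologyParams):
    """Carreau effective viscosity, Pa·s, at shear rate(s) in 1/s.

    Accepts a scalar or array of non-negative shear rates. The result
    always lies in ``[mu_inf, mu0]``; it equals ``mu0`` exactly at zero
    shear and approaches ``mu_inf`` at high shear.
    """
    g = _check_shear_rate(shear_rate)
    x = np.minimum(params.lam * g, _LAM_GAMMA_MAX)
    # (1 + x^2)^((k-1)/2) via exp/log1p: stable for very large x and
    # exactly 1 at x = 0.
    factor = np.exp(0.5 * (params.k - 1.0) * np.log1p(x * x))
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * factor
    if np.ndim(shear_rate) == 0:
        return float(mu)
    return mu


def shear_rate_magnitude(grad_u) -> float:
    """Shear-rate scalar from a 3x3 velocity-gradient tensor, 1/s.

    Uses the standard second invariant of the rate-of-strain tensor,
    ``sqrt(2 D:D)`` with ``D = (grad_u + grad_u^T)/2``, normalized so
    that simple shear du/dy = s gives exactly s.
    """
    G = np.asarray(grad_u, dtype=float)
    if G.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError("velocity-gradient entries must be finite")
    D = 0.5 * (G + G.T)
    return float(math.sqrt(2.0 * np.sum(D * D)))


def viscosity_curve(params: RheologyParams, shear_rates: Iterable[float]) -> pd.DataFrame:
    """Tabulate mu_eff over a set of shear rates.

    Returns a DataFrame with columns ``shear_rate_s-1`` and
    ``mu_eff_Pa_s`` (the CSV export header). Empty input yields an
    empty table.
    """
    g = _check_shear_rate(np.asarray(list(shear_rates), dtype=float))
    mu = effective_viscosity(g, params) if g.size else np.array([], dtype=float)
    return pd.DataFrame({"shear_rate_s-1": g, "mu_eff_Pa_s": mu})
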