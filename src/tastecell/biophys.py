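"""Physical constants, ionic conditions, and equilibrium (Nernst) potentials.

Every channel reversal in the package is derived from an :class:`IonicConditions`
instance through :func:`nernst_potential`, so all concentration bookkeeping lives
here.  Concentrations are treated as activities (activity coefficients ignored),
which is the conventional simplification for whole-cell conductance models.

Units: concentrations in mM, temperature in K, potentials in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "R_GAS",
    "FARADAY",
    "InvalidInputError",
    "IonicConditions",
    "ReversalSet",
    "nernst_potential",
    "reversal_set",
]

#: Molar gas constant, J mol^-1 K^-1 (CODATA 2018).
R_GAS = 8.314462618

#: Faraday constant, C mol^-1 (CODATA 2018).
FARADAY = 96485.332


class InvalidInputError(ValueError):
    """Raised when a physical quantity is outside its valid domain."""


@dataclass(frozen=True)
class IonicConditions:
    """Intra/extracellular Na+, K+, Cl- concentrations and bath temperature.

    Defaults are the standard simulation conditions for the taste-cell model:
    [Na+]o = 150, [K+]o = 5.4, [Cl-]o = 150, [Na+]i = 6, [K+]i = 140,
    [Cl-]i = 30 mM at 25 degC (298.15 K), matching the recording temperature.
    """

    na_out: float = 150.0
    na_in: float = 6.0
    k_out: float = 5.4
    k_in: float = 140.0
    cl_out: float = 150.0
    cl_in: float = 30.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("na_out", "na_in", "k_out", "k_in", "cl_out", "cl_in"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise InvalidInputError(f"{name} must be a positive finite concentration, got {value!r}")
        if not (273.0 <= self.temperature <= 320.0):
            raise InvalidInputError(f"temperature must lie in [273, 320] K, got {self.temperature!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperature_K"] = d.pop("temperature")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IonicConditions":
        d = dict(d)
        if "temperature_K" in d:
            d["temperature"] = d.pop("temperature_K")
        return cls(**d)


@dataclass(frozen=True)
class ReversalSet:
    """Cached Nernst reversal potentials (mV) for Na+, K+ and Cl-."""

    e_na: float
    e_k: float
    e_cl: float


def nernst_potential(valence: int, c_in: float, c_out: float, temperature: float = 298.15) -> float:
    """Nernst equilibrium potential in mV.

    E = (R*T / (z*F)) * ln(c_out / c_in), converted from volts to millivolts.

    Parameters
    ----------
    valence
        Signed ionic charge z (nonzero integer; -1 for Cl-).
    c_in, c_out
        Intra/extracellular concentrations in mM (both > 0).
    temperature
        Absolute temperature in kelvin.
    """
    if valence == 0:
        raise InvalidInputError("valence must be nonzero")
    if not (c_in > 0 and c_out > 0):
        raise InvalidInputError(f"concentrations must be positive, got c_in={c_in!r}, c_out={c_out!r}")
    if temperature <= 0:
        raise InvalidInputError(f"temperature must be positive, got {temperature!r}")
    return 1000.0 * R_GAS * temperature / (valence * FARADAY) * math.log(c_out / c_in)


def reversal_set(conditions: IonicConditions) -> ReversalSet:
    """Compute the Na+/K+/Cl- reversal potentials for a set of ionic conditions."""
    t = conditions.temperature
    return ReversalSet(
        e_na=nernst_potential(+1, conditions.na_in, conditions.na_out, t),
        e_k=nernst_potential(+1, conditions.k_in, conditions.k_out, t),
        e_cl=nernst_potential(-1, conditions.cl_in, conditions.cl_out, t),
    )
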