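"""Membrane current models.

TMC4 — the voltage-dependent, Ca2+-insensitive chloride channel that is the
focus of the package — is modelled as an outwardly rectifying Boltzmann
conductance with an ohmic driving force:

    I_TMC4(V) = g_max * scale * block * anion_scale * a_inf(V) * (V - E_rev)

where a_inf(V) = 1 / (1 + exp(-(V - v_half)/k)) and E_rev is either the
chloride Nernst potential or a fixed per-configuration value (whole-cell
recordings report E_rev directly because pipette/bath anion compositions vary).
Gating is instantaneous by default (`tau_act = 0`); a first-order activation
gate is available for sensitivity checks.  Pharmacological block and anion
substitution enter purely as amplitude multipliers: they scale the current
without moving its reversal, and the current is by construction independent of
intracellular Ca2+ (the defining contrast with ANO1, provided here as a
Ca2+-gated comparator with Hill activation).

The Na+/K+/leak currents are the classical Hodgkin-Huxley forms
g*m^3*h*(V-E_Na), g*n^4*(V-E_K), g*(V-E_leak) with first-order gate kinetics
dx/dt = (x_inf - x)/tau(V).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .biophys import InvalidInputError

__all__ = [
    "KNOWN_ANIONS",
    "Tmc4Params",
    "HHGateParams",
    "Ano1Params",
    "tmc4_activation",
    "tmc4_current",
    "nav_current",
    "kdr_current",
    "leak_current",
    "ano1_current",
    "gate_steady_state",
    "gate_tau",
    "gate_derivative",
]

#: Anion species accepted by default in `anion_scale` maps (extensible).
KNOWN_ANIONS = ("chloride", "bromide", "iodide", "gluconate", "acetate", "methanesulfonate")


def _default_anion_scale() -> dict:
    return {"chloride": 1.0}


@dataclass(frozen=True)
class Tmc4Params:
    """TMC4 channel parameters.

    ``g_max`` (nS) is the maximal conductance; ``scale_factor`` is the
    dimensionless expression-level multiplier swept 0-3 in the working-
    hypothesis simulations.  ``v_half``/``slope_k`` (mV) set the Boltzmann
    rectification; the defaults (0 mV, 25 mV) are artifact choices tuned to
    give strong outward rectification with small inward currents, and are
    config-overridable.  ``block_factor`` in [0, 1] is a pharmacological
    conductance multiplier (1 = no block); ``anion_scale`` maps anion species
    to amplitude factors in (0, 1] (chloride is the reference at exactly 1).
    ``e_rev_mode`` selects the chloride Nernst potential ("nernst_cl") or a
    fixed reversal ("fixed", e.g. -27.6 mV for the KCl whole-cell
    configuration).  ``tau_act`` (ms) of 0 means instantaneous gating.
    """

    g_max: float = 10.0
    scale_factor: float = 1.0
    v_half: float = 0.0
    slope_k: float = 25.0
    e_rev_mode: str = "fixed"
    e_rev_fixed: float = -27.6
    anion_scale: Mapping[str, float] = field(default_factory=_default_anion_scale)
    tau_act: float = 0.0
    block_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.slope_k <= 0:
            raise InvalidInputError(f"slope_k must be > 0, got {self.slope_k!r}")
        if self.scale_factor < 0:
            raise InvalidInputError(f"scale_factor must be >= 0, got {self.scale_factor!r}")
        if self.g_max < 0:
            raise InvalidInputError(f"g_max must be >= 0, got {self.g_max!r}")
        if not 0.0 <= self.block_factor <= 1.0:
            raise InvalidInputError(f"block_factor must lie in [0, 1], got {self.block_factor!r}")
        if self.e_rev_mode not in ("nernst_cl", "fixed"):
            raise InvalidInputError(f"e_rev_mode must be 'nernst_cl' or 'fixed', got {self.e_rev_mode!r}")
        if self.tau_act < 0:
            raise InvalidInputError(f"tau_act must be >= 0, got {self.tau_act!r}")
        cl = self.anion_scale.get("chloride")
        if cl != 1.0:
            raise InvalidInputError(f"anion_scale['chloride'] must be exactly 1, got {cl!r}")
        for species, s in self.anion_scale.items():
            if not 0.0 < s <= 1.0:
                raise InvalidInputError(f"anion_scale[{species!r}] must lie in (0, 1], got {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anion_scale"] = dict(self.anion_scale)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Tmc4Params":
        return cls(**d)


@dataclass(frozen=True)
class HHGateParams:
    """Boltzmann steady state plus a bell-shaped voltage-dependent time constant.

    x_inf(V) = 1 / (1 + exp(-(V - v_half)/slope_k)); a negative ``slope_k``
    makes the gate an inactivation variable.  tau(V) = tau_min +
    (tau_max - tau_min)/cosh((V - v_half)/(2*|slope_k|)) stays inside
    [tau_min, tau_max] and peaks at v_half, the usual first-order HH shape.
    ``exponent`` is the power the gate enters the conductance with.
    """

    v_half: float
    slope_k: float
    tau_min: float
    tau_max: float
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.slope_k == 0:
            raise InvalidInputError("slope_k must be nonzero")
        if not 0 < self.tau_min <= self.tau_max:
            raise InvalidInputError(f"need 0 < tau_min <= tau_max, got {self.tau_min!r}, {self.tau_max!r}")
        if self.exponent < 1:
            raise InvalidInputError(f"exponent must be >= 1, got {self.exponent!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HHGateParams":
        return cls(**d)


@dataclass(frozen=True)
class Ano1Params:
    """Ca2+-activated chloride channel (ANO1) comparator: Hill gating in Ca_i."""

    g_max: float = 10.0
    ca_half: float = 400.0  # nM, mid-activation of the Hill curve
    hill_n: float = 2.0
    e_rev: float = -27.6

    def __post_init__(self) -> None:
        if self.ca_half <= 0:
            raise InvalidInputError(f"ca_half must be > 0, got {self.ca_half!r}")
        if self.hill_n <= 0:
            raise InvalidInputError(f"hill_n must be > 0, got {self.hill_n!r}")


# ---------------------------------------------------------------------------
# TMC4
# ---------------------------------------------------------------------------

def tmc4_activation(v, params: Tmc4Params):
    """Open fraction of TMC4 at membrane potential ``v`` (Boltzmann, in [0, 1])."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - params.v_half) / params.slope_k))
    return float(out) if out.ndim == 0 else out


def tmc4_reversal(params: Tmc4Params, e_cl: float) -> float:
    """Effective reversal potential (mV) given the configured mode."""
    return e_cl if params.e_rev_mode == "nernst_cl" else params.e_rev_fixed


def tmc4_current(v, params: Tmc4Params, e_cl: float, ca_i: float = 0.0,
                 species: str = "chloride", activation=None):
    """TMC4 current in pA at potential ``v`` (mV).

    ``ca_i`` is accepted purely for interface symmetry with
    :func:`ano1_current`; the result is identical for any value — the
    channel's Ca2+-insensitivity is a contract of this model.  ``activation``
    overrides the instantaneous Boltzmann open fraction when a first-order
    TMC4 gate is integrated explicitly (``tau_act > 0``).
    """
    if species not in params.anion_scale:
        raise InvalidInputError(
            f"unknown anion species {species!r}; known: {sorted(params.anion_scale)}")
    del ca_i  # Ca2+-insensitive by contract
    a = tmc4_activation(v, params) if activation is None else activation
    e_rev = tmc4_reversal(params, e_cl)
    g = params.g_max * params.scale_factor * params.block_factor * params.anion_scale[species]
    v = np.asarray(v, dtype=float)
    out = g * a * (v - e_rev)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gates and currents
# ---------------------------------------------------------------------------

def gate_steady_state(v, gate: HHGateParams):
    """Steady-state open fraction x_inf(v) in [0, 1]."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - gate.v_half) / gate.slope_k))
    return float(out) if out.ndim == 0 else out


def gate_tau(v, gate: HHGateParams):
    """Voltage-dependent time constant in ms, bounded by [tau_min, tau_max]."""
    v = np.asarray(v, dtype=float)
    out = gate.tau_min + (gate.tau_max - gate.tau_min) / np.cosh(
        (v - gate.v_half) / (2.0 * abs(gate.slope_k)))
    return float(out) if out.ndim == 0 else out


def gate_derivative(x, v, gate: HHGateParams):
    """First-order relaxation rate dx/dt = (x_inf - x)/tau, in ms^-1."""
    return (gate_steady_state(v, gate) - x) / gate_tau(v, gate)


def nav_current(v, m, h, g_max: float, e_na: float):
    """Voltage-gated Na+ current g*m^3*h*(v - E_Na) in pA (g in nS, v in mV)."""
    return g_max * m ** 3 * h * (v - e_na)


def kdr_current(v, n, g_max: float, e_k: float):
    """Delayed-rectifier K+ current g*n^4*(v - E_K) in pA."""
    return g_max * n ** 4 * (v - e_k)


def leak_current(v, g_leak: float, e_leak: float):
    """Ohmic leak g*(v - E_leak) in pA."""
    return g_leak * (v - e_leak)


def ano1_current(v, ca_i, params: Ano1Params):
    """ANO1 comparator current: Hill activation in intracellular Ca2+ (nM).

    I = g_max * ca^n / (ca^n + ca_half^n) * (v - e_rev).  Monotonically
    increasing in ``ca_i`` at any fixed v > e_rev, in contrast to TMC4.
    """
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ca_i < 0):
        raise InvalidInputError("ca_i must be >= 0")
    ratio = (ca_i / params.ca_half) ** params.hill_n
    out = params.g_max * ratio / (1.0 + ratio) * (np.asarray(v, dtype=float) - params.e_rev)
    return float(out) if out.ndim == 0 else out
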