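"""Reaction thermodynamics under observed conditions.

ΔG′ = ΔG°′ + R·T·ln Q, with ΔG°′ the standard transformed Gibbs energy at
pH 7 and 25 C from the catalogue, R = 8.314 J/(mol K), T = 298.15 K by
default, and Q the reaction quotient built from aqueous molarities and gas
partial pressures (atm).  Water, protons, solids and biomass have unit
activity.  No Henry's-law conversion is applied: gases always enter Q as
partial pressures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .catalog import Catalog, Reaction

__all__ = [
    "ChemicalState",
    "ThermoResult",
    "reaction_quotient",
    "delta_g_prime",
    "R_GAS",
    "T_STANDARD",
]

R_GAS = 8.314  # J / (mol K)
T_STANDARD = 298.15  # K


class StateError(ValueError):
    """A reaction participant has no activity in the chemical state."""


@dataclass(frozen=True)
class ChemicalState:
    """Activities for Q: aqueous in mol/L, gases in atm."""

    aqueous: dict[str, float] = field(default_factory=dict)
    gas: dict[str, float] = field(default_factory=dict)
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for mid, v in {**self.aqueous, **self.gas}.items():
            if v < 0:
                raise ValueError(f"negative activity for {mid!r}")

    def activity(self, metabolite_id: str, catalog: Catalog) -> float:
        met = catalog.metabolite(metabolite_id)
        if met.phase in ("solid", "biomass"):
            return 1.0
        pool = self.gas if met.phase == "gas" else self.aqueous
        if metabolite_id not in pool:
            raise StateError(
                f"no {met.phase} activity for {metabolite_id!r} in state"
            )
        return pool[metabolite_id]


@dataclass(frozen=True)
class ThermoResult:
    reaction_id: str
    dg_prime: float  # kJ per unit extent
    dg0_prime: float
    quotient: float
    temperature: float
    infinite_q: bool = False


def reaction_quotient(reaction: Reaction, state: ChemicalState, catalog: Catalog) -> float:
    """Q = prod(activity^coeff) over explicit participants.

    A zero-activity reactant (negative exponent) gives +inf; a
    zero-activity product gives 0.
    """
    log_q = 0.0
    for mid, coeff in reaction.stoich.items():
        a = state.activity(mid, catalog)
        if a == 0:
            return math.inf if coeff < 0 else 0.0
        log_q += coeff * math.log(a)
    return math.exp(log_q)


def delta_g_prime(
    reaction: Reaction,
    state: ChemicalState,
    catalog: Catalog,
    temperature: float | None = None,
) -> ThermoResult:
    """Transformed Gibbs energy at the observed state, kJ per unit extent."""
    t = temperature if temperature is not None else state.temperature
    q = reaction_quotient(reaction, state, catalog)
    if math.isinf(q):
        return ThermoResult(reaction.id, math.inf, reaction.dg0_prime, q, t,
                            infinite_q=True)
    if q <= 0:
        raise ValueError(f"reaction {reaction.id!r}: Q must be positive, got {q}")
    dg = reaction.dg0_prime + R_GAS * t * math.log(q) / 1000.0
    return ThermoResult(reaction.id, dg, reaction.dg0_prime, q, t)
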