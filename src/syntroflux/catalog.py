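"""Reaction catalogue: metabolites, species, overall reactions, assemblies.

The catalogue is the single source of truth for the stoichiometric model.
Each species is represented by one or more *overall* reactions (lumped
pathways, per glucose-equivalent for the cellulolytic fermenter), and every
reaction must balance carbon and combustion electrons exactly over its
non-biomass participants.  Water and protons are implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Metabolite",
    "Species",
    "Reaction",
    "Assembly",
    "Catalog",
    "CatalogError",
    "BalanceReport",
    "load_catalog",
    "default_assemblies",
    "degree_of_reduction",
    "build_matrix",
    "validate_balance",
    "active_reactions",
]

PHASES = ("aqueous", "gas", "solid", "biomass")

#: Canonical species order used for assembly labels ("Rc&Mc&Mh&Dv").
SPECIES_ORDER = ("Rc", "Mc", "Mh", "Dv")


class CatalogError(ValueError):
    """Raised for unresolvable metabolites, species, or malformed entries."""


def degree_of_reduction(formula: dict[str, int]) -> int:
    """Available combustion electrons per mole of a CHO compound.

    gamma = 4*C + H - 2*O, the electron equivalents released on full
    oxidation to CO2 and H2O.  CO2 itself scores 0, H2 scores 2.
    """
    return 4 * formula.get("C", 0) + formula.get("H", 0) - 2 * formula.get("O", 0)


@dataclass(frozen=True)
class Metabolite:
    id: str
    formula: dict[str, int]
    phase: str
    carbon: int
    gamma: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise CatalogError(f"metabolite {self.id!r}: unknown phase {self.phase!r}")
        if self.carbon < 0 or self.gamma < 0:
            raise CatalogError(f"metabolite {self.id!r}: carbon and gamma must be >= 0")
        if self.phase != "biomass" and self.gamma != degree_of_reduction(self.formula):
            raise CatalogError(
                f"metabolite {self.id!r}: gamma {self.gamma} inconsistent with "
                f"formula (expected {degree_of_reduction(self.formula)})"
            )


@dataclass(frozen=True)
class Species:
    id: str
    description: str = ""


@dataclass(frozen=True)
class Reaction:
    """Species-attributed overall reaction.

    ``stoich`` maps metabolite id to a signed coefficient (negative =
    consumed) per unit extent.  ``atp_yield`` is mol ATP per unit extent,
    ``dg0_prime`` the standard transformed Gibbs energy in kJ per unit
    extent at pH 7 and 25 C.
    """

    id: str
    species: str
    stoich: dict[str, float]
    atp_yield: float
    dg0_prime: float

    def __post_init__(self) -> None:
        if self.atp_yield < 0:
            raise CatalogError(f"reaction {self.id!r}: atp_yield must be >= 0")


@dataclass(frozen=True)
class Assembly:
    """A culture: a subset of species with a canonical '&'-joined label."""

    members: tuple[str, ...]
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.members:
            raise CatalogError("assembly must have at least one member")
        ordered = tuple(s for s in SPECIES_ORDER if s in self.members)
        unknown = set(self.members) - set(SPECIES_ORDER)
        if unknown:
            raise CatalogError(f"unknown species in assembly: {sorted(unknown)}")
        object.__setattr__(self, "members", ordered)
        object.__setattr__(self, "label", "&".join(ordered))

    @classmethod
    def from_label(cls, label: str) -> "Assembly":
        return cls(tuple(label.split("&")))

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.members


@dataclass(frozen=True)
class BalanceReport:
    reaction_id: str
    carbon_residual: float
    electron_residual: float

    @property
    def ok(self) -> bool:
        return self.carbon_residual == 0 and self.electron_residual == 0


class Catalog:
    """Immutable bundle of metabolites, species and reactions (in file order)."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        species: list[Species],
        reactions: list[Reaction],
        y_atp: float = 10.5,
        version: str = "unversioned",
    ):
        self.metabolites = {m.id: m for m in metabolites}
        self.species = {s.id: s for s in species}
        self.reactions = {r.id: r for r in reactions}
        self.y_atp = y_atp
        self.version = version
        for r in reactions:
            if r.species not in self.species:
                raise CatalogError(f"reaction {r.id!r}: unknown species {r.species!r}")
            for m in r.stoich:
                if m not in self.metabolites:
                    raise CatalogError(f"reaction {r.id!r}: unknown metabolite {m!r}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self.metabolites[mid]
        except KeyError:
            raise CatalogError(f"unknown metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[rid]
        except KeyError:
            raise CatalogError(f"unknown reaction {rid!r}") from None


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load a catalogue config; with no path, load the shipped default."""
    if path is None:
        text = resources.files("syntroflux.data").joinpath("catalog.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mets = [
        Metabolite(id=mid, formula=spec["formula"], phase=spec["phase"],
                   carbon=spec["carbon"], gamma=spec["gamma"])
        for mid, spec in raw["metabolites"].items()
    ]
    species = [Species(id=sid, description=d) for sid, d in raw["species"].items()]
    reactions = [
        Reaction(id=rid, species=spec["species"], stoich=dict(spec["stoich"]),
                 atp_yield=float(spec["atp_yield"]), dg0_prime=float(spec["dg0_prime"]))
        for rid, spec in raw["reactions"].items()
    ]
    y_atp = float(raw.get("biomass", {}).get("y_atp", 10.5))
    return Catalog(mets, species, reactions, y_atp=y_atp,
                   version=str(raw.get("version", "unversioned")))


def default_assemblies() -> list[Assembly]:
    """The eight study assemblies: Rc alone and Rc with every partner subset."""
    partners = [s for s in SPECIES_ORDER if s != "Rc"]
    out = []
    for k in range(len(partners) + 1):
        for combo in combinations(partners, k):
            out.append(Assembly(("Rc",) + combo))
    return out


def build_matrix(
    reactions: list[Reaction],
    metabolites: list[str] | list[Metabolite],
    strict: bool = True,
) -> np.ndarray:
    """Stoichiometric matrix S with metabolite rows and reaction columns.

    S[i, j] is the signed coefficient of metabolite i in reaction j;
    metabolites a reaction does not touch get 0.  With ``strict`` (default)
    a reaction referencing a metabolite outside the row list is an error;
    ``strict=False`` silently projects onto the given rows, which is how
    the fit restricts S to the measured analytes (e.g. dropping the
    glucose-equivalent supply row).
    """
    row_ids = [m.id if isinstance(m, Metabolite) else m for m in metabolites]
    index = {mid: i for i, mid in enumerate(row_ids)}
    S = np.zeros((len(row_ids), len(reactions)))
    for j, rxn in enumerate(reactions):
        for mid, coeff in rxn.stoich.items():
            if mid not in index:
                if strict:
                    raise CatalogError(
                        f"reaction {rxn.id!r} references metabolite {mid!r} "
                        "absent from the row list"
                    )
                continue
            S[index[mid], j] = coeff
    return S


def validate_balance(reaction: Reaction, catalog: Catalog) -> BalanceReport:
    """Carbon and electron residuals of a reaction over non-biomass species.

    Both residuals must be exactly zero (integer arithmetic on catalogue
    carbon/gamma) for a balanced reaction; water and protons are implicit.
    """
    carbon = 0.0
    electrons = 0.0
    for mid, coeff in reaction.stoich.items():
        met = catalog.metabolite(mid)
        if met.phase == "biomass":
            continue
        carbon += coeff * met.carbon
        electrons += coeff * met.gamma
    return BalanceReport(reaction.id, carbon, electrons)


def active_reactions(assembly: Assembly, catalog: Catalog) -> list[Reaction]:
    """Reactions whose species is present in the assembly, in catalogue order."""
    return [r for r in catalog.reactions.values() if r.species in assembly]
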