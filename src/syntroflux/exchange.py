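"""Interspecies exchange-network inference from fitted extents.

Who feeds whom: each metabolite's producers and consumers are read off the
fitted reaction extents and the catalogue stoichiometry.  A species
consuming its own product is netted out first (edges are interspecies
only); the remainder of each consumer's intake is allocated to donors in
proportion to their net production shares.

Two edge-weight conventions are supported because the field reports both:

* ``consumer_extent`` (default) — the extent of the receiving reaction,
  attributed to each donor by its share of the supplied material.  For a
  bi-culture with a single producer and a unit-coefficient consumer this
  equals the consumed mmol.
* ``metabolite_total`` — summed mmol of the listed metabolites transferred
  along the edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .catalog import Assembly, Catalog, active_reactions

__all__ = [
    "ExchangeEdge",
    "ExchangeComparison",
    "infer_exchanges",
    "compare_exchanges",
    "edges_to_frame",
    "edges_to_graph",
    "CONVENTIONS",
]

CONVENTIONS = ("consumer_extent", "metabolite_total")


@dataclass(frozen=True)
class ExchangeEdge:
    donor: str
    receiver: str
    metabolites: frozenset[str]
    amount: float  # mmol, per the convention
    convention: str

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError("exchange edges are interspecies only")
        if self.amount < 0:
            raise ValueError("edge amount must be >= 0")

    @property
    def key(self) -> tuple[str, str, frozenset[str]]:
        return (self.donor, self.receiver, self.metabolites)


@dataclass(frozen=True)
class ExchangeComparison:
    donor: str
    receiver: str
    metabolites: frozenset[str]
    amount_a: float
    amount_b: float
    difference: float
    percent_change: float  # (B - A)/A * 100; NaN when A == 0
    status: str  # "shared", "emergent" (B only), "lost" (A only)


def infer_exchanges(
    extents: dict[str, float],
    assembly: Assembly,
    catalog: Catalog,
    convention: str = "consumer_extent",
) -> list[ExchangeEdge]:
    """Donor -> receiver edges implied by fitted extents.

    ``extents`` maps reaction id to fitted extent (mmol) for the assembly's
    active reactions.  Zero-amount edges are dropped.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; one of {CONVENTIONS}")
    reactions = active_reactions(assembly, catalog)

    # species-level production/consumption per metabolite
    prod: dict[tuple[str, str], float] = {}
    cons: dict[tuple[str, str], float] = {}
    for rxn in reactions:
        xi = float(extents.get(rxn.id, 0.0))
        for mid, coeff in rxn.stoich.items():
            if coeff > 0:
                prod[(rxn.species, mid)] = prod.get((rxn.species, mid), 0.0) + xi * coeff
            elif coeff < 0:
                cons[(rxn.species, mid)] = cons.get((rxn.species, mid), 0.0) - xi * coeff

    # net out intra-species recycling
    net_prod = {k: max(prod.get(k, 0.0) - cons.get(k, 0.0), 0.0) for k in prod}
    net_cons = {k: max(cons.get(k, 0.0) - prod.get(k, 0.0), 0.0)
                for k in set(cons) | set(prod)}

    def donor_shares(mid: str, receiver: str) -> dict[str, float]:
        donors = {
            sp: amt for (sp, m), amt in net_prod.items()
            if m == mid and sp != receiver and amt > 0
        }
        total = sum(donors.values())
        return {sp: amt / total for sp, amt in donors.items()} if total > 0 else {}

    # pass 1: external intake per (reaction, metabolite)
    external: dict[tuple[str, str], float] = {}
    for rxn in reactions:
        xi = float(extents.get(rxn.id, 0.0))
        if xi <= 0:
            continue
        for mid, coeff in rxn.stoich.items():
            if coeff >= 0:
                continue
            intake = xi * (-coeff)
            c_total = cons.get((rxn.species, mid), 0.0)
            frac = (
                net_cons.get((rxn.species, mid), 0.0) / c_total if c_total > 0 else 0.0
            )
            external[(rxn.id, mid)] = intake * frac

    # a metabolite cannot be transferred beyond its total net production:
    # imperfect fits may imply more consumption than supply, so demand is
    # scaled down proportionally per metabolite
    demand: dict[str, float] = {}
    supply: dict[str, float] = {}
    for (rid, mid), amt in external.items():
        demand[mid] = demand.get(mid, 0.0) + amt
    for (sp, mid), amt in net_prod.items():
        supply[mid] = supply.get(mid, 0.0) + amt
    cap = {
        mid: min(1.0, supply.get(mid, 0.0) / d) if d > 0 else 1.0
        for mid, d in demand.items()
    }

    # pass 2: allocate to donors proportionally to net-production shares
    amounts: dict[tuple[str, str], float] = {}
    mets: dict[tuple[str, str], set[str]] = {}
    for rxn in reactions:
        xi = float(extents.get(rxn.id, 0.0))
        if xi <= 0:
            continue
        supplied: dict[str, float] = {}  # donor -> mmol into this reaction
        total_external = 0.0
        for mid, coeff in rxn.stoich.items():
            if coeff >= 0:
                continue
            ext = external.get((rxn.id, mid), 0.0) * cap.get(mid, 1.0)
            total_external += ext
            for donor, share in donor_shares(mid, rxn.species).items():
                if ext * share > 0:
                    supplied[donor] = supplied.get(donor, 0.0) + ext * share
                    mets.setdefault((donor, rxn.species), set()).add(mid)
        for donor, mmol in supplied.items():
            if convention == "metabolite_total":
                add = mmol
            else:  # consumer_extent: extent attributed by supply share
                add = xi * mmol / total_external if total_external > 0 else 0.0
            amounts[(donor, rxn.species)] = amounts.get((donor, rxn.species), 0.0) + add

    return [
        ExchangeEdge(d, r, frozenset(mets[(d, r)]), amount, convention)
        for (d, r), amount in amounts.items()
        if amount > 0
    ]


def compare_exchanges(
    edges_a: list[ExchangeEdge], edges_b: list[ExchangeEdge]
) -> list[ExchangeComparison]:
    """Per-edge difference and percent change of condition B relative to A.

    Edges are matched on (donor, receiver, metabolite set); an edge present
    on only one side is treated as 0 on the other and flagged "emergent"
    (B only) or "lost" (A only).
    """
    a = {e.key: e.amount for e in edges_a}
    b = {e.key: e.amount for e in edges_b}
    out = []
    for key in sorted(set(a) | set(b), key=lambda k: (k[0], k[1], sorted(k[2]))):
        va, vb = a.get(key, 0.0), b.get(key, 0.0)
        if key not in a:
            status = "emergent"
        elif key not in b:
            status = "lost"
        else:
            status = "shared"
        pct = (vb - va) / va * 100.0 if va > 0 else float("nan")
        out.append(
            ExchangeComparison(key[0], key[1], key[2], va, vb, vb - va, pct, status)
        )
    return out


def edges_to_frame(edges: list[ExchangeEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"donor": e.donor, "receiver": e.receiver,
             "metabolites": "+".join(sorted(e.metabolites)),
             "mmol": e.amount, "convention": e.convention}
            for e in sorted(edges, key=lambda e: (e.donor, e.receiver))
        ]
    )


def edges_to_graph(edges: list[ExchangeEdge]) -> nx.DiGraph:
    """Directed species graph; parallel metabolite routes merge per pair."""
    g = nx.DiGraph()
    for e in edges:
        if g.has_edge(e.donor, e.receiver):
            g[e.donor][e.receiver]["mmol"] += e.amount
            g[e.donor][e.receiver]["metabolites"] |= set(e.metabolites)
        else:
            g.add_edge(e.donor, e.receiver, mmol=e.amount,
                       metabolites=set(e.metabolites))
    return g
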