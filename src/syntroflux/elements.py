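"""Carbon and electron-equivalent accounting.

Every catalogue metabolite carries a carbon count and a degree of reduction
(gamma, combustion-electron equivalents per mole), so any amount in mmol
maps linearly to mmol C and mmol e-.  The ledger answers "how much carbon
and how many electrons ended up in CH4, CO2, and the other products".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import Catalog
from .measurements import MeasurementSeries

__all__ = ["TransferLedger", "element_content", "transfer_to_products", "ledger_frame"]


@dataclass(frozen=True)
class TransferLedger:
    culture: str
    product: str
    amount_mmol: float
    carbon_mmol: float
    electron_mmol: float


def element_content(
    metabolite_id: str, amount_mmol: float, catalog: Catalog
) -> dict[str, float]:
    """Carbon and electron mmol carried by an amount of one metabolite."""
    if amount_mmol < 0:
        raise ValueError("amount must be >= 0")
    met = catalog.metabolite(metabolite_id)
    return {
        "carbon_mmol": amount_mmol * met.carbon,
        "electron_mmol": amount_mmol * met.gamma,
    }


def transfer_to_products(
    production: dict[str, float] | list[MeasurementSeries],
    products: tuple[str, ...],
    catalog: Catalog,
    culture: str = "",
) -> list[TransferLedger]:
    """Element ledger per product from final cumulative production.

    ``production`` is either a mapping analyte -> final mmol (e.g. fitted
    productions) or a list of cumulative series, whose final values are
    used.  Products absent from the input get a zero ledger row.
    """
    if isinstance(production, dict):
        finals = production
    else:
        finals = {s.analyte: s.final for s in production}
        if production and not culture:
            culture = production[0].culture
    rows = []
    for product in products:
        amount = max(float(finals.get(product, 0.0)), 0.0)
        content = element_content(product, amount, catalog)
        rows.append(TransferLedger(culture, product, amount, **content))
    return rows


def ledger_frame(ledgers: list[TransferLedger]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"culture": l.culture, "product": l.product, "mmol": l.amount_mmol,
             "carbon_mmol": l.carbon_mmol, "electron_mmol": l.electron_mmol}
            for l in ledgers
        ]
    )
    return df
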