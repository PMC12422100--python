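"""Fed-batch measurement bookkeeping.

Cultures run in sealed bottles (default 160 ml) with 20 ml liquid. Every day
2 ml of liquid is sampled and replaced with fresh medium, and 5 ml of
headspace gas is drawn.  Net *cumulative* production of an analyte is
therefore the amount currently in the vessel plus everything previously
removed with samples, minus the day-0 baseline; replenishment medium
contributes no analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog

__all__ = [
    "VesselConfig",
    "RawReading",
    "MeasurementSeries",
    "MeasurementError",
    "gas_mmol",
    "cumulative_production",
    "cumulative_gas_production",
    "read_measurements",
    "series_to_frame",
]

R_GAS = 8.314  # J / (mol K)
ATM_PA = 101325.0


class MeasurementError(ValueError):
    """Malformed or physically impossible measurement input."""


@dataclass(frozen=True)
class VesselConfig:
    """Culture-vessel geometry and sampling scheme (volumes in ml, T in K)."""

    liquid_volume: float = 20.0
    headspace_volume: float = 140.0
    sampled_liquid: float = 2.0
    sampled_gas: float = 5.0
    temperature: float = 307.15  # incubation at 34 C, used for gas bookkeeping

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0 or self.headspace_volume <= 0:
            raise MeasurementError("vessel volumes must be positive")
        if self.sampled_liquid < 0 or self.sampled_gas < 0:
            raise MeasurementError("sampled volumes must be >= 0")
        if self.temperature <= 0:
            raise MeasurementError("temperature must be positive")


@dataclass(frozen=True)
class RawReading:
    """One daily reading: mM for aqueous analytes, atm for gas analytes."""

    culture: str
    replicate: str
    day: int
    analyte: str
    value: float
    context: VesselConfig = field(default_factory=VesselConfig)

    def __post_init__(self) -> None:
        if self.day < 0:
            raise MeasurementError(f"negative day {self.day}")
        if self.value < 0:
            raise MeasurementError(
                f"negative reading for {self.analyte} on day {self.day}"
            )


@dataclass(frozen=True)
class MeasurementSeries:
    """Cumulative net production (mmol) since day 0 for one analyte."""

    culture: str
    replicate: str
    analyte: str
    cumulative: dict[int, float]

    @property
    def final(self) -> float:
        return self.cumulative[max(self.cumulative)]


def gas_mmol(pressure_atm: float, headspace_ml: float, temperature_k: float) -> float:
    """Ideal-gas moles (as mmol) in the headspace at a partial pressure."""
    if temperature_k <= 0:
        raise MeasurementError("temperature must be positive")
    if pressure_atm < 0 or headspace_ml < 0:
        raise MeasurementError("pressure and volume must be >= 0")
    mol = pressure_atm * ATM_PA * headspace_ml * 1e-6 / (R_GAS * temperature_k)
    return mol * 1e3


def _check_days(readings: list[RawReading]) -> list[RawReading]:
    ordered = sorted(readings, key=lambda r: r.day)
    days = [r.day for r in ordered]
    if days != list(range(len(days))):
        missing = sorted(set(range(max(days) + 1)) - set(days))
        raise MeasurementError(f"days must be contiguous from 0; missing {missing}")
    return ordered


def cumulative_production(readings: list[RawReading]) -> MeasurementSeries:
    """Cumulative net production series for one aqueous analyte.

    cumulative[d] = V*C_d + sum_{k<d} v_sampled*C_k - V*C_0   (mmol),
    i.e. what is in the vessel now plus everything previously removed with
    liquid samples, relative to the day-0 baseline.  mM times ml gives umol,
    hence the 1e-3 factor.
    """
    ordered = _check_days(readings)
    first = ordered[0]
    out: dict[int, float] = {}
    removed = 0.0
    for r in ordered:
        ctx = r.context
        in_vessel = ctx.liquid_volume * r.value * 1e-3
        baseline = first.context.liquid_volume * first.value * 1e-3
        out[r.day] = in_vessel + removed - baseline
        removed += ctx.sampled_liquid * r.value * 1e-3
    return MeasurementSeries(first.culture, first.replicate, first.analyte, out)


def cumulative_gas_production(readings: list[RawReading]) -> MeasurementSeries:
    """Cumulative net production for a gas analyte read as partial pressure.

    Mirrors the liquid bookkeeping: headspace amount now, plus gas removed
    with previous headspace samples, minus the day-0 baseline.
    """
    ordered = _check_days(readings)
    first = ordered[0]
    out: dict[int, float] = {}
    removed = 0.0
    for r in ordered:
        ctx = r.context
        in_head = gas_mmol(r.value, ctx.headspace_volume, ctx.temperature)
        baseline = gas_mmol(
            first.value, first.context.headspace_volume, first.context.temperature
        )
        out[r.day] = in_head + removed - baseline
        removed += gas_mmol(r.value, ctx.sampled_gas, ctx.temperature)
    return MeasurementSeries(first.culture, first.replicate, first.analyte, out)


def cumulative_for_analyte(readings: list[RawReading], catalog: Catalog) -> MeasurementSeries:
    """Dispatch on analyte phase: gas readings in atm, aqueous in mM."""
    met = catalog.metabolite(readings[0].analyte)
    if met.phase == "gas":
        return cumulative_gas_production(readings)
    return cumulative_production(readings)


_UNIT_FACTORS = {"mM": 1.0, "uM": 1e-3, "µM": 1e-3, "atm": 1.0}


def read_measurements(
    path,
    catalog: Catalog,
    context: VesselConfig | None = None,
) -> list[RawReading]:
    """Read a tidy CSV/TSV of daily readings into typed records.

    Expects columns {culture, replicate, day, analyte, value, unit}; unit is
    normalized to mM (aqueous) or atm (gas).  Unknown analytes, unknown
    units, and duplicate (culture, replicate, day, analyte) keys are
    rejected with the offending row number.
    """
    context = context or VesselConfig()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"culture", "replicate", "day", "analyte", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise MeasurementError(f"missing columns: {sorted(missing)}")
    readings: list[RawReading] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        analyte = str(row["analyte"])
        if analyte not in catalog.metabolites:
            raise MeasurementError(f"line {line}: unknown analyte {analyte!r}")
        unit = str(row["unit"])
        if unit not in _UNIT_FACTORS:
            raise MeasurementError(f"line {line}: unknown unit {unit!r}")
        key = (row["culture"], row["replicate"], int(row["day"]), analyte)
        if key in seen:
            raise MeasurementError(f"line {line}: duplicate reading for {key}")
        seen.add(key)
        try:
            readings.append(
                RawReading(
                    culture=str(row["culture"]),
                    replicate=str(row["replicate"]),
                    day=int(row["day"]),
                    analyte=analyte,
                    value=float(row["value"]) * _UNIT_FACTORS[unit],
                    context=context,
                )
            )
        except MeasurementError as exc:
            raise MeasurementError(f"line {line}: {exc}") from None
    return readings


def group_readings(
    readings: list[RawReading],
) -> dict[tuple[str, str, str], list[RawReading]]:
    """Group readings by (culture, replicate, analyte)."""
    groups: dict[tuple[str, str, str], list[RawReading]] = {}
    for r in readings:
        groups.setdefault((r.culture, r.replicate, r.analyte), []).append(r)
    return groups


def cumulative_table(readings: list[RawReading], catalog: Catalog) -> pd.DataFrame:
    """Tidy frame of cumulative production for every series in the input."""
    rows = []
    for (culture, replicate, analyte), grp in group_readings(readings).items():
        series = cumulative_for_analyte(grp, catalog)
        for day, mmol in sorted(series.cumulative.items()):
            rows.append(
                {"culture": culture, "replicate": replicate, "analyte": analyte,
                 "day": day, "mmol": mmol}
            )
    return pd.DataFrame(rows)


def series_to_frame(series: list[MeasurementSeries]) -> pd.DataFrame:
    rows = [
        {"culture": s.culture, "replicate": s.replicate, "analyte": s.analyte,
         "day": d, "mmol": v}
        for s in series
        for d, v in sorted(s.cumulative.items())
    ]
    return pd.DataFrame(rows)
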