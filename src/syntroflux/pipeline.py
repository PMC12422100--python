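"""End-to-end orchestration: measurements -> fit -> exchange -> thermo ->
elements -> stats, with versioned JSON/CSV reports.

The pipeline is deterministic for a fixed seed and config; every report
embeds the seed, a config hash and the catalogue version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import Assembly, Catalog, active_reactions, load_catalog
from .elements import ledger_frame, transfer_to_products
from .exchange import edges_to_frame, infer_exchanges
from .fit import CultureFit, fit_culture, proteomics_prior
from .measurements import RawReading, VesselConfig, cumulative_table, read_measurements
from .stats import flux_fold_changes
from .thermo import ChemicalState, delta_g_prime

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

#: Activity floor (mol/L or atm) so unobserved-but-required participants do
#: not produce infinite quotients in routine ΔG′ tables; an analytical
#: detection-limit stand-in, configurable per run.
ACTIVITY_FLOOR = 1e-6

PRODUCTS = ("lactate", "acetate", "ethanol", "H2", "CO2", "CH4")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    measurements: str | Path
    output_dir: str | Path
    catalog: str | Path | None = None  # None = shipped default
    proteins: str | Path | None = None
    protein_mapping: str | Path | None = None
    mode: str = "endpoint"
    lambda_: float = 0.0
    convention: str = "consumer_extent"
    seed: int = 0
    activity_floor: float = ACTIVITY_FLOOR
    vessel: VesselConfig = field(default_factory=VesselConfig)

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _state_from_readings(
    readings: list[RawReading], catalog: Catalog, floor: float
) -> ChemicalState:
    """Mean final-day chemical state of one culture (mol/L and atm)."""
    last = max(r.day for r in readings)
    aqueous: dict[str, list[float]] = {}
    gas: dict[str, list[float]] = {}
    for r in readings:
        if r.day != last:
            continue
        met = catalog.metabolite(r.analyte)
        if met.phase == "gas":
            gas.setdefault(r.analyte, []).append(r.value)
        else:
            aqueous.setdefault(r.analyte, []).append(r.value * 1e-3)  # mM -> M
    # every catalogue metabolite gets at least the floor so Q is finite
    aq = {m.id: max(float(np.mean(v)), floor) if (v := aqueous.get(m.id)) else floor
          for m in catalog.metabolites.values() if m.phase == "aqueous"}
    gs = {m.id: max(float(np.mean(v)), floor) if (v := gas.get(m.id)) else floor
          for m in catalog.metabolites.values() if m.phase == "gas"}
    return ChemicalState(aqueous=aq, gas=gs)


def _single_addition_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """Culture pairs where B extends A by exactly one species."""
    pairs = []
    for a in labels:
        for b in labels:
            ma, mb = set(a.split("&")), set(b.split("&"))
            if ma < mb and len(mb - ma) == 1:
                pairs.append((a, b))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a measurements table and write the report bundle.

    Returns the in-memory bundle; CSV/JSON files land in ``output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        catalog = load_catalog(config.catalog)
    except FileNotFoundError as exc:
        raise PipelineError("catalogue", str(exc)) from exc

    try:
        readings = read_measurements(config.measurements, catalog, config.vessel)
        cum = cumulative_table(readings, catalog)
    except Exception as exc:
        raise PipelineError("measurements", str(exc)) from exc

    proteins = mapping = None
    if config.proteins is not None:
        try:
            proteins = pd.read_csv(config.proteins, sep="\t", index_col=0)
            if config.protein_mapping is None:
                raise ValueError("protein table given without a protein->reaction "
                                 "mapping")
            map_df = pd.read_csv(config.protein_mapping, sep="\t")
            mapping = dict(zip(map_df["protein"], map_df["reaction"]))
        except Exception as exc:
            raise PipelineError("proteomics", str(exc)) from exc

    fits: dict[str, CultureFit] = {}
    exchanges = {}
    thermo_rows = []
    ledgers = []
    try:
        for culture, sub in cum.groupby("culture"):
            assembly = Assembly.from_label(str(culture))
            prior = None
            if proteins is not None and str(culture) in proteins.columns:
                prior = proteomics_prior(proteins, mapping, catalog, str(culture),
                                         assembly)
            fits[str(culture)] = fit_culture(
                sub, assembly, catalog, mode=config.mode, prior=prior,
                lambda_=config.lambda_,
            )
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        for culture, fit in fits.items():
            assembly = Assembly.from_label(culture)
            exchanges[culture] = infer_exchanges(
                fit.mean_extents, assembly, catalog, config.convention
            )
    except Exception as exc:
        raise PipelineError("exchange", str(exc)) from exc

    try:
        for culture in fits:
            state = _state_from_readings(
                [r for r in readings if r.culture == culture], catalog,
                config.activity_floor,
            )
            for rxn in active_reactions(Assembly.from_label(culture), catalog):
                res = delta_g_prime(rxn, state, catalog)
                thermo_rows.append(
                    {"culture": culture, "reaction": rxn.id,
                     "dg_prime_kj": res.dg_prime, "dg0_prime_kj": res.dg0_prime,
                     "quotient": res.quotient}
                )
    except Exception as exc:
        raise PipelineError("thermo", str(exc)) from exc

    try:
        for culture, fit in fits.items():
            finals = {
                a: float(sub[sub["day"] == sub["day"].max()]["mmol"].mean())
                for a, sub in cum[cum["culture"] == culture].groupby("analyte")
            }
            ledgers.extend(
                transfer_to_products(finals, PRODUCTS, catalog, culture=culture)
            )
    except Exception as exc:
        raise PipelineError("elements", str(exc)) from exc

    try:
        comparisons = []
        for a, b in _single_addition_pairs(sorted(fits)):
            shared = set(fits[a].mean_extents) & set(fits[b].mean_extents)
            samples_a = {
                rid: np.array([rep.extents[rid]
                               for rep in fits[a].replicates.values()])
                for rid in shared
            }
            samples_b = {
                rid: np.array([rep.extents[rid]
                               for rep in fits[b].replicates.values()])
                for rid in shared
            }
            comparisons.extend(flux_fold_changes(samples_a, samples_b, a, b))
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    meta = {
        "tool_version": __version__,
        "catalog_version": catalog.version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "lambda": config.lambda_,
        "convention": config.convention,
    }
    bundle = {
        "meta": meta,
        "measurements": cum,
        "fits": fits,
        "exchange": exchanges,
        "thermo": pd.DataFrame(thermo_rows),
        "elements": ledger_frame(ledgers),
        "stats": comparisons,
    }
    _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    bundle["measurements"].to_csv(out_dir / "cumulative_production.csv", index=False)
    bundle["thermo"].to_csv(out_dir / "delta_g_prime.csv", index=False)
    bundle["elements"].to_csv(out_dir / "element_ledger.csv", index=False)

    extents_rows = []
    fit_report = {"meta": bundle["meta"], "cultures": {}}
    for culture, fit in bundle["fits"].items():
        for rid, mean in fit.mean_extents.items():
            extents_rows.append(
                {"culture": culture, "reaction": rid, "extent_mmol": mean,
                 "extent_sd": fit.sd_extents[rid]}
            )
        fit_report["cultures"][culture] = {
            "extents": fit.mean_extents,
            "extents_sd": fit.sd_extents,
            "r_squared": fit.r_squared,
            "nrmse": fit.nrmse,
        }
    pd.DataFrame(extents_rows).to_csv(out_dir / "extents.csv", index=False)
    (out_dir / "fit_report.json").write_text(json.dumps(fit_report, indent=2))

    edge_frames = [
        edges_to_frame(edges).assign(culture=culture)
        for culture, edges in bundle["exchange"].items()
        if edges
    ]
    edges = (
        pd.concat(edge_frames, ignore_index=True)
        if edge_frames else pd.DataFrame(
            columns=["donor", "receiver", "metabolites", "mmol", "convention",
                     "culture"]
        )
    )
    edges.to_csv(out_dir / "exchange_edges.csv", index=False)

    comp_rows = [
        {"quantity": c.quantity, "group_a": c.group_a, "group_b": c.group_b,
         "fold_change": c.fold_change, "direction": c.direction,
         "label": c.fold_label, "p_value": c.p_value, "q_value": c.q_value}
        for c in bundle["stats"]
    ]
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
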