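"""Nonnegative reaction-extent estimation.

Each culture's net metabolite production over the run is modelled as
``S @ xi`` where S is the stoichiometric matrix restricted to the
assembly's active reactions and the measured analytes, and ``xi`` is the
vector of nonnegative reaction extents (mmol of turnover over the run,
called "flux" in community-metabolism shorthand).  Extents are estimated by
weighted nonnegative least squares,

    xi = argmin_{xi >= 0}  || W (S xi - y) ||^2  +  lambda || xi - a ||^2,

optionally shrunk toward a proteomics-derived prior activity ``a``.  The
shrinkage term is folded into the least-squares system as sqrt(lambda)
identity rows, so the whole problem is solved by one active-set NNLS call
(deterministic: Lawson-Hanson active-set order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import Assembly, Catalog, active_reactions, build_matrix

__all__ = [
    "PriorActivity",
    "FitResult",
    "CultureFit",
    "proteomics_prior",
    "fit_extents",
    "goodness_of_fit",
    "bootstrap_extents",
    "fit_culture",
    "DEFAULT_ANALYTES",
]

#: Analytes the model is fitted to: the measured fermentation products and
#: gases.  Glucose-equivalent supply from cellulose is not a measured
#: production and is excluded from the target rows.
DEFAULT_ANALYTES = ("lactate", "acetate", "ethanol", "H2", "CO2", "CH4")

#: Floor on per-analyte normalization ranges, as a fraction of the largest
#: analyte range, so an analyte that stayed at zero cannot acquire an
#: unbounded weight.
RANGE_FLOOR_FRAC = 0.05


@dataclass(frozen=True)
class PriorActivity:
    """Prior reaction extents (mmol, >= 0), e.g. from marker-protein abundance."""

    extents: dict[str, float]
    source: str = "uniform"

    def __post_init__(self) -> None:
        for rid, a in self.extents.items():
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"prior extent for {rid!r} must be finite and >= 0")

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.extents.get(rid, 0.0) for rid in reaction_ids])


@dataclass
class FitResult:
    extents: dict[str, float]
    fitted: dict[str, float]
    residuals: dict[str, float]
    r_squared: float
    nrmse: float
    lambda_: float
    analytes: tuple[str, ...]
    warnings: list[str] = field(default_factory=list)


@dataclass
class CultureFit:
    """Per-replicate fits plus mean +/- SD extents for one culture."""

    culture: str
    replicates: dict[str, FitResult]
    mean_extents: dict[str, float]
    sd_extents: dict[str, float]
    r_squared: float
    nrmse: float


def proteomics_prior(
    abundance: pd.DataFrame,
    mapping: dict[str, str],
    catalog: Catalog,
    culture: str,
    assembly: Assembly | None = None,
    total_scale: float = 1.0,
    atp_scaling: str = "multiply",
) -> PriorActivity:
    """Prior reaction activities from marker-protein abundances.

    For each active reaction the prior is the mean normalized abundance of
    its marker proteins in this culture, scaled by the reaction's ATP yield
    (multiplied by default; set ``atp_scaling='divide'`` to invert), then
    rescaled so the priors sum to ``total_scale``.  A reaction with no
    mapped marker gets the mean of the others' pre-rescaling activities.
    All-zero abundances yield an all-zero prior.
    """
    if culture not in abundance.columns:
        raise KeyError(f"culture {culture!r} absent from abundance table")
    if atp_scaling not in ("multiply", "divide"):
        raise ValueError("atp_scaling must be 'multiply' or 'divide'")
    assembly = assembly or Assembly.from_label(culture)
    reactions = active_reactions(assembly, catalog)
    col = abundance[culture]
    raw: dict[str, float] = {}
    unmapped: list[str] = []
    for rxn in reactions:
        markers = [p for p, rid in mapping.items() if rid == rxn.id and p in col.index]
        if not markers:
            unmapped.append(rxn.id)
            continue
        mean_ab = float(col.loc[markers].mean())
        factor = rxn.atp_yield if atp_scaling == "multiply" else (
            1.0 / rxn.atp_yield if rxn.atp_yield > 0 else 0.0
        )
        raw[rxn.id] = mean_ab * factor
    fill = float(np.mean(list(raw.values()))) if raw else 0.0
    for rid in unmapped:
        raw[rid] = fill
    total = sum(raw.values())
    if total > 0:
        raw = {rid: a / total * total_scale for rid, a in raw.items()}
    return PriorActivity(extents=raw, source="proteomics")


def _normalization_ranges(
    observed: np.ndarray, ranges: np.ndarray | None
) -> np.ndarray:
    """Per-analyte scale for weighting/normalization, floored (see module doc).

    A 1-D ``observed`` is read as an endpoint vector (one value per analyte;
    scale falls back to |value|); a 2-D one as analyte rows over days.
    """
    if ranges is None:
        obs = np.asarray(observed, dtype=float)
        if obs.ndim == 1:
            ranges = np.abs(obs)
        else:
            ranges = obs.max(axis=1) - obs.min(axis=1)
    ranges = np.asarray(ranges, dtype=float)
    top = ranges.max() if ranges.size else 0.0
    if top == 0:
        return np.ones_like(ranges)
    return np.maximum(ranges, RANGE_FLOOR_FRAC * top)


def fit_extents(
    S: np.ndarray,
    y: np.ndarray,
    reaction_ids: list[str],
    analytes: list[str],
    weights: np.ndarray | None = None,
    prior: PriorActivity | None = None,
    lambda_: float = 0.0,
    ranges: np.ndarray | None = None,
) -> FitResult:
    """Weighted NNLS fit of reaction extents to an endpoint production vector.

    ``y`` is the cumulative net production (mmol) per analyte at the end of
    the run, ordered as ``analytes`` = rows of ``S``.  ``weights`` defaults
    to the inverse per-analyte observed range (``ranges``; falls back to
    |y|), which keeps large-mmol gases from dominating the fit.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, dtype=float)
    if S.shape[0] != y.shape[0]:
        raise ValueError(f"S has {S.shape[0]} rows but y has {y.shape[0]} entries")
    notes: list[str] = []
    if weights is None:
        weights = 1.0 / _normalization_ranges(y, ranges)
    W = np.diag(weights)
    A = W @ S
    b = W @ y
    if lambda_ > 0:
        a_vec = (prior or PriorActivity({}, "uniform")).vector(reaction_ids)
        A = np.vstack([A, np.sqrt(lambda_) * np.eye(S.shape[1])])
        b = np.concatenate([b, np.sqrt(lambda_) * a_vec])
    elif np.linalg.matrix_rank(S) < S.shape[1]:
        notes.append("rank-deficient stoichiometric matrix with lambda=0; "
                     "extents may be non-unique (active-set tie-break applies)")
    xi, _ = nnls(A, b)
    fitted = S @ xi
    resid = fitted - y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2, nrmse = goodness_of_fit(y, fitted, ranges=_normalization_ranges(y, ranges))
    if np.isnan(r2):
        notes.append("R^2 undefined on the endpoint vector (no variance across "
                     "normalized analytes); use the trajectory-level fit quality")
    return FitResult(
        extents=dict(zip(reaction_ids, xi)),
        fitted=dict(zip(analytes, fitted)),
        residuals=dict(zip(analytes, resid)),
        r_squared=r2,
        nrmse=nrmse,
        lambda_=lambda_,
        analytes=tuple(analytes),
        warnings=notes,
    )


def goodness_of_fit(
    observed: np.ndarray,
    fitted: np.ndarray,
    ranges: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pooled R^2 and range-normalized RMSE.

    Each analyte's observations and residuals are divided by that analyte's
    observed range so metabolites on different mmol scales are commensurate;
    R^2 = 1 - SSres/SStot and NRMSE = RMSE are then pooled over all
    normalized values.  Zero-variance observations make R^2 undefined (NaN).

    1-D inputs with a matching-length ``ranges`` are read as endpoint
    vectors (one value per analyte); 1-D inputs without one are read as a
    single analyte's trajectory.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.ndim == 1:
        if ranges is not None and np.size(ranges) == observed.size:
            observed = observed[:, None]
            fitted = fitted[:, None]
        else:
            observed = observed[None, :]
            fitted = fitted[None, :]
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have the same shape")
    if observed.size < 2:
        raise ValueError("need at least 2 observations")
    scale = _normalization_ranges(observed, ranges)[:, None]
    obs_n = observed / scale
    fit_n = fitted / scale
    ss_res = float(((obs_n - fit_n) ** 2).sum())
    ss_tot = float(((obs_n - obs_n.mean()) ** 2).sum())
    nrmse = float(np.sqrt(((obs_n - fit_n) ** 2).mean()))
    if ss_tot == 0:
        warnings.warn("zero-variance observations: R^2 undefined", stacklevel=2)
        return float("nan"), nrmse
    return 1.0 - ss_res / ss_tot, nrmse


def bootstrap_extents(
    S: np.ndarray,
    replicate_ys: list[np.ndarray],
    reaction_ids: list[str],
    analytes: list[str],
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[dict[str, float], dict[str, float]]:
    """Bootstrap mean +/- SD of extents by resampling replicates.

    Each draw resamples replicates with replacement, fits their mean
    production vector, and records the extents.  Deterministic for a fixed
    seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(replicate_ys) < 2:
        raise ValueError("need >= 2 replicates to bootstrap")
    rng = np.random.default_rng(seed)
    ys = np.asarray(replicate_ys, dtype=float)
    samples = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(ys), size=len(ys))
        y = ys[idx].mean(axis=0)
        res = fit_extents(S, y, reaction_ids, analytes, **fit_kwargs)
        samples.append([res.extents[r] for r in reaction_ids])
    arr = np.asarray(samples)
    return (
        dict(zip(reaction_ids, arr.mean(axis=0))),
        dict(zip(reaction_ids, arr.std(axis=0, ddof=1))),
    )


def _endpoint_and_ranges(
    cum: pd.DataFrame, analytes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Final cumulative vector and per-analyte day-range from a tidy table."""
    y = np.zeros(len(analytes))
    rng = np.zeros(len(analytes))
    for i, analyte in enumerate(analytes):
        sub = cum[cum["analyte"] == analyte].sort_values("day")
        if len(sub):
            y[i] = sub["mmol"].iloc[-1]
            rng[i] = sub["mmol"].max() - sub["mmol"].min()
    return y, rng


def fit_culture(
    cumulative: pd.DataFrame,
    assembly: Assembly,
    catalog: Catalog,
    mode: str = "endpoint",
    analytes: tuple[str, ...] = DEFAULT_ANALYTES,
    prior: PriorActivity | None = None,
    lambda_: float = 0.0,
) -> CultureFit:
    """Fit extents for one culture from a tidy cumulative-production table.

    ``cumulative`` needs columns {culture, replicate, analyte, day, mmol}
    (one culture).  Replicates are fitted separately; the summary reports
    their mean and SD.  ``mode='endpoint'`` fits the day-7 cumulative
    vector; ``mode='trajectory'`` fits each day's increment by NNLS and
    sums the per-day extents.
    """
    if mode not in ("endpoint", "trajectory"):
        raise ValueError("mode must be 'endpoint' or 'trajectory'")
    reactions = active_reactions(assembly, catalog)
    rids = [r.id for r in reactions]
    S = build_matrix(reactions, list(analytes), strict=False)
    fits: dict[str, FitResult] = {}
    for rep, sub in cumulative.groupby("replicate"):
        if mode == "endpoint":
            y, ranges = _endpoint_and_ranges(sub, list(analytes))
            res = fit_extents(
                S, y, rids, list(analytes), prior=prior, lambda_=lambda_,
                ranges=ranges,
            )
            _score_trajectory(res, S, sub, rids, list(analytes))
            fits[str(rep)] = res
        else:
            fits[str(rep)] = _fit_trajectory(
                S, sub, rids, list(analytes), prior=prior, lambda_=lambda_
            )
    reps = list(fits)
    arr = np.array([[fits[r].extents[rid] for rid in rids] for r in reps])
    mean = dict(zip(rids, arr.mean(axis=0)))
    sd = dict(zip(rids, arr.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(len(rids))))
    return CultureFit(
        culture=str(cumulative["culture"].iloc[0]),
        replicates=fits,
        mean_extents=mean,
        sd_extents=sd,
        r_squared=float(np.mean([f.r_squared for f in fits.values()])),
        nrmse=float(np.mean([f.nrmse for f in fits.values()])),
    )


def _trajectory_pivot(cum: pd.DataFrame, analytes: list[str]) -> np.ndarray:
    return (
        cum.pivot_table(index="analyte", columns="day", values="mmol")
        .reindex(analytes)
        .fillna(0.0)
        .sort_index(axis=1)
        .to_numpy()
    )


def _score_trajectory(
    res: FitResult, S: np.ndarray, cum: pd.DataFrame, rids: list[str],
    analytes: list[str],
) -> None:
    """Replace endpoint-level fit quality with trajectory-level R^2/NRMSE.

    Endpoint extents imply a linear cumulative ramp (constant daily rates);
    that predicted trajectory is scored against all observed days, each
    analyte normalized by its observed day range.
    """
    values = _trajectory_pivot(cum, analytes)
    n_days = values.shape[1] - 1
    if n_days < 1:
        return
    xi = np.array([res.extents[r] for r in rids])
    ramp = np.linspace(0.0, 1.0, n_days + 1)
    fitted = np.outer(S @ xi, ramp) + values[:, :1]
    ranges = values.max(axis=1) - values.min(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2, nrmse = goodness_of_fit(values, fitted, ranges=ranges)
    res.r_squared = r2
    res.nrmse = nrmse


def _fit_trajectory(
    S: np.ndarray,
    cum: pd.DataFrame,
    rids: list[str],
    analytes: list[str],
    prior: PriorActivity | None,
    lambda_: float,
) -> FitResult:
    """Trajectory mode: NNLS per daily increment, extents summed over days."""
    values = _trajectory_pivot(cum, analytes)
    ranges = values.max(axis=1) - values.min(axis=1)
    scale = _normalization_ranges(values, ranges)
    increments = np.diff(values, axis=1)
    n_days = increments.shape[1]
    day_prior = None
    if prior is not None:
        day_prior = PriorActivity(
            {rid: a / n_days for rid, a in prior.extents.items()}, prior.source
        )
    total = np.zeros(len(rids))
    fitted_traj = np.zeros_like(values)
    fitted_traj[:, 0] = values[:, 0]
    for d in range(n_days):
        res = fit_extents(
            S, increments[:, d], rids, analytes,
            weights=1.0 / scale, prior=day_prior, lambda_=lambda_, ranges=ranges,
        )
        xi_d = np.array([res.extents[r] for r in rids])
        total += xi_d
        fitted_traj[:, d + 1] = fitted_traj[:, d] + S @ xi_d
    fitted_final = S @ total
    y_final = values[:, -1] - values[:, 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2, nrmse = goodness_of_fit(values, fitted_traj, ranges=scale)
    return FitResult(
        extents=dict(zip(rids, total)),
        fitted=dict(zip(analytes, fitted_final)),
        residuals=dict(zip(analytes, fitted_final - y_final)),
        r_squared=r2,
        nrmse=nrmse,
        lambda_=lambda_,
        analytes=tuple(analytes),
    )
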