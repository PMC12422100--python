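# Methods

## Overall-reaction model

The community model is deliberately coarse: each species contributes one to
three *overall* reactions — lumped pathways with fixed stoichiometry —
rather than a genome-scale network. The default catalogue
(`src/syntroflux/data/catalog.yaml`), per glucose equivalent for the
fermenter:

| reaction | species | stoichiometry | ATP/extent | ΔG°′ (kJ) |
|---|---|---|---|---|
| lactate fermentation | Rc | glucose → 2 lactate | 2 | −196.0 |
| hydrogenic acetogenesis | Rc | glucose → 2 acetate + 2 CO₂ + 4 H₂ | 4 | −206.3 |
| mixed-acid fermentation | Rc | glucose → ethanol + acetate + 2 CO₂ + 2 H₂ | 3 | −220.0 |
| hydrogenic lactate oxidation | Dv | lactate → acetate + CO₂ + 2 H₂ | 1 | −4.2 |
| hydrogenotrophic methanogenesis | Mh | 4 H₂ + CO₂ → CH₄ | 0.5 | −131.0 |
| acetoclastic methanogenesis | Mc | acetate → CH₄ + CO₂ | 0.25 | −36.0 |

Stoichiometries follow standard anaerobic biochemistry for these organisms;
ATP yields and ΔG°′ values (pH 7, 25 °C) are literature-typical and ship in
the config file precisely so they can be replaced without touching code.
Water and protons are implicit: the transformed-energy convention at pH 7
absorbs them, and they carry neither carbon nor combustion electrons.
Cellulose enters as glucose equivalent (anhydroglucose, 162 g/mol); the
hydrolysis step supplies substrate but is not a fitted reaction. Every
reaction must balance carbon and degree of reduction exactly
(γ = 4C + H − 2O per mole; integer residuals, zero tolerance) — this is a
load-time invariant, not a convention.

An optional biomass pseudo-metabolite can be produced at
Y_ATP × ATP-yield grams per unit extent (Y_ATP = 10.5 g/mol ATP,
configurable); it is excluded from element balances.

## Fed-batch measurement correction

Cultures run in sealed 160 ml bottles with 20 ml liquid at 34 °C. Daily,
2 ml of liquid is removed and replaced with fresh medium and 5 ml of
headspace gas is drawn. Net cumulative production of an aqueous analyte is

    cumulative[d] = V·C_d + Σ_{k<d} v·C_k − V·C_0     (mmol)

— vessel content now, plus everything previously removed in samples, minus
the day-0 baseline; replenishment medium carries no analyte. Gas analytes
get the mirrored bookkeeping with amounts from the ideal-gas law
(n = PV/RT) at the incubation temperature (307.15 K); the gas removed with
each 5 ml draw is credited back. Whether sampled gas should be credited is
a genuine design choice — the symmetric treatment was adopted because the
generator and the correction must be exact inverses for the round-trip
tests to be meaningful, and asymmetric treatment would bias gas totals by
~3.5 % per day of the standing amount.

## Extent estimation

For one culture and replicate, the endpoint mode (default) solves

    ξ̂ = argmin_{ξ≥0} ‖W(Sξ − y)‖² + λ‖ξ − a‖²

with y the day-7 cumulative vector over the measured analytes (lactate,
acetate, ethanol, H₂, CO₂, CH₄ — glucose supply is not a measured
production and is excluded), W = diag(1/range_m) with each analyte's
observed day range, and the shrinkage term folded in as √λ·I rows so a
single Lawson–Hanson active-set NNLS call solves the whole problem
(deterministic, including tie-breaks in degenerate fits). Per-analyte
ranges are floored at 5 % of the largest range so an analyte that stayed at
zero cannot acquire unbounded weight. A trajectory mode fits each day's
increment by NNLS and sums the per-day extents; it follows day-to-day rate
changes but, with as many unknowns as equations per day, absorbs noise into
the extents and is therefore not the default.

λ defaults to 0 (pure NNLS). The prior a comes from marker-protein
abundances: per active reaction, the mean abundance of its markers in that
culture times the reaction's ATP yield (the direction of the ATP scaling is
ambiguous in principle; multiplication is the default and division is a
config switch), rescaled to a user-chosen total-extent scale. A reaction
with no mapped marker receives the mean prior.

Fit quality is reported as R² and NRMSE over *trajectories*: the endpoint
extents imply a linear cumulative ramp (constant daily rates), which is
scored against all observed days with each analyte normalized by its
observed range, pooled across analytes. Normalizing the endpoint vector
alone would make every produced analyte ≈ 1 and the statistic degenerate;
the trajectory-level definition is the meaningful one and is what
`CultureFit` carries. NRMSE is the RMSE of those range-normalized
residuals — a range-normalization was chosen because the analytes span two
orders of magnitude in mmol.

Replicates are fitted separately; summaries report mean ± SD, and a
replicate bootstrap (resample replicates, fit the mean vector; seeded) is
available for SDs when replicates are few.

### Structural non-identifiability

Over every metabolite in the catalogue (glucose included), and even over
ATP at the default yields,

    hydrogenic acetogenesis = lactate fermentation + 2 × lactate oxidation.

The composite of fermenting glucose to lactate and oxidizing that lactate
is chemically identical to direct acetogenesis, so whenever Dv is present
the stoichiometric matrix loses a rank and the data constrain only a line
of extent vectors: (ξ_lf + δ, ξ_ha − δ, ξ_hlo + 2δ). This is a property of
the biology, not a solver artifact. The package (a) surfaces a warning in
the fit result, (b) recovers the identifiable reactions (mixed-acid
fermentation and both methanogeneses) exactly in noise-free round trips,
and (c) lets the proteomics prior select the solution along the degenerate
direction — which is exactly the role protein abundances play in this
experimental design. Because the prior is semi-quantitative (ATP-scaled,
species-normalized), the selected point is biased relative to truth; in
synthetic benchmarks the lactate-oxidation extent lands within roughly
±50 % of its true value where it is not small, and fitted *productions*
always match the data regardless. Downstream numbers that depend on the
degenerate direction (the Rc → Dv lactate/H₂ exchange above all) inherit
this uncertainty and should be read as prior-informed estimates.

## Exchange inference

For each metabolite, per-species production and consumption follow from
extents × coefficients. A species consuming its own product is netted out
first (edges are interspecies only). Each consuming reaction's external
intake is then allocated to donors in proportion to their net production
shares; if fitted consumption exceeds supply (possible under noise),
demand is scaled down per metabolite so transfers never exceed production.
Two edge-weight conventions are exposed: `consumer_extent` (default; the
receiving reaction's extent attributed to each donor — coincides with the
transferred mmol in a bi-culture with a unit coefficient) and
`metabolite_total` (summed mmol transferred). Neither is asserted to be
the convention behind any particular published figure; both are provided
because published edge values for the H₂/CO₂ route cannot be reconciled
with a single convention.

## Thermodynamics

ΔG′ = ΔG°′ + R·T·ln Q with R = 8.314 J/(mol·K) and T = 298.15 K, even
though incubation is at 34 °C — the standard transformed energies are
25 °C values and mixing temperatures would be less defensible than the
small bias. Q uses molarities for aqueous species, partial pressures (atm)
for gases (no Henry's-law conversion), and unit activity for solids,
water, and biomass. A zero-activity reactant yields Q = +∞, flagged rather
than raised; in pipeline ΔG′ tables unobserved activities are floored at
10⁻⁶ (an analytical detection-limit stand-in, configurable) so routine
tables stay finite.

## Synthetic-data generator

The generator is the package's ground truth. Per-day metabolite increments
are S·ξ_day; vessel bookkeeping (the exact inverse of the measurement
correction) converts amounts to mM and atm, including the 3 % H₂ / 97 % N₂
initial headspace; multiplicative Gaussian noise (default CV 5 %, truncated
at zero) is applied per reading; duplicate bottles share the true
trajectory and differ in noise, mirroring technical duplicates. All
randomness flows from one integer seed. A configuration whose extents
would drive a pool negative is rejected rather than clamped.

Shipped per-assembly presets (total mmol over 7 days) emulate the
qualitative regimes of the four-species system: acetoclastic extent
0.32 mmol in Rc&Mc, lactate oxidation 0.18 mmol in Rc&Dv, 0.42 mmol CH₄ in
Rc&Mh, 1.37 mmol CH₄ in the quad-culture, and mixed-acid fermentation shut
off when both hydrogen consumers are present. Not every published fold
change is jointly attainable under the default stoichiometry's H₂ budget
(e.g. the largest reported hydrogenotrophic increases would require more
H₂ than the fermentation extents supply), so where anchors conflict the
presets keep the per-culture anchor magnitudes and the qualitative
ordering. Protein tables carry three markers per active reaction with
abundance proportional to total extent (plus uncorrelated background
proteins), normalized per species to sum to one per culture.

What the generator does *not* emulate: growth kinetics (extents are
constant per day, not Monod-shaped), pH drift and CO₂ speciation,
biological replicate variation beyond measurement noise, and protein
degradation/turnover. Passing round trips therefore demonstrate that the
estimator inverts the measurement process correctly under the stated noise
model — not that real cultures satisfy the constant-rate or
noise-independence assumptions.

## Statistics

Two-sample t-tests default to the pooled-variance (Student) form, with
Welch as an option; two groups with zero variance and equal means give
t = 0, p = 1, and with distinct means are flagged degenerate (p = 0).
q-values use Benjamini–Hochberg step-up. Fold changes are reported as
ratios ≥ 1 with a direction flag; a zero denominator caps the ratio at a
ceiling (default 100), rendered as "> 100". MIP/MRO community-coupling
scores are consumed as user-supplied scalars for correlation only — they
are never computed internally.

## Problem sizes

Default runs are desk-scale by design: 8 assemblies × 7 days × 6 analytes
× 2 replicates per simulation, 50–100 seeds for recovery Monte Carlos, and
a 6-unknown NNLS per fit. The acceptance script completes in well under a
minute on one core.

## Known limitations

* The degeneracy above makes three of six extents prior-dependent whenever
  Dv is present; report productions or identifiable combinations
  (ξ_lf + ξ_ha, 2ξ_ha + ξ_hlo) when prior quality is in doubt.
* Endpoint mode assumes constant daily rates when scoring trajectories;
  strongly lag-phased cultures will show depressed R² even at low noise.
* ΔG°′ defaults are literature-typical, not condition-specific; ionic
  strength and pH corrections are out of scope.
* The t-tests treat replicate extents as independent samples; with two
  technical duplicates the power is nominal at best.
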