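# Methods

## The model

`critsoil` computes critical soil moisture thresholds of ecosystem water
limitation from steady-state soil-plant hydraulics. Water moves through two
conductors in series:

**Soil leg.** Radial flow from bulk soil to the root surface, linearised by
the matric flux potential Φ(h) = ∫ₕ^∞ k(h′) dh′:

    Φ(ψ_soil) − Φ(ψ_soil-root) = T · ln(r_bulk / r_root) / (2π L_root)

with T the transpiration per ground area and L_root the effective absorbing
root length per ground area. Soil curves are the Campbell power-law family
(zero residual water content): θ(h) = θ_s (h_b/h)^{1/b} and
k(h) = K_sat (h_b/h)^τ with τ = 2 + 3/b, both saturated below the air-entry
head h_b. Because the parameter set the per-class table provides is exactly
(θ_s, h_b, b, K_sat), this family is the natural choice; a van Genuchten
variant would require re-derived parameters and offers no benefit here. Φ
then has a closed form, as does its inverse, so the whole trajectory
construction below is analytic.

**Plant leg.** A single lumped conductance between root surface and leaf,
vulnerable to the leaf water potential itself:

    ψ_leaf = ψ_soil-root − T / K_plant(ψ_leaf)

K_plant is piecewise linear: constant at K_plant-max down to an onset
potential, declining linearly below it, crossing 50% at ψ_x* and floored at
10⁻³·K_plant-max so the implicit equation never divides by zero. For this
shape the implicit equation reduces to a quadratic per branch; the solver
uses the closed form to locate the wet-continuation root and polishes it with
bracketed root-finding (robust at the fold where the two declining-branch
roots coalesce). A logistic ("sigmoid") vulnerability with the same 50% point
and midpoint slope is available behind `PlantTraits.vuln_shape`.

**Stress-onset limit (SOL).** For each bulk soil potential, letting the
root-surface potential fall traces a trajectory T(ψ_leaf): linear while both
conductors hold, bending as the soil supply saturates or the plant
conductance declines. The SOL is the first point (toward drier leaf
potentials) where |dT/dψ_leaf| drops to 80% of its per-trajectory maximum —
the edge of the linear zone, taken as the trigger of stomatal downregulation.
θ_crit and ψ_crit are the wettest soil state whose SOL transpiration equals
the potential transpiration T_pot; θ_crit follows from ψ_crit through the
retention curve.

## Numerical scheme

* ψ_soil grid: 400 log-spaced suctions from 10⁻⁴ to 10 MPa (200 in inner
  loops; the difference in θ_crit is < 10⁻³).
* Per-node trajectory: 2000 points parameterised by T from 0 to just below
  the soil-leg capacity (equivalently by ψ_soil-root, but uniform in T so the
  wet, nearly-planar part of the surface is well resolved); root-surface and
  leaf potentials recovered in closed form.
* Derivatives by finite differences along the trajectory; the SOL crossing
  and the T_sol = T_pot crossing are linearly interpolated (the latter in
  log-suction).
* Ties on a flat SOL resolve to the wettest node, matching the "minimum soil
  moisture that can still supply" definition.
* Everything in this chain is deterministic; suction is carried in metres of
  head with a single constant (101.97 m per MPa) for conversion.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| T_pot | 4 | mm d⁻¹ | reference daytime potential transpiration |
| VPD_ref | 1.5 | kPa | demand assumed to drive T_pot; anchors the VPD axis |
| K_plant-max | T_pot/1 = 4 | mm d⁻¹ MPa⁻¹ | wet-soil leaf potential of −1 MPa at T_pot |
| ψ_leaf-max | −1 | MPa | leaf potential at maximum transpiration, wet soil |
| ψ_x* | −2.8 | MPa | 50% conductance loss, typical woody-species embolism value |
| vuln_slope | 1.25 | MPa⁻¹ | see below |
| L_root | 100 | m m⁻² | see below |
| r_root | 0.5 | mm | typical effective fine-root radius |
| r_bulk | (π L_v)^(−1/2), L_v = L_root/0.3 m | m | half mean inter-root spacing |
| conductance floor | 10⁻³·K_plant-max | — | numerical floor |

**Vulnerability slope.** The onset of conductance loss sits at
ψ_x* + 0.5/slope. The slope must keep the sensitivity sweep ψ_x* ∈ [−5, −1.5]
MPa feasible at T_pot = 4 mm d⁻¹: at ψ_x* = −1.5 the wet-soil SOL is
K_plant-max · |onset|, which must exceed T_pot, requiring slope ≥ 1 MPa⁻¹.
The default 1.25 (onset 0.4 MPa above ψ_x*) is the smallest round value with
margin; it also keeps conductance maximal at −1 MPa, which the wet-soil
anchoring requires.

**Effective root length.** L_root is the model's one fitted quantity — an
*effective* absorbing length, far below anatomical root length. The package
fits it by least absolute deviations of θ_crit over observation sets
(`fit_root_length`: log-spaced scan plus golden-section refinement). The
shipped default, 100 m m⁻², is the value at which the simulated per-class
thresholds jointly match the reported levels this analysis targets (sandy
θ_crit below 0.1 at ψ_crit near −0.03 MPa; clay θ_crit near 0.3 at ψ_crit
near −0.6 MPa). An unconstrained fit against a single observed
θ_crit-vs-sand line is degenerate: the objective keeps improving toward the
texture-independent plant-limited regime, which contradicts the observed
texture dependence of ψ_crit — hence the joint anchoring.

**Soil parameter table.** `data/soil_params.tsv` ships class means of
(θ_s, h_b, b, K_sat) from the per-class statistics of Cosby et al. (1984,
*Water Resources Research* 20, 682–690), the standard Campbell-family
parameter set in land-surface modelling. The source has 11 classes; the silt row duplicates silt loam (flagged synthetic
in the fixture header). Within-class variability enters as geometric
standard deviation factors — the source reports the air-entry and
conductivity statistics in log space — set uniformly to 3.2 (h_b), 1.4 (b)
and 4.0 (K_sat): roughly half a decade of air-entry scatter, 40% slope
scatter and 0.6 decades of conductivity scatter, typical of such
compilations. These factors are package assumptions, not transcribed values;
the whole table is overridable via `load_soil_table(path)`, and substituting
locally measured curves is always preferable. Variability endmembers combine
min h_b + min b (max τ) + max K_sat (coarse end) and the opposites (fine
end).

## Flux pipeline

The observable is the evaporative fraction EF = LE/(LE+H) (records with
non-positive fluxes or quality flags outside {0, 1} excluded). Thresholds
come from a linear-plus-plateau regression of EF on soil moisture
(y = a + b·min(x, x₀)), the breakpoint profiled over candidates between
adjacent unique x values and refined by bounded minimisation; significance is
an F-test of the two-segment model against the intercept-only model at
α = 0.05, and fits with non-positive rising slope or an edge breakpoint are
rejected. Records enter through tiered criteria: (1) summer (JJA north / DJF
south) dry-downs — runs of ≥ 10 consecutive days of declining daily soil
moisture after a rain event (> 2 mm d⁻¹, configurable; the source analyses
state no threshold) — then (2) dry-downs in any season, then (3) summer
records alone; the first tier yielding a valid fit wins and is recorded.
Sap-flow series are aggregated to 06:00–20:00 daylight means (clock time, not
solar geometry; days under 50% coverage dropped) and fitted per tree against
the shared site environment, with the same significance rule.

The EF-over-(VPD × θ) analysis filters sub-daily records to
photosynthetically active (PPFD > 500 µmol m⁻² s⁻¹), aerodynamically coupled
(wind > 1 m s⁻¹), warm (daily median temperature ≥ 15 °C) conditions with
VPD in (0.5, 5] kPa, bins median EF on a 20 × 20 grid and reports, per
driver, the median over adjacent occupied interior bin pairs of |ΔEF/Δx̃|
with the driver rescaled to [0, 1] over its filtered range. No canonical
definition of this "relative sensitivity" exists; outputs label it as the
package's definition. Under it, a site is θ-dominated when EF responds to
soil moisture only, and the ratio falls when EF carries a genuine VPD
response (the plant-limited, fine-textured regime).

## Demand projection

Potential transpiration from monthly air temperature and relative humidity
uses the classic humidity formula E = 0.0018·(25+T)²·(100−RH) mm month⁻¹
(clamped to zero below −25 °C); the cited sources do not print their exact
variant, so the constant and form are configurable. Annual PET is the
12-month sum. The aridity index AI = P/PET excludes hyperarid pixels
(AI ≤ 0.05) and flags humid ones (AI > 1). Per textural class a
four-parameter logistic is fitted to the numerical SOL supply curve
T_sol(θ) on its demand-relevant branch (up to ~1.15 × the 1.7·T_pot demand
ceiling, so the +65% projection stays inside the fit); if the RMSE exceeds
2% of the curve's range — which happens for the flattest fine-textured
curves — the model falls back to monotone interpolation with a warning.
Δθ_crit = θ(T_pot·(1+r/100)) − θ(T_pot) through the inverted curve.

## Synthetic data

Generators (`numpy.random.Generator`/PCG64, fully seeded, byte-reproducible)
emulate the statistical structure the pipeline assumes: summer rain events
followed by exponential dry-downs crossing the true threshold; EF exactly
linear-plus-plateau around θ_crit_true (so estimator error is attributable
to noise and filtering, not model mismatch — an optional smooth-knee variant
probes mismatch), truncated-Gaussian EF noise; diurnal PPFD/VPD/temperature
cycles for the sub-daily filters; per-tree lognormal-noise sap flux sharing
one soil-moisture series; and two-period climate grids whose demand change
is known in closed form. They do not emulate instrument artefacts, gap
structure, energy-balance non-closure or evaporation/transpiration
partitioning, so passing recovery tests demonstrates estimator correctness
under the assumed structure, not robustness to real-world data pathology.

Default generator conditions: three years, 8 dry-downs of 20 days, EF
plateau 0.75, EF noise sd 0.05, θ_crit_true 0.15 m³ m⁻³. The recovery study
runs truths {0.05, 0.10, 0.20, 0.30} × 20 seeds with the wet/dry ends of the
drying tracks shifted with the truth so both regimes are observed; the
root-length recovery study uses 12-class observation sets. These problem
sizes keep the full suite in a few minutes while leaving the Monte-Carlo
medians stable.

## Known limitations

* Single-layer topsoil: the initial transpiration decline is attributed to
  surface-layer drying; deep-root water uptake is out of scope.
* No gravity/elevation terms, no hydraulic redistribution, no time-dependent
  stomatal dynamics below the SOL, no soil-structure effects.
* The wet-soil critical VPD implied by the default vulnerability (≈3.6 kPa in
  sand) is higher than the ~2 kPa the observational EF fields suggest; the
  vulnerability slope cannot match that while keeping the ψ_x* sweep feasible
  (see the slope discussion above), and the sweep won.
* With geometric within-class variability, the fine endmember's higher
  air-entry value sustains supply to drier potentials, so the within-class
  θ_crit spread partially cancels; clay spans top out near 0.10 (soil
  variability) and 0.10 (vulnerability) under the shipped sd factors.
* The simulated texture trend of θ_crit/ψ_crit is strongly significant but
  not strictly monotone class-by-class: classes whose parameters sit off the
  sand-fraction ordering (sandy clay, the silt duplicate) break strictness,
  as the per-class scatter in the source parameters would suggest.
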