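# Methods

## Model chain

`portair` treats port-attributable PM₂.₅ as a linear functional of the
annual emissions inventory. A source-receptor matrix (SRM) `K[s, i, j]`
gives the annual-average concentration response (µg m⁻³) at receptor
cell *j* per tonne yr⁻¹ of species *s* emitted at source cell *i*. For
an inventory of records with total mass `E`, cell-allocation weights
`w`, the receptor field is

    C_j = Σ_records  E · w_i · K[s, i, j]

accumulated separately per source category, so every downstream
statistic (intake shares, per-source disparities, scenario deltas)
decomposes additively and exactly. Receptor cells aggregate to census
tracts by area-weighted overlap; a tract's value is the mean of the
overlapping cells' values weighted by intersection area. An alternative
(population-position lookup into the containing cell) exists in the
literature; area weighting was chosen because it behaves sensibly when
one coarse cell spans many tracts and because the constant-field
identity makes it exactly testable.

Exposure uses two indicators: the population-weighted mean
concentration per demographic group, and annual inhalation intake
(concentration × breathing rate × days × persons, µg→g). The two intake
formulations — per-tract sum and weighted-mean product — are
algebraically identical and asserted equal in the tests.

The relative exposure disparity of group *d* is
`(Conc_d − Conc_t)/Conc_t` on population-weighted means. Because the
demographic partition is exhaustive (six census race/ethnicity groups
plus an explicit remainder), the population-weighted average of the
group disparities is exactly zero — an identity, not an approximation,
and a conservation test. Per-source disparities apply the same statistic
to each category's concentration component independently; the package
reports the per-category evaluation and ranks categories by it, with
the group's overall disparity equal to the component-exposure-weighted
mean of the per-source values.

Income quintiles cut the income-ranked tract list at 20/40/60/80% of
*cumulative population* (each quintile ≈20% of people), with a
tract-count cut available as an option; population cutting is the
default because disparity ratios are person-level statistics. Q-Q
comparisons are person-weighted: each person carries their tract's
concentration, and matched quantiles are evaluated at the 5th/95th and
every 10th percentile using the midpoint-CDF weighted-quantile rule,
which makes the identical-distribution case land exactly on the 1:1
line.

## Health damages

Excess mortality uses the attributable-fraction form

    deaths_m = Pop_m · M0 · (RR_m − 1)/RR_m

which keeps attributable deaths below baseline deaths for any RR. Two
CRF variants are exposed: log-linear, RR = exp(β·ΔC) with
β = ln(HR₁₀)/10; and a GEMM-style saturating hazard
θ·ln(1+z/α)/(1+exp(−(z−µ)/ν)) on z = max(0, C − c₀), evaluated as
RR(ambient) − RR(ambient − ΔC) when an ambient level is configured so
that port-attributable ΔC is treated as a marginal change. Defaults —
HR₁₀ = 1.08, baseline mortality 0.0075 yr⁻¹, VSL $10.9M (2020 USD),
GEMM θ = 0.1430, α = 1.6, µ = 15.5, ν = 36.8, c₀ = 2.4 µg m⁻³ — are
standard literature magnitudes shipped as documented, config-overridable
placeholders; damages are always reported as a min–max range across the
configured variants.

## Emissions inventory

Direct sources cover six OGV operating modes (cruise, reduced-speed
zone, maneuvering, berthing, shifts, anchorage), CHC, CHE, port rail,
port other, and in-port drayage trucking (activity × per-vkm factors,
idling folded into equivalent vkm). Embodied sources follow the
pavement maintenance cycle: annual material volume = port area
(5.3 km²) × resurfacing fraction × replaced-layer thickness, with the
default cross-section 10 cm concrete / 2.5 cm aggregate / 7.5 cm
asphalt over a 47 cm compacted aggregate base that is never replaced
(standard resurfacing practice — only the upper layers are rebuilt).
The resurfacing fraction is scenario-swept over {2%, 5%}. Material
densities (concrete 2400, asphalt 2350, aggregate 1600 kg m⁻³) and the
cement-per-concrete mass fraction (0.14) are config values. Each
material is sourced from the facility nearest the port (Euclidean,
lexicographic tie-break); delivery trips = ceil(mass/capacity) emit
along the route with cell allocation proportional to in-cell route
length; refinery records are tagged by fuel end-use (`truck_fuel`,
`delivery_fuel`) so electrification scenarios can zero precisely the
truck-fuel share.

## Mitigation scenarios

Strategies are per-category multipliers in [0, 1] plus optional truck
substitutions (2045 diesel factor table, or full electrification with
nonemitting grid power, which zeroes both tailpipe and truck-fuel
refinery records). "Combine All" composes multiplicatively per category
with elimination absorbing; truck substitutions compose last-wins with
a logged warning. Multiplicative composition is the package's choice
for overlapping reductions — it is order-independent and treats each
20% cut as acting on whatever emissions remain. In this inventory the
catalog's "Rail Reduction" and "Port Rail Reduction" entries act on the
same single rail category; the 2045 truck scenario is scoped to in-port
drayage (not delivery trucks), flagged here as the alternative reading.
Because strategies act linearly, scenario concentration fields equal
the baseline fields with scaled category components; the tests assert
this commutation exactly.

## Synthetic domain

The generator emulates the statistical structure of a ~7.5M-person
coastal metro at reduced scale, defaulting to 200 tracts on a 60×60 km
planar domain (full-size 1,576-tract generation is a parameter away;
the default keeps the suite fast). Tract populations are lognormal with
the median and spread solved from target (25th, 75th) percentiles of
(3,500, 6,000). Demographics use the six census race/ethnicity groups
plus an exact remainder; a segregation parameter boosts one focal
group's share near the port with the domain-wide share renormalized, so
the group's population centroid shifts toward the sources — the
construction the disparity-recovery tests invert. Mean income declines
toward the port (fractional gradient 0.5 with lognormal noise), placing
the lowest quintile near the sources. The analysis grid refines
top-density-quartile coarse cells 3×3, mirroring variable-resolution
air-quality grids qualitatively.

The synthetic SRM is an isotropic Gaussian kernel
`peak_coeff · exp(−d²/(2σ²))` with σ = 6 km and peak coefficient
4×10⁻³ µg m⁻³ per t yr⁻¹, chosen once from a box-model dilution
argument so that a few-hundred-tonne near-port inventory yields
near-port concentrations of a few tenths of a µg m⁻³ and a
population-weighted mean of a few hundredths — the magnitudes typical
of single-port attribution studies. Precursor blocks scale the primary
kernel by secondary-formation yields (NOₓ 0.01, VOC 0.005, SO₂ 0.05,
NH₃ 0.10). What the kernel does *not* emulate: wind-direction
anisotropy, coastal meteorology, nonlinear ammonium/sulfate chemistry,
or the long-range plume shapes of a real reduced-complexity model.
Passing tests therefore demonstrate the correctness of the accounting
chain — linearity, conservation, weighting, ranking — on a physically
plausible operator, not the accuracy of any real domain's concentration
surface.

## Numerical choices

- All geometry is planar meters; no CRS handling anywhere.
- Concentrations below 10⁻³⁰⁰ in magnitude are clamped to exactly 0 and
  logged, avoiding sign noise in ratio statistics.
- Empty distance bins are reported as missing (NaN), never zero.
- Ties: nearest-facility by lexicographic id; quintile ranking by
  (income, tract_id); quintile membership by the midpoint of a tract's
  cumulative-population interval.
- Degenerate inputs reject loudly: zero group population (undefined
  weighted mean), zero total concentration (undefined disparity),
  tracts without grid overlap, routes off-grid, unknown materials,
  HR < 1, mixed dollar-years.
- CSV readers use round-trip float parsing so write→read→write is
  byte-identical.

## Limitations

Single-pollutant (PM₂.₅) mortality only; no morbidity, age
stratification, or income-adjusted VSL. Off-port drayage beyond the
freeway entrances, goods' embodied emissions, and construction-phase
emissions are out of scope of the inventory. The synthetic damages
range reflects the placeholder CRF/VSL configuration and the reduced
domain scale, not a calibrated forecast; with real inputs the same code
paths apply unchanged.
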