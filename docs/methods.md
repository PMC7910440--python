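# Methods

`radh2` models the production of hydrogen and oxidants by radiolysis of
porewater in marine sediment, and compares that energy supply with
organic-fuelled respiration inferred from porewater chemistry. This note
records the model, its parameters, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Radiolytic production model

Sediment radioactivity comes from the ²³⁸U and ²³⁵U decay series, the ²³²Th
series, and ⁴⁰K. Bulk U (ppm), Th (ppm) and K₂O (wt%) of the solid phase are
split into isotopes with natural-abundance mass fractions and converted to
activities A = λN (decays yr⁻¹ g⁻¹ solid). Both uranium series and the
thorium series are assumed to be in secular equilibrium, so the energy
released per parent decay is the chain sum, tabulated separately for α, β
and γ radiation (`src/radh2/data/isotopes.csv`; mean absorbed β energies,
neutrinos excluded). These chain sums are standard compilation values, not
site measurements; they ship as a CSV and every API accepts a replacement
table. Disequilibrium (e.g. radon loss) is ignored.

The volumetric H₂ production rate per bulk sediment volume is

    P_H2 = Σ_i Σ_series  A_m · ρ (1 − φ) · E_i · G(H₂)_i / 100

in molecules cm⁻³ yr⁻¹, where ρ is grain density (g cm⁻³), φ porosity, E_i
the chain decay energy (eV per parent decay) and G(H₂)_i the radiolytic
yield in molecules per 100 eV. The 1/100 scaling is applied at exactly one
place in the code. Production is linear in each activity and in (1 − φ);
these identities are property-tested.

Water radiolysis splits water as 2H₂O → H₂ + H₂O₂, so oxidant production in
electron equivalents equals H₂ production in electron equivalents by
construction (2 e⁻ per H₂). The electron-equivalent ledger (2 per H₂, 4 per
O₂, 4 per organic C) is the single conversion point between chemical
species.

### Yield table

The packaged G(H₂) table (`data/yields.csv`) encodes the experimentally
established catalysis of radiolysis by marine sediment: relative to pure
water, mean α-yields are amplified ~13× (abyssal clay, with a per-sample
maximum of 27×), 15× (clay-bearing siliceous ooze), 12× (calcareous marl)
and 5× (calcareous ooze); γ-yields by 8× (siliceous ooze), 4× (abyssal
clay) and 2× (calcareous ooze and marl). Seawater yields are
indistinguishable from pure water (α G = 1.30 ± 0.13; γ G = 0.45). Only
lithology means are packaged; per-sample rows are absent and flagged as
such. Lithogenous sediment has no published amplification factor and is
assigned the conservative calcareous-ooze factors (5× α, 2× γ) — override
the table if better constraints exist.

β-yields have never been measured for wet sediment; the table resolves β
queries to the γ entry of the same medium. `beta_assumption_sensitivity`
quantifies the consequences: with the packaged energy partitions and
lithology-average compositions, β radiation carries ~3% of total production,
the β=pure-water alternative shifts depth-integrated totals by ~2%, and the
β=α alternative by ~19% (because sediment α-catalysis is much stronger than
γ-catalysis). Slurry-derived G values are applied unchanged to in situ
porewater.

## Sediment columns

Porosity follows an Athy-type exponential φ(z) = φ₀ e^(−c₀ z) with the
compaction coefficient chosen by water-depth class: 0.5×10⁻³ m⁻¹ on the
shelf (0–200 m), 1.7×10⁻³ m⁻¹ on the margin (200–2500 m), 0.85×10⁻³ m⁻¹ in
the abyss (>3500 m). The unpublished 2500–3500 m band is assigned the
abyssal coefficient (overridable). Columns are integrated in 1-m steps with
porosity evaluated at interval midpoints; integration halts at basement or
where φ reaches 0.1%, whichever is shallower (with the packaged
coefficients the halt triggers only for multi-kilometre margin columns).
Lithology, composition, grain density and G are constant with depth unless
a layered column is supplied explicitly.

Sediment age is linear in depth: age(z) = z / (Z / basement age). This
mean-accumulation-rate model ignores compaction of the age scale and
hiatuses; site-specific age models can be substituted.

## Expected dissolved H₂ (no consumption)

At steady state with a depth-constant source and zero-concentration
boundaries at the seafloor (loss to the ocean) and basement (loss to
permeable crust), the expected profile is the parabola

    H₂(x) = ½ (P φ F / D) (xZ − x²),

with maximum PφFZ²/(8D) at mid-column. P here is per porewater volume; the
per-bulk-volume rate is divided by φ at exactly one conversion site.
D is the free-solution diffusivity of H₂ at in situ temperature (linearized
as (2.45 + 0.082 T°C)×10⁻⁵ cm² s⁻¹; override with a measured value), and
the formation factor defaults to Archie's F = φ⁻² when not supplied.

Layered columns are solved two ways: a closed-form two-layer solution
(continuity of concentration and of the flux −(D/(φF)) dC/dx at the
interface) and a conservative finite-volume solver. The solver uses exact
inter-node transmissibilities (h / ∫dx/k) and exact cell-averaged sources,
which makes it exact to round-off on uniform columns (the solution is a
quadratic) and keeps interface errors below 10⁻⁵ relative regardless of
whether layer boundaries align with the grid.

Measured profiles are compared to expected ones as per-depth ratios;
measurements below the detection limit are replaced by the limit and the
ratios flagged as lower bounds. A median ratio above 10 raises the
consumption flag: sustained in situ consumption is the only steady-state
explanation for concentrations orders of magnitude below supply. With
typical abyssal-clay parameters and detection limits of 1–5 nM the expected
profiles sit roughly 3–5 orders of magnitude above measurements.

## Net-rate inversion

O₂ (oxic columns) and DIC (anoxic columns) profiles are fitted with a
standard interpolating Akima spline (≥5 points, strictly increasing
depths). The diffusive flux per bulk sediment area J = −(D/F) dC/dx is
evaluated from the fitted derivative, and the net volumetric rate over each
depth bin is the flux divergence (J_bottom − J_top)/Δz, assuming steady
state and no advection or burial. The sign convention is net production of
the measured species, so O₂ consumption is negative. Bins default to the
intervals between successive data midpoints.

Two numerical choices matter:

* **End fluxes.** The depth-integrated rate telescopes to the two boundary
  fluxes, and Akima end polynomials extrapolate their derivative poorly, so
  the fluxes at the shallowest and deepest data points use one-sided
  three-point parabolic differences of the data instead of the spline.
  This took the noise-free recovery error of the depth-integrated rate on
  forward-modelled profiles from tens of percent to <1%.
* **Uncertainty.** Measurement noise is propagated by Monte Carlo:
  concentrations perturbed with independent Gaussian noise at their
  reported standard deviation, refitted and re-inverted (default 200–500
  draws, explicit seed, bit-reproducible). On synthetic profiles with 1 µM
  noise the 2-sd intervals cover the true bin rates ~95% of the time.

Akima interpolation is not linear in the data (its slope weights are
data-dependent); the inversion is exactly homogeneous of degree 1 and
exactly additive under linear concentration shifts, and those are the
properties the test suite asserts.

## Bioenergetics and the ratio analysis

In situ Gibbs energy of aerobic H₂ oxidation (Knallgas reaction,
H₂ + ½O₂ → H₂O):

    ΔG_r = ΔG°_r(T,P) + 2.3 R T log₁₀ Q,   Q = a_H₂O / (a_H₂ · a_O₂^½),

with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ and ΔG_r in kJ per mol H₂. ΔG°_r(T,P)
should be supplied from site thermodynamics; the shipped default is a rough
linearization around −263 kJ mol⁻¹ at 25 °C, adequate only for
order-of-magnitude screening. Activity coefficients default to 1 with a
warning; ion-interaction models are out of scope. Where H₂ is below
detection the energy is reported as a bound at the detection limit.

The ratio analysis divides radiolytic e⁻eq production by the magnitude of
the net organic-fuelled rate (O₂ or DIC, converted to e⁻eq) per interval,
against interval age. The H₂-based and oxidant-based ratios are identical
in electron equivalents. The crossover age is the first age at which the
ratio reaches 1, linearly interpolated between bracketing bins; with a
depth-constant radiolytic supply and organic rates decaying as R₀e^(−k·age)
it equals ln(R₀/P)/k, which the tests recover within one age bin. With the
generator's defaults the crossover falls at 2–5 Ma.

## Global rollup

Ocean cells on a lat/lon grid (default synthetic mosaic; any NetCDF grid
with lithology, thickness, seafloor porosity and water depth can be
supplied) are reclassified before integration: Atlantic abyssal clay is
treated as calcareous marl (Atlantic "clay" seafloor typically overlies
carbonate-rich sections), a Southern Ocean opal belt (57–66°S) is set to
siliceous ooze, and the 50–57°S, 66–90°S and Arctic bands default to
lithogenous where unclassified. Each lithology carries a parameter set
(U/Th/K, grain density, G values) from `data/lithologies.csv`; the U/Th/K
values are typical literature compositions (pelagic clay, carbonate, opal,
upper continental crust for lithogenous sediment).

Each cell is depth-integrated exactly as a single column: the 1-m midpoint
sum of (1 − φ(z)) has a closed geometric form (including the 0.1% halt)
that is identical to the explicit loop to round-off, which is what makes a
5-arc-minute global pass cheap. Cell areas are spherical quadrilaterals on
the authalic radius (6371.0 km); the full tiling closes to 4πR² within
0.1%. Unclassified cells are excluded and counted in a coverage
diagnostic; zero-thickness (land) cells contribute zero but are not counted
as unclassified. Because the question of whether a single printed global
figure should count H₂, oxidants, or both is convention-dependent, the
result object reports the H₂ e⁻eq total, the (identical) oxidant total, and
their sum.

## Synthetic data

The generator exists so that every stage is testable without downloads; all
draws flow from one explicit seeded generator.

* **Columns**: lithology-typical U/Th/K (±20% lognormal), grain density,
  water-depth and thickness ranges; abyssal-clay seafloor porosity drawn
  uniformly from the observed 0.80–0.85 range.
* **Porewater profiles**: a known net-rate field (canonically exponential
  decay with depth, surface rate 1–2×10⁻¹¹ mol cm⁻³ yr⁻¹, ~10 m e-fold,
  matching slow oxic deep-sea respiration) is forward-solved with fixed
  seafloor concentration and zero basal flux, sampled at ~25 depths, and
  perturbed with 1 µM Gaussian noise; the ground truth is returned for
  recovery tests.
* **Grids**: a smooth random elevation field defines ~30% land, a concave
  hypsometric mapping puts most ocean floor at abyssal depth (median
  ~3.5 km), margins get mostly thick lithogenous sediment and the open
  ocean thin abyssal clay/ooze. Thickness is margin-correlated lognormal
  spanning ≥4 orders of magnitude (0.3 m–12 km), which drives the ~5 orders
  of magnitude spread in areal production.

What the generator does **not** emulate: real bathymetry and basin
geometry, site-specific stratigraphy and hiatuses, correlated (non-i.i.d.)
measurement errors, advection, and depth-varying lithology. Passing tests
therefore demonstrate correctness of the computational chain under the
model's own assumptions, not fidelity to any particular drill site. The
synthetic-globe total (~1×10¹³ mol e⁻eq yr⁻¹ at 1° resolution, ~1% of the
~10¹⁵ mol e⁻eq yr⁻¹ organic flux to the seafloor) reflects realistic
parameter magnitudes, but a defensible global figure requires the published
lithology/thickness/porosity/bathymetry rasters, which are deliberately not
bundled.

## Problem sizes and defaults

The shipped analyses use: 1-m depth steps (0.1-m refinement changes areal
rates by <0.5%); 2001-node forward solves; 25-point profiles over 30-m
columns for inversion studies; 200 Monte-Carlo draws for rate standard
deviations and 200 replicate profiles for coverage studies; 1°×1°
synthetic globes (the closed-form cell integral makes resolution cheap).

## Known limitations

* Chain energy partitions and isotopic constants are compilation values;
  small differences against other tables propagate linearly into rates.
* The lithogenous yield factors are assigned, not measured.
* The β=γ yield substitution is untested experimentally; its footprint is
  quantified but not constrained.
* ΔG°_r(T,P) default is a linearization, not a thermodynamic model.
* The inversion assumes steady state, no advection and depth-resolved
  transport fields; its published counterpart's exact depth binning is not
  reproduced, only the recovery properties.
* The age model is linear in depth between seafloor and basement.
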