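# Methods

## Scope and data model

The pipeline operates on regional annual aggregates, not gridded
fields. Its interchange container is a tidy table of fluxes per
region, year, component and management class, in native units:
net soil CO₂ exchange (Pg C yr⁻¹, negative = sink), two
land-use-change (LUC) emission streams — deforestation to pasture and
grassland to cropland (Pg C yr⁻¹, carried under the managed class,
since conversion is a management act on the grassland side) — CH₄ as
CH₄-C (Tg C yr⁻¹) and N₂O as N₂O-N (Tg N yr⁻¹). Keeping element-mass
units internally and converting to molecule mass only in the balance
module puts all conversion factors (44/12, 16/12, 44/28) in one place.

## CO₂-equivalent balance

The balance is a linear combination of the five components with GWP100
constants as *data*, defaulting to 34 (CH₄) and 267 (N₂O) — the
with-feedback values the forcing module itself reproduces (below).
Decadal means are arithmetic means over calendar decades [y₀, y₀+9];
a decade not fully covered raises an error rather than being padded.
The 2010–2012 tail of the default period therefore belongs to no
default decade; callers can request it explicitly. The managed/sparse
split partitions rows by label; partitioning is exact by construction
and asserted in tests at 1 part in 10¹².

## Tier 1/2 emission calculators

Enteric CH₄ uses the gross-energy method: intake × 18.45 MJ kg⁻¹ ×
Ym / 55.65 MJ kg⁻¹, with Ym = 0.065. Manure CH₄ is volatile solids ×
B₀ × MCF × 0.67 kg m⁻³. Direct soil N₂O applies EF3_PRP = 0.02 to
pasture excreta N, EF1 = 0.01 to fertilizer and applied manure N, an
equal deposition factor to atmospheric N deposition, and a
manure-management factor (0.005, solid-storage mid-range) to housed
excreta N. Wild grazers get per-head CH₄ (38 kg head⁻¹ yr⁻¹) and
excreta N (60 kg head⁻¹ yr⁻¹, through EF3_PRP); they are the only
emission source of the sparse class — nitrogen deposition on natural
grassland is folded into the managed deposition term rather than split,
a simplification consistent with treating it as a minor managed-class
contribution. Soil CH₄/N₂O uptake is excluded. Indirect N₂O from
volatilization and leaching (EF4/EF5 pathways) is not implemented.
Every factor is an overridable field with an uncertainty descriptor
(normal or lognormal) used by the Monte Carlo stage. Every calculator
is homogeneous of degree 1 in its activity argument; totals are
exactly additive over sources.

## Pre-industrial extrapolation and anthropogenic fluxes

Model-era fluxes start at the 1860 reference year. Earlier years are
reconstructed by rule: CO₂ and LUC are zero (pre-industrial grassland
assumed CO₂ neutral); managed CH₄/N₂O scale with the regional human
population index relative to 1860; sparse CH₄/N₂O scale with the
regional wild-grazer population over 1800–1859 and are frozen at the
1800 level over 1750–1799. Decadal population anchors can be
interpolated to annual values piecewise-linearly. Anthropogenic fluxes
subtract the 1750 level pointwise in time (the baseline is a flux
level, not a cumulative stock) for CH₄ and N₂O; CO₂ and LUC pass
through, since even the sparse-grassland sink is driven by indirect
human forcing (CO₂ fertilization, N deposition, climate change).
Whether the managed scaler should be rural or total population is
undecidable from aggregate inputs; the pipeline uses the total
population index supplied in the activity table.

## Impulse-response forcing model

Atmospheric burdens follow discrete convolution of annual emissions
with gas impulse-response functions: a four-pool CO₂ response
(fractions 0.2173/0.2240/0.2824/0.2763, timescales ∞/394.4/36.54/4.304
yr) and single-exponential decay for CH₄ (perturbation lifetime
12.4 yr, with a lifetime-adjustment knob for ozone-precursor effects)
and N₂O (121 yr). Radiative efficiencies are linear by default
(1.37×10⁻⁵ / 3.63×10⁻⁴ / 3.00×10⁻³ W m⁻² ppb⁻¹); a logarithmic CO₂
option exists for large perturbations, but attribution perturbations
are 1%, so linearization error is second-order and linear mode is the
default. Indirect components ride on direct forcing: +50%
(tropospheric O₃) and +15% (stratospheric H₂O) for CH₄; a net
stratospheric-O₃ multiplier for N₂O (calibrated, negative — N₂O-driven
ozone chemistry offsets part of its direct forcing).

Time stepping is annual with sub-annual refinement (default 4 steps
per year; a convergence test pins the 4-vs-16-step GWP difference
below 1%). Forcing is reported at the start of each calendar year:
the first year of any run is exactly zero and forcing at year t is
independent of emissions in years ≥ t (causality is exact, not
approximate).

Climate–carbon feedback is an additional CO₂ flux proportional to the
temperature response (two-box kernel, 0.631 K/(W m⁻²) at 8.4 yr and
0.429 at 409.5 yr) of the forcing being evaluated, applied in a single
pass and — for metrics — consistently to both the gas and the CO₂
reference pulse. It is enabled for metric computation and disabled by
default for forcing runs, where the historical CO₂ response is already
part of the input fluxes.

Two parameters are not pinned by the published parameter family: the
feedback gain γ (Pg C yr⁻¹ K⁻¹) and the N₂O stratospheric-O₃
multiplier. `scripts/calibrate_gwp.py` solves for them once (CH₄
first — its metric is independent of the N₂O multiplier — then N₂O)
so that the model's own GWP100 with feedback equals the 34/267
constants used by the balance module; the solved values
(γ = 4.139 Pg C yr⁻¹ K⁻¹, f_stratO3 = −0.0693) are frozen as defaults.
Without feedback the model yields GWP100 ≈ 28.5 (CH₄) and ≈ 285 (N₂O
before the O₃ offset), squarely in the published no-feedback range —
the calibration adjusts only the two genuinely free parameters, not
the AR5-style backbone. GWP(CO₂) is exactly 1 by construction.

Albedo forcing is a diagnostic outside the gas-cycle model:
RF(t) = ½ Σ_regions Σ_biomes coef·(area(t) − area(1750)), with
per-(region, biome) coefficients in mW m⁻² per km². The ½ factor is
applied exactly once: a transition between two biomes changes both
areas, and halving prevents double-counting when biome-specific
forcings are summed. The managed/sparse split assigns
forest/cropland/managed-grassland deviations to the managed aggregate
and sparse-grassland/other to the sparse one.

## Normalized-marginal attribution

A control run uses the full anthropogenic trajectories (plus an
optional rest-of-world background). For each of 9 regions × 8 sectors
(CO₂ soil, CH₄, N₂O — each managed and sparse — plus the two LUC
streams) and for the background block, a factorial run scales that
key's entire 1750–2012 trajectory by 1 − ε (ε = 0.01). Differences
from the control at the evaluation year (default 2012), normalized by
their sum, give shares; shares × control total give contributions that
partition the total exactly. In linear mode each contribution equals
the stand-alone forcing of that sector's emissions — the test suite's
brute-force oracle — and shares are invariant to ε to first order.
Albedo forcing bypasses the factorial machinery and is added to the
managed/sparse aggregates as its own term.

## Monte Carlo uncertainty

One multiplicative error per sample on the whole CO₂ budget (relative
sd 0.46) and one on LUC emissions (0.31): the dominant uncertainty is
systematic (model structure), so errors are fully correlated across
regions and years within a sample, which is also what makes the
*global budget's* relative sd equal the configured value. CH₄/N₂O are
re-derived by sampling emission factors — normal for symmetric
uncertainties (mean-centred, clipped at zero), lognormal for
asymmetric ones with the central value as the median (unbiased in log
space) — and exploiting the exact linearity of each Tier source in its
factor product: per-source central emissions times the sampled factor
ratio is an exact re-computation stored compactly, not an
approximation. Forcing-model parameters (radiative efficiencies,
lifetimes) are drawn once per sample, paired one-to-one with the flux
draws rather than crossed. Inventory constraints weight the ensemble
with Gaussian likelihoods on global gas emissions at a reference year;
summaries are weighted means and *population-convention* weighted
standard deviations (stated here to make the test fixtures
unambiguous), with the effective sample size 1/Σw² reported. The
default sample count is 10,000, with 500 used in pipeline runs and
smaller sizes in tests; sampling is vectorised so the full size runs
in seconds.

## Synthetic scenarios

The generator's defaults describe a plausible world at the scale of
the real one: nine regions; livestock growing exponentially at
1.05% yr⁻¹ from ~2.3×10⁸ head globally in 1750 (≈3.6×10⁹ by 2012);
wild grazers declining with ~75-yr half-lives from ~3.8×10⁸ head;
herd-average intake 650 kg DM head⁻¹ yr⁻¹ (70% grazed), 2% of intake
excreted as N; fertilizer rising logistically after ~1950 to regional
plateaus; a soil sink growing with a CO₂-index (ppm above 278, ~115 by
2012) at regional coefficients that give a global sink of roughly
−0.6 Pg C yr⁻¹ today, 80%-dominated by the sparse class; AR(1)
interannual noise (sd 0.04 Pg C yr⁻¹ per region, lag-1 correlation
0.5); Gaussian-in-time LUC pulses (Latin American deforestation
peaking in 1970, northern-hemisphere cropland conversion peaking
1880–1950). The resulting global magnitudes — pre-industrial CH₄-C
≈ 13.4 Tg C yr⁻¹, present-day CH₄-C ≈ 38 Tg C yr⁻¹, LUC ≈ 0.27 Pg C
yr⁻¹ in the 2000s — sit at the scale of published grassland budgets.
Land-cover tables move area between biomes in step with the emission
pulses and herd growth (at fixed carbon-density and stocking
conversions), with flows limited by the donor pool so areas stay
non-negative and regional totals are conserved exactly.

Randomness derives from a single seed; each (region, variable) pair
hashes to its own sub-stream, so adding a region does not perturb the
draws of existing ones.

What the generator does *not* emulate: spatial (sub-regional)
heterogeneity, interactions between drivers (fire–grazing coupling,
degradation thresholds), erosion fluxes, peatland emissions, or
realistic covariance between regions' climate noise. Passing tests
therefore demonstrate the correctness of the accounting, forcing,
attribution and uncertainty machinery under realistic magnitudes and
trends — not the realism of any particular regional number.

## Numerical choices and degenerate inputs

* Exact rational conversion factors; component sums asserted to
  1 part in 10¹².
* Convolution kernels are evaluated at sub-step midpoints, which keeps
  a pulse's own-step survival consistent with the IRF at second order.
* A single decadal anchor extends as a constant with a warning; a
  fully empty activity table yields an empty (not invalid) record set;
  an all-zero sector in attribution yields a zero difference rather
  than an error, while an all-zero *total* is rejected (no attribution
  is possible).
* Constraint weights are computed in log space and shifted by the
  maximum before exponentiation; total underflow raises an error
  advising wider constraint sds.
* Normal factor draws are clipped at zero to preserve non-negativity
  of emissions; at the shipped dispersions the clipped mass is < 10⁻⁴.

## Known limitations

The forcing model is deliberately compact: no temperature or
sea-level projection, no regional forcing patterns, no interactive
atmospheric chemistry (indirect effects are fixed multipliers), and a
single global atmosphere. LUC area bookkeeping uses fixed carbon
densities per transition. The albedo coefficients shipped with the
synthetic scenarios are synthetic placeholders with physically
motivated signs, not satellite-derived values. Wild-grazer population
trajectories are inputs; the package does not reconstruct them.
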