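"""Synthetic regional grassland scenarios, 1750-2012.

The generator emulates the statistical structure of land-surface-model
output and its drivers so the whole pipeline is testable without any
external data set:

* monotone livestock growth (global herd grows from a few hundred
  million head in 1750 to a few billion today),
* exponential wild-grazer decline (hunting, disease, habitat loss),
  strongest over the nineteenth century,
* a CO2-fertilization-driven soil carbon sink that grows with an
  atmospheric-CO2 index, plus AR(1) interannual climate noise,
* land-use-change emission pulses, Gaussian in time — deforestation to
  pasture peaking around 1970 in Latin America, grassland-to-cropland
  conversion peaking earlier in the northern-hemisphere breadbaskets,
* land-cover trajectories whose transitions conserve total regional
  area.

CH4 and N2O fluxes are not drawn directly: the generator produces
activity data (intake, excreta and fertilizer nitrogen, head counts)
and runs them through the Tier 1/2 calculators of
:mod:`grassflux.tier`, so the synthetic fluxes are exactly consistent
with the emission-factor machinery downstream stages perturb.

Randomness: one integer seed; each (region, variable) pair gets an
independent sub-stream derived by stable hashing, so adding a region
leaves the others' draws untouched.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from grassflux.tables import BIOMES, make_flux_table
from grassflux.tier import EmissionFactorSet, emissions_table, emissions_to_flux_components

__all__ = [
    "ScenarioConfig",
    "RegionParams",
    "DEFAULT_REGIONS",
    "generate_scenario",
    "grazer_population_series",
    "degenerate_region_params",
]

DEFAULT_REGIONS = (
    "North America",
    "Latin America",
    "Europe",
    "Russia",
    "Sub-Saharan Africa",
    "Middle East & North Africa",
    "South Asia",
    "East & Southeast Asia",
    "Oceania",
)

#: kg dry-matter intake per ruminant head per year (herd-average,
#: grass-fed share; cattle ~2500, small ruminants ~350)
INTAKE_PER_HEAD = 650.0
GRAZED_FRACTION = 0.7
#: kg N excreted per kg dry matter ingested
EXCRETA_N_PER_DM = 0.02
#: fraction of housed excreta N returned to fields as manure
MANURE_RETURN_FRACTION = 0.5
#: km2 of forest cleared per Pg C of deforestation-to-pasture emissions
KM2_PER_PGC_DEFOREST = 8.3e4  # ~120 t C ha-1 biomass+soil loss
#: km2 converted per Pg C of grassland-to-cropland emissions
KM2_PER_PGC_CROP = 1.0e5
#: km2 of sparse grassland brought under management per additional head
KM2_PER_HEAD = 0.003


@dataclass(frozen=True)
class RegionParams:
    """Trend parameters of one region's synthetic trajectories."""

    livestock_heads_1750: float = 2.5e7
    livestock_growth: float = 0.0105  # fraction yr-1, exponential
    wild_heads_1750: float = 4.0e7
    wild_half_life: float = 75.0  # yr; math.inf = no decline
    human_pop_growth: float = 0.008  # fraction yr-1, index = 1 at 1860
    sink_growth_managed: float = 1.0e-4  # Pg C yr-1 per ppm-equivalent index
    sink_growth_sparse: float = 4.2e-4
    luc_pasture_center: float = 1950.0  # yr
    luc_pasture_width: float = 45.0  # yr
    luc_pasture_amplitude: float = 0.0  # Pg C yr-1 at pulse peak
    luc_crop_center: float = 1900.0
    luc_crop_width: float = 55.0
    luc_crop_amplitude: float = 0.0
    climate_sd: float = 0.04  # Pg C yr-1, stationary sd of the AR(1) noise
    ar1: float = 0.5  # lag-1 autocorrelation of the climate noise
    fertilizer_N_2012: float = 2.0e8  # kg N yr-1 at the logistic plateau
    fertilizer_midpoint: float = 1980.0
    N_deposition_base: float = 2.0e7  # kg N yr-1 pre-industrial level
    N_deposition_growth: float = 8.0e7  # kg N yr-1 added by 2012

    def validate(self, region: str) -> None:
        for name in ("climate_sd", "livestock_heads_1750", "wild_heads_1750",
                     "fertilizer_N_2012", "N_deposition_base", "N_deposition_growth"):
            if getattr(self, name) < 0:
                raise ValueError(f"region {region!r}: {name} must be >= 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError(f"region {region!r}: ar1 must be in [0, 1)")
        if self.wild_half_life <= 0:
            raise ValueError(f"region {region!r}: wild_half_life must be > 0")


_REGION_OVERRIDES: dict[str, dict] = {
    "North America": dict(livestock_heads_1750=1.0e7, wild_heads_1750=8.0e7,
                          luc_crop_amplitude=0.060, luc_crop_center=1900.0,
                          sink_growth_sparse=5.5e-4),
    "Latin America": dict(livestock_heads_1750=1.5e7, wild_heads_1750=5.0e7,
                          luc_pasture_amplitude=0.250, luc_pasture_center=1970.0,
                          luc_pasture_width=40.0),
    "Europe": dict(livestock_heads_1750=5.0e7, wild_heads_1750=1.0e7,
                   luc_crop_amplitude=0.055, luc_crop_center=1880.0,
                   fertilizer_N_2012=1.5e9, N_deposition_growth=2.0e8),
    "Russia": dict(livestock_heads_1750=2.0e7, wild_heads_1750=4.0e7,
                   luc_crop_amplitude=0.030, luc_crop_center=1900.0,
                   sink_growth_sparse=6.0e-4),
    "Sub-Saharan Africa": dict(livestock_heads_1750=3.0e7, wild_heads_1750=1.2e8,
                               wild_half_life=90.0),
    "Middle East & North Africa": dict(livestock_heads_1750=2.0e7, wild_heads_1750=1.5e7,
                                       sink_growth_sparse=2.0e-4),
    "South Asia": dict(livestock_heads_1750=5.0e7, wild_heads_1750=2.0e7,
                       luc_crop_amplitude=0.030, luc_crop_center=1950.0,
                       fertilizer_N_2012=1.0e9),
    "East & Southeast Asia": dict(livestock_heads_1750=3.0e7, wild_heads_1750=2.5e7,
                                  luc_pasture_amplitude=0.075, luc_pasture_center=1975.0,
                                  fertilizer_N_2012=1.5e9),
    "Oceania": dict(livestock_heads_1750=3.0e6, wild_heads_1750=2.0e7,
                    sink_growth_sparse=5.0e-4),
}


def default_region_params(region: str) -> RegionParams:
    return RegionParams(**_REGION_OVERRIDES.get(region, {}))


def degenerate_region_params() -> RegionParams:
    """Parameters with every trend amplitude and noise sd at zero."""
    return RegionParams(
        livestock_growth=0.0, wild_half_life=math.inf, human_pop_growth=0.0,
        sink_growth_managed=0.0, sink_growth_sparse=0.0,
        luc_pasture_amplitude=0.0, luc_crop_amplitude=0.0,
        climate_sd=0.0, fertilizer_N_2012=0.0, N_deposition_growth=0.0,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario definition: regions, year span, seed, per-region trends."""

    regions: tuple[str, ...] = DEFAULT_REGIONS
    start_year: int = 1750
    end_year: int = 2012
    seed: int = 0
    region_params: dict[str, RegionParams] = field(default_factory=dict)

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region identifiers must be unique")
        for region, params in self.region_params.items():
            if region not in self.regions:
                raise ValueError(f"region_params for unknown region {region!r}")
            params.validate(region)

    def params_for(self, region: str) -> RegionParams:
        return self.region_params.get(region, default_region_params(region))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def _substream(seed: int, region: str, variable: str) -> np.random.Generator:
    """Independent RNG stream for one (region, variable) pair."""
    digest = hashlib.sha256(f"{seed}:{region}:{variable}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def grazer_population_series(initial_heads: float, half_life: float, years: np.ndarray) -> np.ndarray:
    """Exponentially declining wild-grazer population.

    value(t) = initial * 2 ** (-(t - t0) / half_life), t0 = first year.
    """
    if initial_heads < 0:
        raise ValueError("initial_heads must be >= 0")
    if not half_life > 0:
        raise ValueError("half_life must be > 0")
    years = np.asarray(years, dtype=float)
    if initial_heads == 0:
        return np.zeros_like(years)
    exponent = -(years - years[0]) / half_life
    return initial_heads * np.power(2.0, exponent)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - ar1**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = ar1 * x[i - 1] + shocks[i - 1]
    return x


def _gaussian_pulse(years: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    if amplitude == 0.0:
        return np.zeros_like(years, dtype=float)
    return amplitude * np.exp(-0.5 * ((years - center) / width) ** 2)


def co2_index(years: np.ndarray) -> np.ndarray:
    """ppm-equivalent atmospheric-CO2 index (0 in 1750, ~115 in 2012)."""
    frac = (np.asarray(years, dtype=float) - 1750.0) / 262.0
    return 115.0 * np.clip(frac, 0.0, None) ** 2.5


def _region_activity(region: str, p: RegionParams, years: np.ndarray) -> pd.DataFrame:
    t = years.astype(float)
    livestock = p.livestock_heads_1750 * np.exp(p.livestock_growth * (t - t[0]))
    wild = grazer_population_series(p.wild_heads_1750, p.wild_half_life, years)
    human = np.exp(p.human_pop_growth * (t - 1860.0))
    intake = livestock * INTAKE_PER_HEAD
    grazed = intake * GRAZED_FRACTION
    harvested = intake * (1.0 - GRAZED_FRACTION)
    fert = p.fertilizer_N_2012 / (1.0 + np.exp(-(t - p.fertilizer_midpoint) / 12.0))
    dep = p.N_deposition_base + p.N_deposition_growth * co2_index(years) / co2_index(
        np.array([2012]))[0]
    housed_n = harvested * EXCRETA_N_PER_DM
    return pd.DataFrame({
        "region": region,
        "year": years,
        "grazed_dm": grazed,
        "harvested_dm": harvested,
        "excreta_N_pasture": grazed * EXCRETA_N_PER_DM,
        "excreta_N_housed": housed_n,
        "fertilizer_N": fert,
        "manure_applied_N": MANURE_RETURN_FRACTION * housed_n,
        "N_deposition": dep,
        "livestock_heads": livestock,
        "wild_grazer_heads": wild,
        "human_pop_index": human,
    })


def _region_co2_fluxes(region: str, p: RegionParams, years: np.ndarray, seed: int) -> list[dict]:
    index = co2_index(years)
    records = []
    for cls, coef, noise_sd in (
        ("managed", p.sink_growth_managed, 0.4 * p.climate_sd),
        ("sparse", p.sink_growth_sparse, p.climate_sd),
    ):
        rng = _substream(seed, region, f"co2_{cls}")
        noise = _ar1_noise(rng, len(years), noise_sd, p.ar1)
        values = -coef * index + noise
        records += [
            {"region": region, "year": int(y), "component": "co2_soil",
             "management": cls, "value": float(v)}
            for y, v in zip(years, values)
        ]
    for comp, center, width, amp in (
        ("luc_pasture", p.luc_pasture_center, p.luc_pasture_width, p.luc_pasture_amplitude),
        ("luc_crop", p.luc_crop_center, p.luc_crop_width, p.luc_crop_amplitude),
    ):
        pulse = _gaussian_pulse(years, center, width, amp)
        records += [
            {"region": region, "year": int(y), "component": comp,
             "management": "managed", "value": float(v)}
            for y, v in zip(years, pulse)
        ]
    return records


_INITIAL_AREAS = {  # km2, per region
    "forest": 3.0e6,
    "grassland_sparse": 4.5e6,
    "grassland_managed": 0.8e6,
    "cropland": 0.4e6,
    "other": 1.3e6,
}


def _region_landcover(region: str, p: RegionParams, years: np.ndarray,
                      activity: pd.DataFrame, luc: pd.DataFrame) -> pd.DataFrame:
    """Annual biome areas; transitions conserve the regional total.

    Flows: forest -> managed grassland (deforestation to pasture, area
    tied to the emission pulse), managed grassland -> cropland (tied to
    the cropland emission pulse), sparse -> managed grassland (tied to
    herd growth). Flows are limited by the donor pool so areas stay
    non-negative, which preserves the conservation invariant exactly.
    """
    areas = {b: np.empty(len(years)) for b in BIOMES}
    state = dict(_INITIAL_AREAS)
    heads = activity["livestock_heads"].to_numpy()
    e_pasture = luc[luc["component"] == "luc_pasture"].set_index("year")["value"].reindex(years).to_numpy()
    e_crop = luc[luc["component"] == "luc_crop"].set_index("year")["value"].reindex(years).to_numpy()
    for i, _year in enumerate(years):
        for b in BIOMES:
            areas[b][i] = state[b]
        d_heads = heads[i + 1] - heads[i] if i + 1 < len(years) else 0.0
        flows = (
            ("forest", "grassland_managed", e_pasture[i] * KM2_PER_PGC_DEFOREST),
            ("grassland_managed", "cropland", e_crop[i] * KM2_PER_PGC_CROP),
            ("grassland_sparse", "grassland_managed", max(d_heads, 0.0) * KM2_PER_HEAD),
        )
        for src, dst, flow in flows:
            flow = min(max(flow, 0.0), state[src])
            state[src] -= flow
            state[dst] += flow
    frames = [
        pd.DataFrame({"region": region, "year": years, "biome": b, "area_km2": areas[b]})
        for b in BIOMES
    ]
    return pd.concat(frames, ignore_index=True)


def generate_scenario(config: ScenarioConfig | None = None,
                      ef: EmissionFactorSet | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (FluxTable, ActivityTable, LandCoverTable) for a scenario.

    Deterministic for a fixed config (the seed lives in the config).
    CH4/N2O components are computed from the activity table through the
    Tier calculators with ``ef`` (defaults to the shipped factor set).
    """
    config = config or ScenarioConfig()
    ef = ef or EmissionFactorSet()
    years = config.years
    activity_frames, flux_records, landcover_frames = [], [], []
    for region in config.regions:
        p = config.params_for(region)
        p.validate(region)
        act = _region_activity(region, p, years)
        activity_frames.append(act)
        co2_records = _region_co2_fluxes(region, p, years, config.seed)
        flux_records += co2_records
        luc = pd.DataFrame.from_records(
            [r for r in co2_records if r["component"].startswith("luc")])
        landcover_frames.append(_region_landcover(region, p, years, act, luc))
    activity = pd.concat(activity_frames, ignore_index=True)
    landcover = pd.concat(landcover_frames, ignore_index=True)
    fluxes = make_flux_table(flux_records)
    gas_components = emissions_to_flux_components(emissions_table(activity, ef))
    fluxes = pd.concat([fluxes, gas_components], ignore_index=True)
    fluxes = fluxes.sort_values(["region", "component", "management", "year"]).reset_index(drop=True)
    return fluxes, activity, landcover


def default_albedo_coefficients(regions=DEFAULT_REGIONS) -> dict[tuple[str, str], float]:
    """Synthetic per-(region, biome) albedo-forcing coefficients.

    mW m-2 of global forcing per km2 of area deviation from 1750.
    Signs follow the brightness ordering forest < grassland < cropland:
    forest loss brightens the surface (cooling when forest area falls),
    cropland expansion over grassland brightens it slightly.
    """
    per_biome = {
        "forest": 6.0e-6,
        "grassland_managed": -1.0e-6,
        "grassland_sparse": -1.0e-6,
        "cropland": -3.0e-6,
        "other": 0.0,
    }
    return {(r, b): c for r in regions for b, c in per_biome.items()}
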