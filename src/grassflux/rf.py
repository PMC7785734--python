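"""Compact impulse-response climate model: emissions -> burden -> forcing.

The model replaces a full reduced-complexity Earth-system model with
the minimal machinery the grassland analysis needs:

* a four-pool impulse-response function (IRF) for CO2 (one permanent
  pool plus three decaying pools, AR5/Joos-style),
* single-exponential perturbation decay for CH4 and N2O,
* linearized radiative efficiencies per gas (a logarithmic CO2 option
  exists for large perturbations),
* indirect-forcing multipliers: tropospheric O3 and stratospheric H2O
  riding on direct CH4 forcing, stratospheric O3 (net negative, it
  also shortens the CH4 response) riding on direct N2O forcing,
* an optional climate-carbon feedback: forcing drives a two-box
  temperature response which releases additional CO2 at a fixed gain.

Time stepping is annual with sub-annual refinement (default 4 steps per
year). Forcing is reported at the *start* of each calendar year, so the
value for the first year of a run is exactly zero and forcing at year t
never depends on emissions in years >= t.

The same machinery computes emission metrics: ``gwp`` integrates the
forcing of unit pulses, and with the default parameters (feedback gain
and the N2O stratospheric-O3 multiplier calibrated once, see
``scripts/calibrate_gwp.py``) reproduces GWP100 = 34 for CH4 and 267
for N2O with climate-carbon feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grassflux.balance import MW_CH4_FROM_C, MW_CO2_FROM_C, MW_N2O_FROM_N
from grassflux.tables import validate_flux_table, validate_landcover_table

__all__ = [
    "IRFParams",
    "AlbedoBookkeeping",
    "burden_from_emissions",
    "rf_from_burden",
    "gwp",
    "albedo_rf",
    "run_rf",
]

GASES = ("co2", "ch4", "n2o")

# atmospheric conversion: 1 ppm CO2 = 2.123 Pg C -> 7.7843e9 kg CO2 per ppb;
# equal mole count per ppb scales other gases by molar mass (44 g/mol CO2)
_KG_CO2_PER_PPB = 2.123e12 * (44.0 / 12.0) * 1e-3
_DEFAULT_KG_PER_PPB = {
    "co2": _KG_CO2_PER_PPB,
    "ch4": _KG_CO2_PER_PPB * 16.0 / 44.0,
    "n2o": _KG_CO2_PER_PPB,  # N2O and CO2 share molar mass 44
}


@dataclass(frozen=True)
class IRFParams:
    """Impulse-response and radiative parameters of the compact model.

    Defaults follow the updated-AR5 parameter family: Joos-style CO2
    pool fractions/timescales, perturbation lifetimes of 12.4 yr (CH4)
    and 121 yr (N2O), AR5 radiative efficiencies, +50% tropospheric-O3
    and +15% stratospheric-H2O multipliers on direct CH4 forcing, and a
    two-box temperature kernel (Boucher-Reddy coefficients). The
    climate-carbon feedback gain ``gamma_feedback`` (Pg C yr-1 K-1) and
    the net N2O stratospheric-O3 multiplier ``f_stratO3`` are fixed by
    the one-off metric calibration in ``scripts/calibrate_gwp.py`` so
    that GWP100(CH4) = 34 and GWP100(N2O) = 267 with feedback enabled.
    """

    co2_pool_fractions: tuple[float, ...] = (0.2173, 0.2240, 0.2824, 0.2763)
    co2_pool_timescales: tuple[float, ...] = (394.4, 36.54, 4.304)  # a0 pool is permanent
    ch4_lifetime: float = 12.4  # yr, perturbation lifetime
    n2o_lifetime: float = 121.0  # yr
    radiative_efficiency: dict[str, float] = field(
        default_factory=lambda: {"co2": 1.37e-5, "ch4": 3.63e-4, "n2o": 3.00e-3}
    )  # W m-2 ppb-1
    f_tropO3: float = 0.50  # tropospheric O3 RF per unit direct CH4 RF
    f_stratH2O: float = 0.15  # stratospheric H2O RF per unit direct CH4 RF
    f_lifetime: float = 1.0  # multiplier on the CH4 perturbation lifetime
    f_stratO3: float = -0.069282  # stratospheric O3 RF per unit direct N2O RF (calibrated)
    gamma_feedback: float = 4.138576  # Pg C yr-1 K-1 feedback CO2 release (calibrated)
    temp_response_coeffs: tuple[float, ...] = (0.631, 0.429)  # K per (W m-2)
    temp_response_timescales: tuple[float, ...] = (8.4, 409.5)  # yr
    kg_per_ppb: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_KG_PER_PPB))
    steps_per_year: int = 4
    co2_rf_mode: str = "linear"  # "linear" or "log"
    co2_reference_ppm: float = 278.0
    co2_log_alpha: float = 5.35  # W m-2 for the log formulation

    def __post_init__(self):
        if abs(sum(self.co2_pool_fractions) - 1.0) > 1e-12:
            raise ValueError("CO2 pool fractions must sum to 1")
        if len(self.co2_pool_fractions) != len(self.co2_pool_timescales) + 1:
            raise ValueError("need one more pool fraction (permanent pool) than timescales")
        if min(self.co2_pool_timescales) <= 0 or self.ch4_lifetime <= 0 or self.n2o_lifetime <= 0:
            raise ValueError("lifetimes must be > 0")
        if any(v <= 0 for v in self.radiative_efficiency.values()):
            raise ValueError("radiative efficiencies must be > 0")
        if self.steps_per_year < 1:
            raise ValueError("steps_per_year must be >= 1")
        if self.co2_rf_mode not in ("linear", "log"):
            raise ValueError(f"unknown co2_rf_mode {self.co2_rf_mode!r}")

    def irf(self, gas: str, t: np.ndarray) -> np.ndarray:
        """Fraction of a unit pulse of ``gas`` remaining after ``t`` years."""
        t = np.asarray(t, dtype=float)
        if gas == "co2":
            a0 = self.co2_pool_fractions[0]
            out = np.full_like(t, a0)
            for a, tau in zip(self.co2_pool_fractions[1:], self.co2_pool_timescales):
                out = out + a * np.exp(-t / tau)
            return out
        if gas == "ch4":
            return np.exp(-t / (self.ch4_lifetime * self.f_lifetime))
        if gas == "n2o":
            return np.exp(-t / self.n2o_lifetime)
        raise ValueError(f"unknown gas {gas!r}")


def _fine_emissions(emissions: pd.Series, steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Annual kg yr-1 series -> (years, fine-grid rate array)."""
    years = np.asarray(emissions.index, dtype=int)
    if len(years) == 0:
        raise ValueError("empty emission series")
    if np.any(np.diff(years) != 1):
        raise ValueError("emission years must be contiguous")
    rate = np.repeat(emissions.to_numpy(dtype=float), steps)
    return years, rate


def _convolve_irf(rate: np.ndarray, gas: str, params: IRFParams) -> np.ndarray:
    """Mass (kg) remaining airborne at the end of each fine step."""
    s = params.steps_per_year
    dt = 1.0 / s
    n = len(rate)
    # kernel at midpoints keeps a pulse's own-step survival ~ IRF(0)
    kernel = params.irf(gas, (np.arange(n) + 0.5) * dt)
    return np.convolve(rate, kernel)[:n] * dt


def burden_from_emissions(emissions: pd.Series, gas: str, params: IRFParams | None = None) -> pd.Series:
    """Atmospheric burden perturbation (ppb) from an emission series.

    ``emissions`` is an annual series in kg yr-1 indexed by contiguous
    calendar years; the burden is reported at the start of each year
    (so the first year is zero) plus one extra year after the series
    end, carrying the final-state burden.
    """
    params = params or IRFParams()
    if gas not in GASES:
        raise ValueError(f"unknown gas {gas!r}")
    years, rate = _fine_emissions(emissions, params.steps_per_year)
    mass = _convolve_irf(rate, gas, params)
    s = params.steps_per_year
    start_of_year = np.concatenate([[0.0], mass[s - 1 :: s]])  # y0, y0+1, ..., y_end+1
    ppb = start_of_year / params.kg_per_ppb[gas]
    return pd.Series(ppb, index=np.arange(years[0], years[-1] + 2))


def rf_from_burden(burden: pd.Series, gas: str, params: IRFParams | None = None) -> pd.DataFrame:
    """Direct and indirect forcing components (W m-2) of a burden series.

    Direct forcing is radiative efficiency x burden (or the logarithmic
    CO2 formulation when selected); indirect components are fixed
    multiples of the direct term. Burdens that would drive the total
    concentration negative (below -C0 for CO2 in log mode) raise
    ``ValueError``.
    """
    params = params or IRFParams()
    if gas not in GASES:
        raise ValueError(f"unknown gas {gas!r}")
    b = burden.to_numpy(dtype=float)
    if gas == "co2" and params.co2_rf_mode == "log":
        c0 = params.co2_reference_ppm * 1e3  # ppb
        if np.any(b <= -c0):
            raise ValueError("CO2 burden drives concentration negative")
        direct = params.co2_log_alpha * np.log1p(b / c0)
    else:
        direct = params.radiative_efficiency[gas] * b
    out = {f"rf_{gas}_direct" if gas != "co2" else "rf_co2": direct}
    if gas == "ch4":
        out["rf_ch4_tropO3"] = params.f_tropO3 * direct
        out["rf_ch4_stratH2O"] = params.f_stratH2O * direct
    elif gas == "n2o":
        out["rf_n2o_stratO3"] = params.f_stratO3 * direct
    return pd.DataFrame(out, index=burden.index)


def _temperature_from_rf(rf_total_fine: np.ndarray, params: IRFParams) -> np.ndarray:
    """Two-box temperature response (K) on the fine grid."""
    s = params.steps_per_year
    dt = 1.0 / s
    n = len(rf_total_fine)
    t = (np.arange(n) + 0.5) * dt
    kernel = np.zeros(n)
    for c, d in zip(params.temp_response_coeffs, params.temp_response_timescales):
        kernel += (c / d) * np.exp(-t / d)
    return np.convolve(rf_total_fine, kernel)[:n] * dt


def _gas_rf_fine(rate: np.ndarray, gas: str, params: IRFParams) -> np.ndarray:
    """Total (direct+indirect) forcing of one gas on the fine grid (W m-2)."""
    mass = _convolve_irf(rate, gas, params)
    ppb = mass / params.kg_per_ppb[gas]
    direct = params.radiative_efficiency[gas] * ppb
    if gas == "ch4":
        return direct * (1.0 + params.f_tropO3 + params.f_stratH2O)
    if gas == "n2o":
        return direct * (1.0 + params.f_stratO3)
    return direct


def _feedback_co2_rf_fine(rf_fine: np.ndarray, params: IRFParams) -> np.ndarray:
    """Forcing from feedback CO2 released by the warming of ``rf_fine``."""
    temp = _temperature_from_rf(rf_fine, params)
    fb_rate_kg = params.gamma_feedback * temp * 1e12 * MW_CO2_FROM_C  # Pg C yr-1 -> kg CO2 yr-1
    return _gas_rf_fine(fb_rate_kg, "co2", params)


def _agwp(gas: str, horizon: float, params: IRFParams, with_feedback: bool) -> float:
    """Time-integrated forcing (W m-2 yr per kg) of a 1 kg pulse."""
    s = params.steps_per_year
    dt = 1.0 / s
    n = int(round(horizon * s))
    rate = np.zeros(n)
    rate[0] = 1.0 / dt  # 1 kg emitted in the first sub-step
    rf = _gas_rf_fine(rate, gas, params)
    if with_feedback:
        rf = rf + _feedback_co2_rf_fine(rf, params)
    return float(np.sum(rf) * dt)


def gwp(gas: str, horizon: float = 100.0, params: IRFParams | None = None,
        with_feedback: bool = True) -> float:
    """Global warming potential of ``gas`` over ``horizon`` years.

    Ratio of the time-integrated forcing (all components, feedback CO2
    included when flagged — consistently for the gas *and* the CO2
    reference pulse) of a 1 kg pulse of ``gas`` to that of 1 kg CO2.
    ``gwp("co2", ...)`` is exactly 1.
    """
    params = params or IRFParams()
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if gas not in GASES:
        raise ValueError(f"unknown gas {gas!r}")
    if gas == "co2":
        return 1.0
    return _agwp(gas, horizon, params, with_feedback) / _agwp("co2", horizon, params, with_feedback)


@dataclass(frozen=True)
class AlbedoBookkeeping:
    """Coefficients for the land-cover-change albedo forcing diagnostic.

    ``coefficients`` maps (region, biome) to mW m-2 per km2 of biome
    area deviation from the baseline (1750) state; ``biome_class`` maps
    each biome to the managed or sparse aggregate. The final forcing is
    divided by 2 exactly once, so that a transition between two biomes
    — which changes both areas — is not double-counted.
    """

    coefficients: dict[tuple[str, str], float]
    biome_class: dict[str, str] = field(default_factory=lambda: {
        "grassland_managed": "managed",
        "cropland": "managed",
        "forest": "managed",
        "grassland_sparse": "sparse",
        "other": "sparse",
    })
    half_factor: float = 0.5


def albedo_rf(landcover: pd.DataFrame, book: AlbedoBookkeeping,
              baseline_year: int | None = None) -> pd.DataFrame:
    """Albedo forcing (mW m-2) from land-cover deviations, split by class.

    Returns a frame indexed by year with columns ``managed``, ``sparse``
    and ``total``. Zero whenever the land-cover state equals the
    baseline state. A biome whose area deviates from baseline in a
    region with no coefficient raises ``ValueError``.
    """
    validate_landcover_table(landcover)
    baseline_year = baseline_year if baseline_year is not None else int(landcover["year"].min())
    wide = landcover.pivot_table(index=["region", "biome"], columns="year", values="area_km2")
    base = wide[baseline_year]
    dev = wide.sub(base, axis=0)
    years = dev.columns
    out = pd.DataFrame(0.0, index=years, columns=["managed", "sparse"])
    for (region, biome), row in dev.iterrows():
        if (region, biome) not in book.coefficients:
            if np.any(np.abs(row.to_numpy()) > 0):
                raise ValueError(f"no albedo coefficient for observed transition ({region!r}, {biome!r})")
            continue
        coef = book.coefficients[(region, biome)]
        cls = book.biome_class[biome]
        out[cls] += book.half_factor * coef * row
    out["total"] = out["managed"] + out["sparse"]
    out.index.name = "year"
    return out


#: FluxTable component -> (gas, element-mass -> molecule-mass factor, kg per native unit)
_COMPONENT_GAS = {
    "co2_soil": ("co2", MW_CO2_FROM_C, 1e12),  # Pg C -> kg CO2
    "luc_pasture": ("co2", MW_CO2_FROM_C, 1e12),
    "luc_crop": ("co2", MW_CO2_FROM_C, 1e12),
    "ch4": ("ch4", MW_CH4_FROM_C, 1e9),  # Tg C -> kg CH4
    "n2o": ("n2o", MW_N2O_FROM_N, 1e9),  # Tg N -> kg N2O
}


def global_gas_emissions(fluxes: pd.DataFrame, gas: str) -> pd.Series:
    """Global kg yr-1 emission series of one gas from a FluxTable."""
    years = np.arange(int(fluxes["year"].min()), int(fluxes["year"].max()) + 1)
    total = pd.Series(0.0, index=years)
    for comp, (g, mw, scale) in _COMPONENT_GAS.items():
        if g != gas:
            continue
        sel = fluxes[fluxes["component"] == comp]
        if not len(sel):
            continue
        series = sel.groupby("year")["value"].sum() * mw * scale
        total = total.add(series, fill_value=0.0)
    return total


def run_rf(fluxes: pd.DataFrame, params: IRFParams | None = None,
           landcover: pd.DataFrame | None = None,
           albedo_book: AlbedoBookkeeping | None = None,
           with_feedback: bool = False) -> pd.DataFrame:
    """Full forcing trajectory of an anthropogenic FluxTable.

    Returns a frame indexed by year with the component decomposition
    (mW m-2): ``rf_co2``, ``rf_ch4_direct``, ``rf_ch4_tropO3``,
    ``rf_ch4_stratH2O``, ``rf_n2o_direct``, ``rf_n2o_stratO3``,
    ``rf_albedo`` and their exact sum ``rf_total``. Climate-carbon
    feedback is off by default for forcing runs (it is a metric-side
    convention); when enabled its CO2 forcing is folded into
    ``rf_co2``.
    """
    params = params or IRFParams()
    validate_flux_table(fluxes)
    years = np.arange(int(fluxes["year"].min()), int(fluxes["year"].max()) + 1)
    columns = [
        "rf_co2", "rf_ch4_direct", "rf_ch4_tropO3", "rf_ch4_stratH2O",
        "rf_n2o_direct", "rf_n2o_stratO3", "rf_albedo",
    ]
    out = pd.DataFrame(0.0, index=years, columns=columns)
    out.index.name = "year"
    for gas in GASES:
        emissions = global_gas_emissions(fluxes, gas)
        burden = burden_from_emissions(emissions, gas, params)
        comps = rf_from_burden(burden, gas, params).reindex(years) * 1e3  # W -> mW
        for col in comps.columns:
            out[col] += comps[col]
    if with_feedback:
        rf_fine = np.zeros(len(years) * params.steps_per_year)
        for gas in GASES:
            rate = np.repeat(global_gas_emissions(fluxes, gas).reindex(years, fill_value=0.0)
                             .to_numpy(), params.steps_per_year)
            rf_fine += _gas_rf_fine(rate, gas, params)
        fb = _feedback_co2_rf_fine(rf_fine, params)
        s = params.steps_per_year
        fb_start_of_year = np.concatenate([[0.0], fb[s - 1 :: s]])[: len(years)]
        out["rf_co2"] += fb_start_of_year * 1e3
    if landcover is not None:
        if albedo_book is None:
            raise ValueError("landcover given without albedo coefficients")
        alb = albedo_rf(landcover, albedo_book).reindex(years).fillna(0.0)
        out["rf_albedo"] = alb["total"]
    out["rf_total"] = out[columns].sum(axis=1)
    return out
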