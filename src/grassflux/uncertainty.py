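"""Constrained Monte Carlo propagation of flux and forcing uncertainty.

Sampling design
---------------

* The grassland CO2 budget carries a single multiplicative error per
  sample (relative sd 46%), shared across regions and years: the
  dominant uncertainty is systematic model error, not interannual
  noise. Land-use-change emissions get their own multiplier (31%).
* CH4 and N2O are re-derived from sampled emission factors. Factors
  with symmetric uncertainty are drawn normal (central value = mean,
  clipped at zero); factors with asymmetric ranges are drawn lognormal
  with the central value as the *median* (unbiased in log space).
  Because every Tier source is exactly linear in its factor product,
  resampling multiplies each source's central emissions by the sampled
  factor-product ratio — an exact re-computation, stored compactly.
* Forcing-model parameters (radiative efficiencies, perturbation
  lifetimes) are drawn once per flux sample, paired one-to-one rather
  than crossed.

The raw ensemble is then *weighted* using inventory-style constraints:
weight_i proportional to exp(-0.5 * sum_g ((E_i,g - E_ref,g)/sigma_g)^2)
over the constrained gas emissions, normalized to sum to one. All
summaries are weighted means and population-convention weighted
standard deviations, with the effective sample size reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from grassflux.balance import GasConstants, MW_CH4_FROM_C, MW_CO2_FROM_C, MW_N2O_FROM_N
from grassflux.rf import IRFParams, burden_from_emissions, rf_from_burden
from grassflux.tables import global_series, validate_flux_table
from grassflux.tier import EmissionFactorSet, emissions_table

__all__ = [
    "UncertaintySpec",
    "EmissionConstraint",
    "FluxEnsemble",
    "sample_fluxes",
    "weight_ensemble",
    "summarize",
    "rf_ensemble",
]

#: factor names whose product scales each Tier source
SOURCE_FACTORS: dict[tuple[str, str], tuple[str, ...]] = {
    ("CH4", "enteric"): ("Ym", "GE_density"),
    ("CH4", "manure_mgmt"): ("VS_per_DM", "B0", "MCF"),
    ("CH4", "wild"): ("wild_ch4_per_head",),
    ("N2O", "soil_excreta"): ("EF3_PRP",),
    ("N2O", "soil_fertilizer"): ("EF1",),
    ("N2O", "soil_manure"): ("EF1",),
    ("N2O", "soil_deposition"): ("EF_dep",),
    ("N2O", "manure_mgmt"): ("EF_mm_N2O",),
    ("N2O", "wild"): ("wild_Nex_per_head", "EF3_PRP"),
}


@dataclass(frozen=True)
class EmissionConstraint:
    """Inventory constraint on one gas's global emissions at one year."""

    gas: str  # "ch4" (Tg C yr-1) or "n2o" (Tg N yr-1)
    year: int
    reference: float
    sd: float

    def __post_init__(self):
        if not np.isfinite(self.reference):
            raise ValueError("constraint reference must be finite")
        if self.sd <= 0:
            raise ValueError("constraint sd must be > 0")


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte Carlo configuration."""

    n_samples: int = 10_000
    co2_rel_sd: float = 0.46
    luc_rel_sd: float = 0.31
    rf_param_rel_sd: dict[str, float] = field(default_factory=lambda: {
        "re_co2": 0.10, "re_ch4": 0.10, "re_n2o": 0.10,
        "ch4_lifetime": 0.15, "n2o_lifetime": 0.10,
    })
    constraints: tuple[EmissionConstraint, ...] = ()

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.co2_rel_sd < 0 or self.luc_rel_sd < 0:
            raise ValueError("relative sds must be >= 0")


def _sample_factor(central: float, family: str, dispersion: float,
                   rng: np.random.Generator, n: int) -> np.ndarray:
    if dispersion == 0.0 or central == 0.0:
        return np.full(n, central)
    z = rng.standard_normal(n)
    if family == "lognormal":
        return central * np.exp(dispersion * z)  # central value is the median
    return np.clip(central * (1.0 + dispersion * z), 0.0, None)


@dataclass
class FluxEnsemble:
    """Compact Monte Carlo ensemble of FluxTables.

    Per-sample state is three sets of multipliers (CO2 budget, LUC,
    per-source emission-factor ratios) applied to the central tables;
    :meth:`sample_flux_table` materializes any single member in full.
    """

    central: pd.DataFrame
    spec: UncertaintySpec
    co2_mult: np.ndarray
    luc_mult: np.ndarray
    source_ratio: dict[tuple[str, str], np.ndarray]
    central_source_global: dict[tuple[str, str], pd.Series]
    rf_param_mult: dict[str, np.ndarray]
    weights: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.co2_mult)

    def _central_component(self, component: str) -> pd.Series:
        return global_series(self.central, component)

    def co2_budget(self, year: int) -> np.ndarray:
        """Sampled global soil CO2 flux (Pg C yr-1) at ``year``."""
        return self.co2_mult * self._central_component("co2_soil").loc[year]

    def luc_budget(self, year: int) -> np.ndarray:
        central = (self._central_component("luc_pasture")
                   + self._central_component("luc_crop")).loc[year]
        return self.luc_mult * central

    def gas_emission(self, gas: str, year: int) -> np.ndarray:
        """Sampled global emissions of ``gas`` ('ch4' Tg C, 'n2o' Tg N)."""
        gas_label = gas.upper().replace("CH4", "CH4").replace("N2O", "N2O")
        total = np.zeros(self.n)
        for (g, source), series in self.central_source_global.items():
            if g != gas_label or year not in series.index:
                continue
            total += self.source_ratio[(g, source)] * series.loc[year]
        return total

    def ghg_total(self, year: int, constants: GasConstants | None = None) -> np.ndarray:
        """Sampled global GHG balance (Gt CO2e yr-1) at ``year``."""
        constants = constants or GasConstants()
        co2e = (self.co2_budget(year) + self.luc_budget(year)) * MW_CO2_FROM_C
        co2e += self.gas_emission("ch4", year) * MW_CH4_FROM_C * constants.gwp_ch4 * 1e-3
        co2e += self.gas_emission("n2o", year) * MW_N2O_FROM_N * constants.gwp_n2o * 1e-3
        return co2e

    def sample_flux_table(self, i: int) -> pd.DataFrame:
        """Materialize ensemble member ``i`` as a full FluxTable."""
        out = self.central.copy()
        comp = out["component"]
        out.loc[comp == "co2_soil", "value"] *= self.co2_mult[i]
        out.loc[comp.str.startswith("luc"), "value"] *= self.luc_mult[i]
        # gas components: weighted by the source mix of that region-year
        for gas, label in (("CH4", "ch4"), ("N2O", "n2o")):
            mask = comp == label
            sub = out.loc[mask]
            scaled = np.zeros(len(sub))
            base = np.zeros(len(sub))
            for (g, source), frame in self._source_frames.items():
                if g != gas:
                    continue
                vals = frame.reindex(
                    pd.MultiIndex.from_frame(sub[["region", "year", "management"]])
                )["value"].fillna(0.0).to_numpy()
                base += vals
                scaled += vals * self.source_ratio[(g, source)][i]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(base != 0, scaled / np.where(base == 0, 1.0, base), 1.0)
            out.loc[mask, "value"] = sub["value"].to_numpy() * ratio
        return out


def sample_fluxes(central: pd.DataFrame, activity: pd.DataFrame,
                  ef: EmissionFactorSet, spec: UncertaintySpec,
                  seed: int) -> FluxEnsemble:
    """Draw a FluxEnsemble around a central FluxTable.

    Reproducible for a fixed seed. ``activity`` and ``ef`` must be the
    inputs the central CH4/N2O fluxes were computed from, so that the
    factor-ratio resampling is an exact re-computation.
    """
    validate_flux_table(central)
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    co2_mult = 1.0 + spec.co2_rel_sd * rng.standard_normal(n)
    luc_mult = 1.0 + spec.luc_rel_sd * rng.standard_normal(n)

    factor_samples = {
        name: _sample_factor(getattr(ef, name), unc.family, unc.dispersion, rng, n)
        for name, unc in ef.uncertainty.items()
    }
    source_ratio = {}
    for key, factors in SOURCE_FACTORS.items():
        ratio = np.ones(n)
        for f in factors:
            central_value = getattr(ef, f)
            if central_value != 0:
                ratio = ratio * factor_samples[f] / central_value
        source_ratio[key] = ratio

    records = emissions_table(activity, ef)
    central_source_global = {
        key: grp.groupby("year")["value"].sum()
        for key, grp in records.groupby(["gas", "source"])
    }
    source_frames = {
        key: grp.groupby(["region", "year", "management"], as_index=True)[["value"]].sum()
        for key, grp in records.groupby(["gas", "source"])
    }

    rf_param_mult = {
        name: np.clip(1.0 + rel_sd * rng.standard_normal(n), 0.05, None)
        for name, rel_sd in spec.rf_param_rel_sd.items()
    }
    ens = FluxEnsemble(
        central=central, spec=spec, co2_mult=co2_mult, luc_mult=luc_mult,
        source_ratio=source_ratio, central_source_global=central_source_global,
        rf_param_mult=rf_param_mult,
    )
    ens._source_frames = source_frames
    return ens


def weight_ensemble(ensemble: FluxEnsemble,
                    constraints: tuple[EmissionConstraint, ...] | None = None) -> np.ndarray:
    """Gaussian inventory-constraint weights, normalized to sum to one.

    With no constraints the weights are uniform. Raises ``ValueError``
    if every weight underflows to zero (constraints too tight).
    """
    constraints = constraints if constraints is not None else ensemble.spec.constraints
    log_w = np.zeros(ensemble.n)
    for c in constraints:
        emission = ensemble.gas_emission(c.gas, c.year)
        log_w -= 0.5 * ((emission - c.reference) / c.sd) ** 2
    log_w -= log_w.max()  # guard the exp against underflow of the whole batch
    w = np.exp(log_w)
    total = w.sum()
    if total == 0.0 or not np.isfinite(total):
        raise ValueError("all constraint weights underflow; widen the constraint sds")
    w /= total
    ensemble.weights = w
    return w


def summarize(values: np.ndarray, weights: np.ndarray | None = None) -> dict[str, float]:
    """Weighted mean and population-convention weighted sd of a scalar.

    Returns mean, sd and the effective sample size 1 / sum(w^2).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty ensemble")
    if weights is None:
        weights = np.full(values.size, 1.0 / values.size)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess <= 0:
        raise ValueError("zero effective sample size")
    mean = float(np.sum(w * values))
    sd = float(np.sqrt(np.sum(w * (values - mean) ** 2)))
    return {"mean": mean, "sd": sd, "ess": float(ess)}


_GAS_KG = {"co2": 1e12 * MW_CO2_FROM_C, "ch4": 1e9 * MW_CH4_FROM_C, "n2o": 1e9 * MW_N2O_FROM_N}


def rf_ensemble(ensemble: FluxEnsemble, params: IRFParams | None = None,
                year: int = 2012) -> np.ndarray:
    """Per-sample total forcing (mW m-2) at ``year``.

    Emission trajectories are rebuilt from each sample's multipliers;
    the forcing-model parameters (radiative efficiencies, lifetimes)
    are the sample's paired draws.
    """
    params = params or IRFParams()
    years = np.sort(ensemble.central["year"].unique())
    co2_central = (global_series(ensemble.central, "co2_soil")
                   .reindex(years, fill_value=0.0))
    luc_central = (global_series(ensemble.central, "luc_pasture")
                   .add(global_series(ensemble.central, "luc_crop"), fill_value=0.0)
                   .reindex(years, fill_value=0.0))
    gas_series = {"CH4": None, "N2O": None}
    for gas in gas_series:
        parts = [s.reindex(years, fill_value=0.0)
                 for (g, _), s in ensemble.central_source_global.items() if g == gas]
        gas_series[gas] = parts

    out = np.empty(ensemble.n)
    for i in range(ensemble.n):
        p = replace(
            params,
            radiative_efficiency={
                "co2": params.radiative_efficiency["co2"] * ensemble.rf_param_mult["re_co2"][i],
                "ch4": params.radiative_efficiency["ch4"] * ensemble.rf_param_mult["re_ch4"][i],
                "n2o": params.radiative_efficiency["n2o"] * ensemble.rf_param_mult["re_n2o"][i],
            },
            ch4_lifetime=params.ch4_lifetime * ensemble.rf_param_mult["ch4_lifetime"][i],
            n2o_lifetime=params.n2o_lifetime * ensemble.rf_param_mult["n2o_lifetime"][i],
        )
        total = 0.0
        co2_kg = (ensemble.co2_mult[i] * co2_central
                  + ensemble.luc_mult[i] * luc_central) * _GAS_KG["co2"]
        sources = {"co2": co2_kg}
        for gas, label in (("CH4", "ch4"), ("N2O", "n2o")):
            series = sum(
                ensemble.source_ratio[(gas, key[1])][i] * s
                for key, s in zip(
                    [k for k in ensemble.central_source_global if k[0] == gas],
                    gas_series[gas],
                )
            )
            sources[label] = series * _GAS_KG[label]
        for gas_label, kg_series in sources.items():
            burden = burden_from_emissions(pd.Series(kg_series.to_numpy(), index=years), gas_label, p)
            comps = rf_from_burden(burden, gas_label, p)
            total += float(comps.loc[year].sum()) * 1e3
        out[i] = total
    return out
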