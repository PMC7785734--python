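"""IPCC (2006) Tier 1 / Tier 2 CH4 and N2O emission calculators.

Covers enteric fermentation from grazed and harvested forage, CH4 and
N2O from manure management, direct N2O from managed soils (excreta on
pasture, synthetic fertilizer, applied manure, atmospheric nitrogen
deposition) and the emissions of wild grazers on sparsely grazed
grassland. Potential CH4/N2O uptake by grassland soils is excluded.

Every operation is homogeneous of degree 1 in its activity argument:
emission factors multiply activity amounts, nothing else. Emissions are
reported internally as CH4-C (Tg C yr-1) and N2O-N (Tg N yr-1); the
molecular-weight conversions to full-molecule mass live in
:mod:`grassflux.balance` so the CO2-equivalent bookkeeping stays in one
place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EmissionFactorSet",
    "FactorUncertainty",
    "enteric_ch4",
    "manure_ch4",
    "soil_n2o",
    "wild_grazer_emissions",
    "emissions_table",
    "KG_CH4_TO_TG_C",
    "KG_N_TO_TG_N",
]

#: kg CH4 -> Tg CH4-C  (12/16 carbon mass fraction, 1e-9 kg->Tg)
KG_CH4_TO_TG_C = (12.0 / 16.0) * 1e-9
#: kg N2O-N -> Tg N
KG_N_TO_TG_N = 1e-9

#: m3 CH4 -> kg CH4 at standard conditions
CH4_DENSITY_KG_M3 = 0.67

#: source labels emitted by :func:`emissions_table`
CH4_SOURCES = ("enteric", "manure_mgmt", "wild")
N2O_SOURCES = ("soil_excreta", "soil_fertilizer", "soil_manure", "soil_deposition", "manure_mgmt", "wild")


@dataclass(frozen=True)
class FactorUncertainty:
    """Distribution descriptor for one emission factor.

    family
        ``normal`` (dispersion = relative 1-sigma sd of the central
        value) or ``lognormal`` (dispersion = sd of ln(factor); the
        central value is the median).
    """

    family: str = "normal"
    dispersion: float = 0.0

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class EmissionFactorSet:
    """Central emission factors plus their uncertainty descriptors.

    Defaults are the IPCC (2006) Tier 1 values for grazing ruminant
    systems where the guidelines fix one (Ym, GE density, EF1, EF3_PRP)
    and representative mid-range choices elsewhere; every value is a
    plain field so region- or study-specific sets can be supplied.
    """

    Ym: float = 0.065  # fraction of gross energy lost as CH4
    GE_density: float = 18.45  # MJ per kg dry matter
    ch4_energy: float = 55.65  # MJ per kg CH4
    B0: float = 0.18  # m3 CH4 per kg volatile solids
    MCF: float = 0.10  # methane conversion factor of the manure system
    VS_per_DM: float = 0.33  # kg volatile solids excreted per kg DM intake
    EF1: float = 0.01  # kg N2O-N per kg N applied (fertilizer, manure)
    EF3_PRP: float = 0.02  # kg N2O-N per kg excreta N on pasture
    EF_mm_N2O: float = 0.005  # kg N2O-N per kg managed-manure N
    EF_dep: float = 0.01  # kg N2O-N per kg deposited N
    wild_ch4_per_head: float = 38.0  # kg CH4 head-1 yr-1
    wild_Nex_per_head: float = 60.0  # kg N head-1 yr-1
    uncertainty: dict[str, FactorUncertainty] = field(default_factory=lambda: dict(_DEFAULT_UNCERTAINTY))

    def __post_init__(self):
        for name in ("Ym", "MCF"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in (
            "GE_density", "ch4_energy", "B0", "VS_per_DM", "EF1", "EF3_PRP",
            "EF_mm_N2O", "EF_dep", "wild_ch4_per_head", "wild_Nex_per_head",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_values(self, **kwargs) -> "EmissionFactorSet":
        return replace(self, **kwargs)


# IPCC (2006) Vol. 4 uncertainty guidance: symmetric ranges -> normal,
# order-of-magnitude asymmetric ranges (EF1, EF3_PRP) -> lognormal.
_DEFAULT_UNCERTAINTY: dict[str, FactorUncertainty] = {
    "Ym": FactorUncertainty("normal", 0.10),
    "GE_density": FactorUncertainty("normal", 0.05),
    "ch4_energy": FactorUncertainty("normal", 0.0),
    "B0": FactorUncertainty("normal", 0.15),
    "MCF": FactorUncertainty("lognormal", 0.30),
    "VS_per_DM": FactorUncertainty("normal", 0.15),
    "EF1": FactorUncertainty("lognormal", 0.60),
    "EF3_PRP": FactorUncertainty("lognormal", 0.60),
    "EF_mm_N2O": FactorUncertainty("lognormal", 0.60),
    "EF_dep": FactorUncertainty("lognormal", 0.60),
    "wild_ch4_per_head": FactorUncertainty("normal", 0.25),
    "wild_Nex_per_head": FactorUncertainty("normal", 0.25),
}


def _check_nonneg(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


def enteric_ch4(dm_intake, ef: EmissionFactorSet):
    """Tier 2 enteric fermentation CH4 (kg yr-1) from dry-matter intake.

    Gross-energy method: GE = intake x energy density; a fixed fraction
    Ym of gross energy is lost as CH4 and divided by the energy content
    of CH4.
    """
    dm = _check_nonneg(dm_intake, "dm_intake")
    return dm * ef.GE_density * ef.Ym / ef.ch4_energy


def manure_ch4(dm_intake, ef: EmissionFactorSet):
    """Manure-management CH4 (kg yr-1) from the intake behind the manure.

    Volatile solids VS = intake x VS_per_DM; CH4 = VS x B0 x MCF,
    converted from m3 to kg at 0.67 kg m-3.
    """
    dm = _check_nonneg(dm_intake, "dm_intake")
    vs = dm * ef.VS_per_DM
    return vs * ef.B0 * ef.MCF * CH4_DENSITY_KG_M3


def soil_n2o(activity_row, ef: EmissionFactorSet) -> dict[str, float]:
    """Direct N2O-N (kg yr-1) from managed soils and manure management.

    ``activity_row`` is any mapping with the nitrogen-input fields of an
    ActivityTable row. Returns one entry per source.
    """
    get = activity_row.get if hasattr(activity_row, "get") else activity_row.__getitem__
    n_pasture = _check_nonneg(get("excreta_N_pasture"), "excreta_N_pasture")
    n_housed = _check_nonneg(get("excreta_N_housed"), "excreta_N_housed")
    n_fert = _check_nonneg(get("fertilizer_N"), "fertilizer_N")
    n_manure = _check_nonneg(get("manure_applied_N"), "manure_applied_N")
    n_dep = _check_nonneg(get("N_deposition"), "N_deposition")
    return {
        "soil_excreta": ef.EF3_PRP * n_pasture,
        "soil_fertilizer": ef.EF1 * n_fert,
        "soil_manure": ef.EF1 * n_manure,
        "soil_deposition": ef.EF_dep * n_dep,
        "manure_mgmt": ef.EF_mm_N2O * n_housed,
    }


def wild_grazer_emissions(heads, ef: EmissionFactorSet):
    """(kg CH4 yr-1, kg N2O-N yr-1) from a wild-grazer population.

    Per-head CH4 factor plus excreta nitrogen run through the
    pasture-range-paddock factor (wild excreta is never managed).
    """
    h = _check_nonneg(heads, "heads")
    return h * ef.wild_ch4_per_head, h * ef.wild_Nex_per_head * ef.EF3_PRP


def emissions_table(activity: pd.DataFrame, ef: EmissionFactorSet) -> pd.DataFrame:
    """Per-source CH4/N2O records for every region-year of an ActivityTable.

    Returns a tidy frame with columns region, year, gas, management,
    source, value; CH4 in Tg CH4-C yr-1, N2O in Tg N2O-N yr-1. Wild
    grazers are the only sparse source; all farm-chain sources are
    managed. Totals are exactly additive over sources.

    Raises ``ValueError`` listing gaps if any activity column is missing
    or any region-year carries NaN activity.
    """
    required = [
        "region", "year", "grazed_dm", "harvested_dm", "excreta_N_pasture",
        "excreta_N_housed", "fertilizer_N", "manure_applied_N", "N_deposition",
        "wild_grazer_heads",
    ]
    missing = [c for c in required if c not in activity.columns]
    if missing:
        raise ValueError(f"activity table missing column(s): {missing}")
    if not len(activity):
        return pd.DataFrame(columns=["region", "year", "gas", "management", "source", "value"])
    gaps = activity[required].isna().any(axis=1)
    if gaps.any():
        bad = activity.loc[gaps, ["region", "year"]].to_records(index=False).tolist()
        raise ValueError(f"activity gaps at region-years: {bad[:10]}")

    rows = []

    def emit(gas, management, source, kg):
        scale = KG_CH4_TO_TG_C if gas == "CH4" else KG_N_TO_TG_N
        rows.append(
            pd.DataFrame({
                "region": activity["region"],
                "year": activity["year"],
                "gas": gas,
                "management": management,
                "source": source,
                "value": np.asarray(kg, dtype=float) * scale,
            })
        )

    total_dm = activity["grazed_dm"].to_numpy() + activity["harvested_dm"].to_numpy()
    emit("CH4", "managed", "enteric", enteric_ch4(total_dm, ef))
    # only the housed (harvested-forage) stream passes through manure storage
    emit("CH4", "managed", "manure_mgmt", manure_ch4(activity["harvested_dm"].to_numpy(), ef))

    n2o = soil_n2o(activity, ef)
    for source, kg in n2o.items():
        emit("N2O", "managed", source, kg)

    wild_ch4, wild_n2o = wild_grazer_emissions(activity["wild_grazer_heads"].to_numpy(), ef)
    emit("CH4", "sparse", "wild", wild_ch4)
    emit("N2O", "sparse", "wild", wild_n2o)

    out = pd.concat(rows, ignore_index=True)
    return out


def emissions_to_flux_components(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-source records to FluxTable ch4/n2o component rows."""
    from grassflux.tables import COMPONENT_UNITS

    agg = (
        records.groupby(["region", "year", "gas", "management"], as_index=False)["value"].sum()
    )
    agg["component"] = agg["gas"].map({"CH4": "ch4", "N2O": "n2o"})
    agg["unit"] = agg["component"].map(COMPONENT_UNITS)
    return agg[["region", "year", "component", "management", "value", "unit"]]
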