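"""Tidy-table schemas shared across the pipeline.

The interchange container everywhere is a pandas DataFrame in long
("tidy") form. Three table kinds exist:

FluxTable
    columns: region, year, component, management, value, unit
    One row per region-year-component-management. Components and their
    native units:

    ============== ===================== =========================
    component      unit                  meaning
    ============== ===================== =========================
    co2_soil       PgC/yr                net ecosystem CO2 exchange
                                         (negative = sink)
    luc_pasture    PgC/yr                deforestation-to-pasture
                                         emissions
    luc_crop       PgC/yr                grassland-to-cropland
                                         emissions
    ch4            TgC/yr                CH4 emissions as CH4-C
    n2o            TgN/yr                N2O emissions as N2O-N
    ============== ===================== =========================

    ``management`` is ``managed`` or ``sparse``; both land-use-change
    streams are carried under ``managed`` (conversion is a management
    act on the grassland side of the transition).

ActivityTable
    columns: region, year, plus one column per activity driver
    (grazed_dm, harvested_dm, excreta_N_pasture, excreta_N_housed,
    fertilizer_N, manure_applied_N, N_deposition in kg yr-1;
    livestock_heads, wild_grazer_heads in head; human_pop_index
    dimensionless).

LandCoverTable
    columns: region, year, biome, area_km2 with biomes
    grassland_managed, grassland_sparse, forest, cropland, other.
"""

from __future__ import annotations

import pandas as pd

FLUX_COMPONENTS = ("co2_soil", "luc_pasture", "luc_crop", "ch4", "n2o")

COMPONENT_UNITS = {
    "co2_soil": "PgC/yr",
    "luc_pasture": "PgC/yr",
    "luc_crop": "PgC/yr",
    "ch4": "TgC/yr",
    "n2o": "TgN/yr",
}

MANAGEMENT_CLASSES = ("managed", "sparse")

#: components that may legitimately carry either management label
SPLIT_COMPONENTS = ("co2_soil", "ch4", "n2o")

ACTIVITY_COLUMNS = (
    "grazed_dm",
    "harvested_dm",
    "excreta_N_pasture",
    "excreta_N_housed",
    "fertilizer_N",
    "manure_applied_N",
    "N_deposition",
    "livestock_heads",
    "wild_grazer_heads",
    "human_pop_index",
)

BIOMES = ("grassland_managed", "grassland_sparse", "forest", "cropland", "other")

FLUX_TABLE_COLUMNS = ("region", "year", "component", "management", "value", "unit")


class SchemaError(ValueError):
    """A table does not satisfy its declared schema."""


def make_flux_table(records: list[dict]) -> pd.DataFrame:
    """Build a FluxTable from row dicts, filling the unit column."""
    df = pd.DataFrame.from_records(records)
    if "unit" not in df.columns and len(df):
        df["unit"] = df["component"].map(COMPONENT_UNITS)
    if not len(df):
        df = pd.DataFrame(columns=list(FLUX_TABLE_COLUMNS))
    return df[list(FLUX_TABLE_COLUMNS)]


def validate_flux_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check FluxTable schema; return the frame unchanged on success.

    Raises :class:`SchemaError` naming the first offending column or
    value.
    """
    missing = [c for c in FLUX_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"FluxTable missing column(s): {missing}")
    bad_comp = set(df["component"].unique()) - set(FLUX_COMPONENTS)
    if bad_comp:
        raise SchemaError(f"unknown flux component(s): {sorted(bad_comp)}")
    bad_mgmt = set(df["management"].unique()) - set(MANAGEMENT_CLASSES)
    if bad_mgmt:
        raise SchemaError(f"unknown management label(s): {sorted(bad_mgmt)}")
    luc_sparse = df[df["component"].str.startswith("luc") & (df["management"] == "sparse")]
    if len(luc_sparse):
        raise SchemaError("land-use-change components must be labelled managed")
    for comp, unit in COMPONENT_UNITS.items():
        wrong = df[(df["component"] == comp) & (df["unit"] != unit)]
        if len(wrong):
            raise SchemaError(
                f"component {comp!r} expects unit {unit!r}, "
                f"found {sorted(wrong['unit'].unique())}"
            )
    return df


def validate_landcover_table(df: pd.DataFrame, rtol: float = 1e-9) -> pd.DataFrame:
    """Check LandCoverTable schema and per-region area conservation."""
    for c in ("region", "year", "biome", "area_km2"):
        if c not in df.columns:
            raise SchemaError(f"LandCoverTable missing column {c!r}")
    if (df["area_km2"] < 0).any():
        raise SchemaError("negative biome area")
    totals = df.groupby(["region", "year"])["area_km2"].sum().groupby("region")
    for region, tot in totals:
        if tot.max() - tot.min() > rtol * max(tot.max(), 1.0):
            raise SchemaError(f"total area not conserved over time in region {region!r}")
    return df


def flux_matrix(df: pd.DataFrame, component: str, management: str | None = None) -> pd.DataFrame:
    """Pivot one component to a region x year value matrix (years as columns)."""
    sel = df[df["component"] == component]
    if management is not None:
        sel = sel[sel["management"] == management]
    out = sel.pivot_table(
        index="region", columns="year", values="value", aggfunc="sum", fill_value=0.0
    )
    return out


def global_series(df: pd.DataFrame, component: str) -> pd.Series:
    """Sum one component over regions and management classes, by year."""
    sel = df[df["component"] == component]
    return sel.groupby("year")["value"].sum()
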