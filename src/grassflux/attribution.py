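"""Normalized-marginal attribution of forcing to region x sector.

The total anthropogenic forcing at an evaluation year is attributed to
nine regions times eight grassland sectors plus one "rest of world"
background term (73 keys in a full run). For each key, a factorial
simulation removes a small fraction (default 1%) of that key's entire
emission trajectory; the forcing differences from the control run,
normalized by their sum, define each key's share, and shares times the
control total give contributions in mW m-2. By construction the 73
contributions sum exactly to the control total.

In the default linearized-forcing mode the model is additive in
emissions, so each sector's normalized-marginal contribution equals
the forcing its emissions would produce alone — a property the test
suite uses as a brute-force oracle.

Albedo forcing bypasses this machinery (it is a diagnostic outside the
gas-cycle model) and is added to the managed/sparse aggregates as its
own component.
"""

from __future__ import annotations

import pandas as pd

from grassflux.rf import IRFParams, run_rf
from grassflux.tables import validate_flux_table

__all__ = [
    "SECTORS",
    "REST",
    "sector_of",
    "factorial_runs",
    "normalize_shares",
    "managed_sparse_rf",
    "attribute",
]

SECTORS = (
    "co2_soil_managed",
    "co2_soil_sparse",
    "ch4_managed",
    "ch4_sparse",
    "n2o_managed",
    "n2o_sparse",
    "luc_pasture",
    "luc_crop",
)

#: key of the non-grassland background term
REST = ("REST", "REST")


def sector_of(component: str, management: str) -> str:
    """Map a FluxTable (component, management) pair to its sector label."""
    if component in ("luc_pasture", "luc_crop"):
        return component
    return f"{component}_{management}"


def _sector_mask(fluxes: pd.DataFrame, region: str, sector: str) -> pd.Series:
    labels = fluxes.apply(lambda r: sector_of(r["component"], r["management"]), axis=1)
    return (fluxes["region"] == region) & (labels == sector)


def factorial_runs(fluxes: pd.DataFrame, background: pd.DataFrame | None,
                   params: IRFParams | None = None, epsilon: float = 0.01,
                   year: int = 2012) -> tuple[dict[tuple[str, str], float], float]:
    """Forcing differences of the region x sector factorial simulations.

    Returns ``(deltas, control_total)`` where ``deltas`` maps each
    (region, sector) key — plus the REST key — to
    RF(control) - RF(control with that key's emissions scaled by
    1 - epsilon) at ``year``, in mW m-2. ``background`` is the
    non-grassland emission trajectory (a FluxTable or None for a
    grassland-only world); the REST run perturbs it as one block.

    An all-zero sector is allowed and yields a zero difference.
    """
    params = params or IRFParams()
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    validate_flux_table(fluxes)
    if background is not None:
        validate_flux_table(background)
        control_table = pd.concat([fluxes, background], ignore_index=True)
    else:
        control_table = fluxes
    control = run_rf(control_table, params)
    if year not in control.index:
        raise ValueError(f"evaluation year {year} outside the run period")
    control_total = float(control.loc[year, "rf_total"])

    regions = sorted(fluxes["region"].unique())
    labels = fluxes.apply(lambda r: sector_of(r["component"], r["management"]), axis=1)
    deltas: dict[tuple[str, str], float] = {}
    n_grass = len(fluxes)
    for region in regions:
        region_mask = (fluxes["region"] == region).to_numpy()
        for sector in SECTORS:
            mask = region_mask & (labels == sector).to_numpy()
            if not mask.any() or (fluxes.loc[mask, "value"] == 0).all():
                deltas[(region, sector)] = 0.0
                continue
            perturbed = control_table.copy()
            perturbed.iloc[:n_grass, perturbed.columns.get_loc("value")] = (
                fluxes["value"].to_numpy() * (1.0 - epsilon * mask)
            )
            rf_p = run_rf(perturbed, params)
            deltas[(region, sector)] = control_total - float(rf_p.loc[year, "rf_total"])
    if background is not None and len(background):
        perturbed = pd.concat(
            [fluxes, background.assign(value=background["value"] * (1.0 - epsilon))],
            ignore_index=True,
        )
        rf_p = run_rf(perturbed, params)
        deltas[REST] = control_total - float(rf_p.loc[year, "rf_total"])
    else:
        deltas[REST] = 0.0
    return deltas, control_total


def normalize_shares(deltas: dict[tuple[str, str], float], control_total: float,
                     year: int = 2012) -> pd.DataFrame:
    """AttributionTable from factorial differences.

    share_k = delta_k / sum_j delta_j; contribution_k = share_k x
    control total, so contributions partition the control forcing
    exactly. All-zero deltas raise ``ValueError`` (nothing to
    attribute).
    """
    total_delta = sum(deltas.values())
    if total_delta == 0.0:
        raise ValueError("all factorial differences are zero; no attribution possible")
    rows = [
        {"region": region, "sector": sector, "year": year,
         "share": d / total_delta, "contribution_mWm2": (d / total_delta) * control_total}
        for (region, sector), d in deltas.items()
    ]
    return pd.DataFrame(rows)


MANAGED_SECTORS = ("co2_soil_managed", "ch4_managed", "n2o_managed", "luc_pasture", "luc_crop")
SPARSE_SECTORS = ("co2_soil_sparse", "ch4_sparse", "n2o_sparse")


def managed_sparse_rf(table: pd.DataFrame,
                      albedo_split: dict[str, float] | None = None) -> dict[str, float]:
    """Managed and sparse forcing aggregates (mW m-2) of an AttributionTable.

    Managed collects the managed gas sectors plus both land-use-change
    sectors (and the managed albedo term when given); sparse collects
    the sparse gas sectors (plus sparse albedo). The two aggregates sum
    to the grassland total (total minus the REST contribution) plus any
    albedo forcing.
    """
    grass = table[table["sector"] != "REST"]
    managed = float(grass.loc[grass["sector"].isin(MANAGED_SECTORS), "contribution_mWm2"].sum())
    sparse = float(grass.loc[grass["sector"].isin(SPARSE_SECTORS), "contribution_mWm2"].sum())
    if albedo_split is not None:
        managed += float(albedo_split.get("managed", 0.0))
        sparse += float(albedo_split.get("sparse", 0.0))
    return {"managed": managed, "sparse": sparse, "grassland_total": managed + sparse}


def attribute(fluxes: pd.DataFrame, background: pd.DataFrame | None = None,
              params: IRFParams | None = None, epsilon: float = 0.01,
              year: int = 2012) -> pd.DataFrame:
    """Factorial runs plus normalization in one call."""
    deltas, control_total = factorial_runs(fluxes, background, params, epsilon, year)
    return normalize_shares(deltas, control_total, year)
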