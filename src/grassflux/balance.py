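"""CO2-equivalent greenhouse-gas balance of grasslands.

The balance combines the net soil CO2 exchange, the two land-use-change
emission streams and the CH4 and N2O fluxes into a single Gt CO2e yr-1
quantity:

    GHG = F_CO2-C * 44/12 + E_LUC * 44/12
        + F_CH4-C * 16/12 * GWP_CH4
        + F_N2O-N * 44/28 * GWP_N2O

with fluxes in Pg C yr-1 (CO2, LUC), Tg C yr-1 (CH4-C) and
Tg N yr-1 (N2O-N). The molecular-weight ratios convert element mass to
full-molecule mass; the 100-yr global warming potentials convert CH4
and N2O mass to the CO2 mass with the same time-integrated forcing.
Positive values are sources to the atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from grassflux.tables import (
    COMPONENT_UNITS,
    FLUX_COMPONENTS,
    SchemaError,
    validate_flux_table,
)

__all__ = ["GasConstants", "co2e_balance", "decadal_means", "managed_sparse_split"]

# exact rational molecular-weight ratios (element mass -> molecule mass)
MW_CO2_FROM_C = 44.0 / 12.0
MW_CH4_FROM_C = 16.0 / 12.0
MW_N2O_FROM_N = 44.0 / 28.0


@dataclass(frozen=True)
class GasConstants:
    """Metric constants of the CO2-equivalent conversion.

    Defaults are GWP100 with climate-carbon feedback (34 for CH4, 267
    for N2O); other metric sets (e.g. feedback-free AR5 values) can be
    passed without touching the balance code. The molecular-weight
    ratios are fixed rationals and not configurable.
    """

    gwp_ch4: float = 34.0  # Gt CO2e per Gt CH4
    gwp_n2o: float = 267.0  # Gt CO2e per Gt N2O
    horizon: float = 100.0  # yr, documentation of the metric choice

    def __post_init__(self):
        if self.gwp_ch4 <= 0 or self.gwp_n2o <= 0:
            raise ValueError("GWPs must be > 0")


#: CO2e columns of a GHGBalance frame, in component order
CO2E_COLUMNS = [f"co2e_{c}" for c in FLUX_COMPONENTS]


def _component_co2e(component: str, value, constants: GasConstants):
    """Convert one native-unit flux to Gt CO2e yr-1."""
    v = np.asarray(value, dtype=float)
    if component in ("co2_soil", "luc_pasture", "luc_crop"):
        return v * MW_CO2_FROM_C  # Pg C -> Gt CO2
    if component == "ch4":
        return v * MW_CH4_FROM_C * constants.gwp_ch4 * 1e-3  # Tg C -> Gt CO2e
    if component == "n2o":
        return v * MW_N2O_FROM_N * constants.gwp_n2o * 1e-3  # Tg N -> Gt CO2e
    raise SchemaError(f"unknown component {component!r}")


def co2e_balance(fluxes: pd.DataFrame, constants: GasConstants | None = None) -> pd.DataFrame:
    """CO2-equivalent decomposition of a FluxTable.

    Returns a GHGBalance frame with one row per region-year-management,
    columns ``co2e_<component>`` (Gt CO2e yr-1, zero where a component
    is absent for that class) and ``ghg_total`` equal to their sum.
    Missing components for a region-year are treated as zero flux;
    unknown components or units raise :class:`SchemaError`.
    """
    constants = constants or GasConstants()
    validate_flux_table(fluxes)
    df = fluxes.copy()
    df["co2e"] = 0.0
    for comp in FLUX_COMPONENTS:
        m = df["component"] == comp
        df.loc[m, "co2e"] = _component_co2e(comp, df.loc[m, "value"].to_numpy(), constants)
    wide = df.pivot_table(
        index=["region", "year", "management"],
        columns="component",
        values="co2e",
        aggfunc="sum",
        fill_value=0.0,
    )
    for comp in FLUX_COMPONENTS:
        if comp not in wide.columns:
            wide[comp] = 0.0
    wide = wide[list(FLUX_COMPONENTS)]
    wide.columns = CO2E_COLUMNS
    wide["ghg_total"] = wide[CO2E_COLUMNS].sum(axis=1)
    return wide.reset_index()


def decadal_means(balance: pd.DataFrame, decades: list[int] | None = None) -> pd.DataFrame:
    """Arithmetic decadal means of a GHGBalance, globally aggregated.

    ``decades`` lists decade start years (e.g. 1750, 1760, ...); by
    default every complete calendar decade covered by the balance is
    used. A decade not fully covered by the data raises ``ValueError``
    (no silent padding); partial trailing years are simply not part of
    any default decade.
    """
    years = np.sort(balance["year"].unique())
    if decades is None:
        decades = [y0 for y0 in range(int(years.min()), int(years.max()) + 1, 10)
                   if y0 % 10 == 0 and y0 + 9 <= years.max()]
        if not decades:  # span shorter than one aligned decade
            raise ValueError("no complete calendar decade in the balance")
    value_cols = CO2E_COLUMNS + ["ghg_total"]
    annual = balance.groupby("year", as_index=True)[value_cols].sum()  # global totals
    out = []
    for y0 in decades:
        want = set(range(y0, y0 + 10))
        have = want & set(years.tolist())
        if have != want:
            raise ValueError(f"decade {y0}-{y0 + 9} not fully covered (missing {sorted(want - have)})")
        means = annual.loc[list(sorted(want))].mean(axis=0)
        out.append(pd.Series({"decade": y0, **means.to_dict()}))
    return pd.DataFrame(out)


def managed_sparse_split(balance: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a GHGBalance into its managed and sparse views.

    LUC streams travel with the managed view (they are labelled managed
    upstream). The two views partition the total exactly; an unlabelled
    row raises :class:`SchemaError`.
    """
    labels = set(balance["management"].unique())
    bad = labels - {"managed", "sparse"}
    if bad:
        raise SchemaError(f"unlabelled management class(es): {sorted(bad)}")
    managed = balance[balance["management"] == "managed"].reset_index(drop=True)
    sparse = balance[balance["management"] == "sparse"].reset_index(drop=True)
    return managed, sparse
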