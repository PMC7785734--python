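"""Pre-industrial extrapolation and anthropogenic-flux derivation.

Land-surface-model output starts in 1860; forcing calculations need
fluxes back to 1750 (end of pre-industrial times) and, more
importantly, need the *anthropogenic* part of the fluxes, because
emissions that already existed in 1750 do not perturb the atmosphere
relative to its pre-industrial state.

Extrapolation rules for 1750-1859:

* grassland is CO2 neutral: soil CO2 and both LUC streams are zero;
* managed-grassland CH4 and N2O follow the regional human-population
  index, with 1860 as the reference level (the dominant driver is
  domestic ruminants, whose numbers track population);
* sparsely grazed CH4 and N2O follow the reconstructed regional
  wild-grazer population over 1800-1859 and are frozen at the 1800
  level over 1750-1799.

Anthropogenic fluxes are then the pointwise difference from the 1750
level for CH4 and N2O; CO2 and LUC pass through unchanged (the sink in
sparsely grazed grassland is driven by indirect human effects and
counts as human-induced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grassflux.tables import make_flux_table, validate_flux_table

__all__ = [
    "BaselineRules",
    "interpolate_decadal",
    "extrapolate_1750_1859",
    "anthropogenic_fluxes",
]


@dataclass(frozen=True)
class BaselineRules:
    """Scalers and anchor years of the pre-industrial extrapolation.

    ``managed_scaler`` and ``sparse_scaler`` are tidy frames with
    columns region, year, value: the regional human-population index
    and wild-grazer population respectively, covering at least
    [preindustrial_year, reference_year].
    """

    managed_scaler: pd.DataFrame
    sparse_scaler: pd.DataFrame
    reference_year: int = 1860
    preindustrial_year: int = 1750
    freeze_year: int = 1800  # sparse scaler frozen at this year before it

    def scaler_ratio(self, which: str, region: str, years: np.ndarray) -> np.ndarray:
        """scaler(region, year)/scaler(region, reference_year), with the
        sparse scaler frozen at the freeze-year value before it."""
        table = self.managed_scaler if which == "managed" else self.sparse_scaler
        sel = table[table["region"] == region].set_index("year")["value"]
        if self.reference_year not in sel.index:
            raise ValueError(f"{which} scaler missing reference year {self.reference_year} for region {region!r}")
        ref = sel.loc[self.reference_year]
        if ref <= 0:
            raise ValueError(f"{which} scaler must be > 0 at the reference year (region {region!r})")
        lookup_years = np.asarray(years, dtype=int)
        if which == "sparse":
            lookup_years = np.where(lookup_years < self.freeze_year, self.freeze_year, lookup_years)
        try:
            vals = sel.loc[lookup_years].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"{which} scaler missing year(s) for region {region!r}: {exc}") from exc
        return vals / ref


def interpolate_decadal(series: pd.Series) -> pd.Series:
    """Annual series from decadal anchor points by linear interpolation.

    ``series`` is indexed by anchor years (ascending); the result spans
    the full anchor range annually and reproduces the anchors exactly.
    A single anchor yields a constant series (with a warning).
    """
    years = np.asarray(series.index, dtype=int)
    if len(years) == 0:
        raise ValueError("no anchor points")
    if np.any(np.diff(years) <= 0):
        raise ValueError("anchor years must be strictly ascending")
    if len(years) == 1:
        warnings.warn("single anchor point: constant extension", stacklevel=2)
        return pd.Series([float(series.iloc[0])], index=years)
    annual_years = np.arange(years[0], years[-1] + 1)
    values = np.interp(annual_years, years, series.to_numpy(dtype=float))
    return pd.Series(values, index=annual_years)


def extrapolate_1750_1859(fluxes: pd.DataFrame, rules: BaselineRules) -> pd.DataFrame:
    """Extend a FluxTable back to the pre-industrial year.

    ``fluxes`` must contain the reference year (1860) for every
    region-component-management present. Returns a FluxTable covering
    [preindustrial_year, reference_year - 1] with CO2/LUC components at
    zero and CH4/N2O scaled per the class rules.
    """
    validate_flux_table(fluxes)
    ref = fluxes[fluxes["year"] == rules.reference_year]
    if not len(ref):
        raise ValueError(f"fluxes missing the reference year {rules.reference_year}")
    years = np.arange(rules.preindustrial_year, rules.reference_year)
    records = []
    for _, row in ref.iterrows():
        comp, mgmt = row["component"], row["management"]
        if comp in ("co2_soil", "luc_pasture", "luc_crop"):
            values = np.zeros_like(years, dtype=float)  # CO2-neutral pre-industrial grassland
        else:
            ratio = rules.scaler_ratio(mgmt, row["region"], years)
            values = row["value"] * ratio
        for y, v in zip(years, values):
            records.append({
                "region": row["region"], "year": int(y), "component": comp,
                "management": mgmt, "value": float(v), "unit": row["unit"],
            })
    return make_flux_table(records)


def anthropogenic_fluxes(total: pd.DataFrame, preindustrial_year: int = 1750) -> pd.DataFrame:
    """Subtract the pre-industrial flux level to get anthropogenic fluxes.

    CH4 and N2O: anthropogenic(t) = total(t) - total(preindustrial_year)
    per region-management (pointwise in time; the 1750 level is a flux,
    not a stock). CO2 and LUC pass through unchanged. Raises
    ``ValueError`` if a CH4/N2O series lacks the pre-industrial year.
    """
    validate_flux_table(total)
    out = total.copy()
    nonco2 = out["component"].isin(["ch4", "n2o"])
    base = (
        out[nonco2 & (out["year"] == preindustrial_year)]
        .set_index(["region", "component", "management"])["value"]
    )
    sub = out[nonco2]
    keys = pd.MultiIndex.from_frame(sub[["region", "component", "management"]])
    missing = keys.unique().difference(base.index)
    if len(missing):
        raise ValueError(
            f"missing {preindustrial_year} baseline for: {list(missing[:5])}"
        )
    out.loc[nonco2, "value"] = sub["value"].to_numpy() - base.loc[keys].to_numpy()
    return out
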