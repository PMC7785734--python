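"""Normalized-marginal attribution: conservation, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from grassflux.attribution import (
    REST,
    SECTORS,
    attribute,
    factorial_runs,
    managed_sparse_rf,
    normalize_shares,
    sector_of,
)
from grassflux.rf import IRFParams, run_rf
from grassflux.tables import make_flux_table

P = IRFParams()


def two_sector_table(years=range(1900, 1940)):
    rows = []
    for y in years:
        rows += [
            {"region": "A", "year": y, "component": "ch4", "management": "managed", "value": 2.0},
            {"region": "B", "year": y, "component": "n2o", "management": "sparse", "value": 0.1},
        ]
    return make_flux_table(rows)


def test_sector_labelling():
    assert sector_of("co2_soil", "sparse") == "co2_soil_sparse"
    assert sector_of("luc_pasture", "managed") == "luc_pasture"
    assert len(SECTORS) == 8


class TestFactorialRuns:
    def test_epsilon_bounds_enforced(self):
        with pytest.raises(ValueError, match="epsilon"):
            factorial_runs(two_sector_table(), None, P, epsilon=0.0, year=1939)

    def test_empty_sectors_yield_zero_delta(self):
        deltas, _ = factorial_runs(two_sector_table(), None, P, year=1939)
        assert deltas[("A", "n2o_managed")] == 0.0
        assert deltas[("A", "ch4_managed")] > 0.0
        assert deltas[REST] == 0.0

    def test_rest_only_world(self):
        grass = two_sector_table()
        grass["value"] = 0.0
        background = two_sector_table()
        deltas, _ = factorial_runs(grass, background, P, year=1939)
        nonzero = {k for k, v in deltas.items() if v != 0.0}
        assert nonzero == {REST}

    def test_linear_mode_delta_proportional_to_epsilon(self):
        d1, _ = factorial_runs(two_sector_table(), None, P, epsilon=0.01, year=1939)
        d2, _ = factorial_runs(two_sector_table(), None, P, epsilon=0.005, year=1939)
        key = ("A", "ch4_managed")
        assert d1[key] == pytest.approx(2 * d2[key], rel=1e-9)


class TestNormalizeShares:
    def test_single_nonzero_delta_takes_share_one(self):
        table = normalize_shares({("A", "ch4_managed"): 0.5, ("B", "n2o_sparse"): 0.0}, 10.0)
        shares = table.set_index(["region", "sector"])["share"]
        assert shares.loc[("A", "ch4_managed")] == 1.0

    def test_two_equal_deltas_split_evenly(self):
        table = normalize_shares({("A", "ch4_managed"): 0.3, ("B", "n2o_sparse"): 0.3}, 10.0)
        assert np.allclose(table["share"], 0.5)

    def test_all_zero_deltas_rejected(self):
        with pytest.raises(ValueError, match="no attribution"):
            normalize_shares({("A", "ch4_managed"): 0.0}, 10.0)


class TestConservationAndOracle:
    def test_contributions_partition_control_total(self, anthro_fluxes):
        table = attribute(anthro_fluxes, None, P, year=2012)
        control = run_rf(anthro_fluxes, P).loc[2012, "rf_total"]
        assert table["share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["contribution_mWm2"].sum() == pytest.approx(control, abs=1e-6)

    def test_linear_contribution_equals_standalone_run(self, anthro_small):
        table = attribute(anthro_small, None, P, year=1960)
        labels = anthro_small.apply(
            lambda r: sector_of(r["component"], r["management"]), axis=1)
        for _, row in table.iterrows():
            if row["sector"] == "REST":
                continue
            mask = (anthro_small["region"] == row["region"]) & (labels == row["sector"])
            if not mask.any() or (anthro_small.loc[mask, "value"] == 0).all():
                assert row["contribution_mWm2"] == 0.0
                continue
            standalone = run_rf(anthro_small[mask], P).loc[1960, "rf_total"]
            assert row["contribution_mWm2"] == pytest.approx(standalone, rel=1e-6)

    def test_shares_robust_to_epsilon(self, anthro_small):
        t1 = attribute(anthro_small, None, P, epsilon=0.01, year=1960)
        t2 = attribute(anthro_small, None, P, epsilon=0.005, year=1960)
        merged = t1.merge(t2, on=["region", "sector"], suffixes=("_1", "_2"))
        big = merged["share_1"].abs() > 1e-12
        rel = np.abs(merged.loc[big, "share_1"] - merged.loc[big, "share_2"]) / np.abs(
            merged.loc[big, "share_1"])
        assert rel.max() < 0.01


@pytest.fixture(scope="session")
def anthro_small(small_scenario):
    from grassflux.pipeline import baseline_rules_from_activity
    from grassflux.preindustrial import anthropogenic_fluxes

    fluxes, activity, _ = small_scenario
    # scenario starts at the reference year, so subtraction uses 1860
    return anthropogenic_fluxes(fluxes, preindustrial_year=1860)


class TestManagedSparseAggregates:
    def test_symmetric_scenario_splits_evenly(self):
        rows = []
        for y in range(1900, 1940):
            rows += [
                {"region": "A", "year": y, "component": "ch4", "management": "managed", "value": 1.0},
                {"region": "A", "year": y, "component": "ch4", "management": "sparse", "value": 1.0},
            ]
        table = attribute(make_flux_table(rows), None, P, year=1939)
        agg = managed_sparse_rf(table)
        assert agg["managed"] == pytest.approx(agg["sparse"], rel=1e-9)

    def test_luc_only_scenario_has_zero_sparse(self):
        rows = [
            {"region": "A", "year": y, "component": "luc_pasture",
             "management": "managed", "value": 0.2}
            for y in range(1900, 1940)
        ]
        table = attribute(make_flux_table(rows), None, P, year=1939)
        agg = managed_sparse_rf(table)
        assert agg["sparse"] == 0.0
        assert agg["managed"] > 0.0

    def test_aggregates_resum_to_grassland_total(self, anthro_fluxes):
        table = attribute(anthro_fluxes, None, P, year=2012)
        agg = managed_sparse_rf(table)
        grass_total = table.loc[table["sector"] != "REST", "contribution_mWm2"].sum()
        assert agg["grassland_total"] == pytest.approx(grass_total, rel=1e-9)
        albedo = {"managed": -3.0, "sparse": 1.0}
        agg2 = managed_sparse_rf(table, albedo)
        assert agg2["managed"] == pytest.approx(agg["managed"] - 3.0)
        assert agg2["sparse"] == pytest.approx(agg["sparse"] + 1.0)
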