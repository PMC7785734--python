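"""Monte Carlo sampling, constraint weighting and weighted summaries."""

import numpy as np
import pandas as pd
import pytest

from grassflux.tier import EmissionFactorSet, FactorUncertainty
from grassflux.uncertainty import (
    EmissionConstraint,
    UncertaintySpec,
    rf_ensemble,
    sample_fluxes,
    summarize,
    weight_ensemble,
)

EF = EmissionFactorSet()


@pytest.fixture(scope="module")
def small_ensemble(default_scenario_module):
    fluxes, activity, _ = default_scenario_module
    spec = UncertaintySpec(n_samples=400)
    return sample_fluxes(fluxes, activity, EF, spec, seed=12)


@pytest.fixture(scope="module")
def default_scenario_module():
    from grassflux.synthetic import DEFAULT_REGIONS, ScenarioConfig, generate_scenario

    cfg = ScenarioConfig(regions=DEFAULT_REGIONS[:3], start_year=1950, end_year=2012, seed=2)
    return generate_scenario(cfg)


class TestSampling:
    def test_zero_sds_reproduce_central_exactly(self, default_scenario_module):
        fluxes, activity, _ = default_scenario_module
        ef0 = EmissionFactorSet(
            uncertainty={k: FactorUncertainty("normal", 0.0) for k in EF.uncertainty})
        spec = UncertaintySpec(n_samples=5, co2_rel_sd=0.0, luc_rel_sd=0.0)
        ens = sample_fluxes(fluxes, activity, ef0, spec, seed=1)
        sample = ens.sample_flux_table(3)
        pd.testing.assert_frame_equal(sample, fluxes)

    def test_co2_and_luc_relative_sd_match_spec(self, default_scenario_module):
        fluxes, activity, _ = default_scenario_module
        spec = UncertaintySpec(n_samples=2000)
        ens = sample_fluxes(fluxes, activity, EF, spec, seed=5)
        co2 = ens.co2_budget(2000)
        rel_sd = co2.std() / abs(np.mean(co2) / np.mean(ens.co2_mult))
        assert rel_sd == pytest.approx(0.46, rel=0.05)
        luc = ens.luc_budget(2000)
        rel_sd_luc = luc.std() / abs(np.mean(luc) / np.mean(ens.luc_mult))
        assert rel_sd_luc == pytest.approx(0.31, rel=0.05)

    def test_lognormal_factor_preserves_median(self, default_scenario_module):
        fluxes, activity, _ = default_scenario_module
        spec = UncertaintySpec(n_samples=4001)
        ens = sample_fluxes(fluxes, activity, EF, spec, seed=9)
        # EF3_PRP is lognormal; the excreta source ratio's median must be ~1
        ratio = ens.source_ratio[("N2O", "soil_excreta")]
        assert np.median(ratio) == pytest.approx(1.0, rel=0.05)

    def test_seed_reproducibility(self, default_scenario_module):
        fluxes, activity, _ = default_scenario_module
        spec = UncertaintySpec(n_samples=50)
        a = sample_fluxes(fluxes, activity, EF, spec, seed=3)
        b = sample_fluxes(fluxes, activity, EF, spec, seed=3)
        np.testing.assert_array_equal(a.co2_mult, b.co2_mult)
        for key in a.source_ratio:
            np.testing.assert_array_equal(a.source_ratio[key], b.source_ratio[key])

    def test_materialized_member_matches_multipliers(self, small_ensemble):
        i = 7
        table = small_ensemble.sample_flux_table(i)
        co2 = table[table["component"] == "co2_soil"].groupby("year")["value"].sum()
        assert co2.loc[2000] == pytest.approx(small_ensemble.co2_budget(2000)[i], rel=1e-12)
        ch4 = table[table["component"] == "ch4"].groupby("year")["value"].sum()
        assert ch4.loc[2000] == pytest.approx(
            small_ensemble.gas_emission("ch4", 2000)[i], rel=1e-9)


class TestWeights:
    def test_no_constraints_uniform(self, small_ensemble):
        w = weight_ensemble(small_ensemble, ())
        assert np.allclose(w, 1.0 / small_ensemble.n)

    def test_sample_at_constraint_dominates(self, small_ensemble):
        year = 2000
        ch4 = small_ensemble.gas_emission("ch4", year)
        target = ch4[42]
        c = EmissionConstraint("ch4", year, reference=target, sd=1e-4 * abs(target))
        w = weight_ensemble(small_ensemble, (c,))
        assert w.argmax() == 42
        assert w[42] > 0.5

    def test_symmetric_samples_weighted_equally(self):
        # direct check of the Gaussian weight formula on a 2-point ensemble
        class Fake:
            n = 2
            spec = UncertaintySpec(n_samples=2)

            def gas_emission(self, gas, year):
                return np.array([9.0, 11.0])  # ±1 sigma around 10

        w = weight_ensemble(Fake(), (EmissionConstraint("ch4", 2000, 10.0, 1.0),))
        assert w[0] == pytest.approx(w[1])

    def test_constraint_validation(self):
        with pytest.raises(ValueError, match="sd"):
            EmissionConstraint("ch4", 2000, 1.0, 0.0)
        with pytest.raises(ValueError, match="finite"):
            EmissionConstraint("ch4", 2000, float("nan"), 1.0)


class TestSummarize:
    def test_hand_computed_weighted_moments(self):
        out = summarize(np.array([1.0, 2.0, 3.0]))
        assert out["mean"] == pytest.approx(2.0)
        assert out["sd"] == pytest.approx(np.sqrt(2.0 / 3.0))  # population convention
        assert out["ess"] == pytest.approx(3.0)

    def test_single_sample_sd_zero(self):
        out = summarize(np.array([5.0]))
        assert out["mean"] == 5.0 and out["sd"] == 0.0

    def test_concentrated_weights_pick_that_sample(self):
        out = summarize(np.array([1.0, 2.0, 9.0]), np.array([0.0, 0.0, 1.0]))
        assert out["mean"] == 9.0 and out["sd"] == 0.0 and out["ess"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(np.array([]))


def test_one_sigma_coverage_near_68_percent():
    """Repeated small experiments: the 1-sigma interval of the sampled
    CO2 budget should cover the central value ~68% of the time."""
    rng = np.random.default_rng(2024)
    n_exp, n_samp, rel_sd, truth = 60, 80, 0.46, -1.0
    hits = 0
    for _ in range(n_exp):
        samples = truth * (1.0 + rel_sd * rng.standard_normal(n_samp))
        s = summarize(samples)
        # 1-sigma interval of the recovered budget: mean +/- standard error
        hits += abs(s["mean"] - truth) <= s["sd"] / np.sqrt(s["ess"])
    # binomial(60, 0.68) has sd ~3.6; accept a 3-sigma band around 41
    assert 30 <= hits <= 52


def test_rf_ensemble_runs_and_centres_near_deterministic(default_scenario_module):
    from grassflux.rf import IRFParams, run_rf

    fluxes, activity, _ = default_scenario_module
    spec = UncertaintySpec(n_samples=60)
    ens = sample_fluxes(fluxes, activity, EF, spec, seed=21)
    vals = rf_ensemble(ens, IRFParams(), year=2012)
    central = run_rf(fluxes, IRFParams()).loc[2012, "rf_total"]
    assert np.isfinite(vals).all()
    s = summarize(vals)
    assert abs(s["mean"] - central) < 3 * s["sd"] / np.sqrt(spec.n_samples) + 0.25 * abs(central)
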