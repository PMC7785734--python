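import pandas as pd
import pytest

from grassflux.pipeline import baseline_rules_from_activity
from grassflux.preindustrial import anthropogenic_fluxes, extrapolate_1750_1859
from grassflux.synthetic import (
    DEFAULT_REGIONS,
    RegionParams,
    ScenarioConfig,
    generate_scenario,
)


@pytest.fixture(scope="session")
def default_scenario():
    """Full default 9-region 1750-2012 scenario, seed 1."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    """Three regions, shorter span: cheap input for per-run-expensive tests."""
    regions = DEFAULT_REGIONS[:3]
    cfg = ScenarioConfig(regions=regions, start_year=1860, end_year=1960, seed=7)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def anthro_fluxes(default_scenario):
    """Anthropogenic fluxes of the default scenario via the baseline rules."""
    fluxes, activity, _ = default_scenario
    rules = baseline_rules_from_activity(activity)
    modern = fluxes[fluxes["year"] >= rules.reference_year]
    early = extrapolate_1750_1859(modern, rules)
    total = pd.concat([early, modern], ignore_index=True)
    return anthropogenic_fluxes(total, rules.preindustrial_year)


@pytest.fixture()
def degenerate_config():
    from grassflux.synthetic import degenerate_region_params

    regions = DEFAULT_REGIONS[:2]
    params = {r: degenerate_region_params() for r in regions}
    return ScenarioConfig(regions=regions, seed=3, region_params=params)
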