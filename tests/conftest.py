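import pytest

from cld4 import (CampaignConfig, FeatureTable, build_feature_table,
                  generate_campaign, load_plan, warehouse_from_bundle)


@pytest.fixture(scope="session")
def small_config() -> CampaignConfig:
    """A fast 8-clone campaign used by most unit tests."""
    return CampaignConfig(
        n_clones=8, n_stations=2, duration_days=6, sensor_interval_s=1800,
        n_elite=2, titre_sample_days=[2, 4, 6], first_feed_day=2,
        feed_spacing_days=1, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_campaign(small_config)


@pytest.fixture(scope="session")
def small_warehouse(small_bundle):
    return warehouse_from_bundle(small_bundle)


@pytest.fixture(scope="session")
def small_features(small_warehouse) -> FeatureTable:
    return build_feature_table(small_warehouse, load_plan("ranking"))


@pytest.fixture(scope="session")
def default_bundle():
    """One full 48-clone campaign at the default configuration."""
    return generate_campaign(CampaignConfig(seed=1))


@pytest.fixture(scope="session")
def default_warehouse(default_bundle):
    return warehouse_from_bundle(default_bundle)
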