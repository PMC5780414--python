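import pytest
from hypothesis import settings

from darkcarbon import datasets, metrics_frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def campaign_profiles():
    """The bundled deep-Mediterranean transect as StationProfile objects."""
    return datasets.load_station_profiles()


@pytest.fixture(scope="session")
def campaign_metrics(campaign_profiles):
    """Per-depth derived metrics over the bundled campaign."""
    return metrics_frame(campaign_profiles)


@pytest.fixture(scope="session")
def published_cell_specific():
    """As-published cell-specific values for regression comparison."""
    return datasets.cell_specific_published()


@pytest.fixture(scope="session")
def phpp():
    """Literature photic-zone primary production table."""
    return datasets.phpp_table()
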