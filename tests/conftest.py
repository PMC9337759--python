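import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from firetrack.synthetic import SeasonSpec, simulate_season


@pytest.fixture(scope="session")
def default_season():
    """One default synthetic season shared by read-only tests."""
    return simulate_season(SeasonSpec(), seed=42)


@pytest.fixture(scope="session")
def default_result(default_season):
    from firetrack.pipeline import run_pipeline

    return run_pipeline(
        default_season.detections,
        default_season.stack,
        ba_raster=default_season.ba_raster,
    )
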