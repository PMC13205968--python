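import json
from pathlib import Path

import pytest

import betternest as bn

GOLDEN_PATH = Path(__file__).parent / "data" / "table1_golden.json"


@pytest.fixture(scope="session")
def instrument() -> bn.Instrument:
    return bn.load_instrument()


@pytest.fixture(scope="session")
def golden() -> dict:
    return json.loads(GOLDEN_PATH.read_text("utf-8"))


@pytest.fixture(scope="session")
def geo() -> bn.GeoTable:
    # 30 counties covers every lead x air band combination twice.
    return bn.generate_fixture(n_counties=30, seed=7)


def record(postal_code: str = "00000", **overrides) -> dict:
    """A complete, valid flat response record (best answers by default)."""
    base = {
        "life_stage": "currently_pregnant",
        "postal_code": postal_code,
        "Q3": "never_public",
        "Q4": "green_only",
        "Q5": "never_rarely",
        "Q6": "almost_never",
        "Q7": "always_dirty_dozen",
        "Q8": "less_than_10",
        "Q9": "all_the_time",
    }
    base.update(overrides)
    return base


WORST_ANSWERS = {
    "Q3": "daily_smoker",
    "Q4": "daily",
    "Q5": "regularly",
    "Q6": "daily",
    "Q7": "never_cheapest",
    "Q8": "more_than_18",
    "Q9": "never",
}


@pytest.fixture()
def single_county_geo() -> bn.GeoTable:
    """One clean county (both band maxima) reachable at ZIP 07043."""
    county = bn.CountyRecord(county_id="essex", pct_pre1980_housing=30.0, pm25_annual=8.0)
    return bn.GeoTable(counties={"essex": county}, crosswalk={"07043": "essex"})
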