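import pytest

from popmortgen import (
    SyntheticParams,
    build_popmort,
    make_life_table,
)


@pytest.fixture
def params():
    return SyntheticParams(seed=42)


@pytest.fixture
def life_table_pair(params):
    """Synthetic male/female life tables for the 2016-2020 period."""
    return [make_life_table(params, (2016, 2020), sex) for sex in (1, 2)]


@pytest.fixture
def popmort(life_table_pair):
    """PopMort table over 2009-2024 built from the synthetic pair."""
    return build_popmort(life_table_pair, 2009, 2024)


@pytest.fixture
def small_popmort(life_table_pair):
    """Single-year PopMort table (202 records) for cheap tests."""
    return build_popmort(life_table_pair, 2018, 2018)
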