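import logging

import pytest
from hypothesis import settings

import ufcarbon as uf

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# the fixture tables intentionally trip two printed-rounding warnings
logging.getLogger("ufcarbon.tables").setLevel(logging.ERROR)
logging.getLogger("ufcarbon.uncertainty").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rus():
    return uf.load_ru_table()


@pytest.fixture(scope="session")
def cities():
    return uf.load_city_table()


@pytest.fixture(scope="session")
def rules():
    return uf.load_ecozone_rules()


@pytest.fixture(scope="session")
def ru_by_id(rus):
    return {ru.ru_id: ru for ru in rus}


@pytest.fixture(scope="session")
def city_by_name(cities):
    return {c.name: c for c in cities}


@pytest.fixture(scope="session")
def zone_map(cities, rus, rules):
    return uf.derive_ecozone_densities(cities, rus, rules)


@pytest.fixture(scope="session")
def ru_densities(zone_map, rus):
    return uf.assign_ru_densities(zone_map, rus)


@pytest.fixture(scope="session")
def accounts(rus, ru_densities):
    return uf.build_account(rus, ru_densities)


@pytest.fixture(scope="session")
def printed_ru_densities(rus):
    return uf.assign_ru_densities(uf.load_printed_densities(), rus)
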