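import warnings

import pytest

import olacea as o


@pytest.fixture(scope="session")
def fixture_dict():
    return o.load_fixture()


def _scenario(country, variant="corrected", **overrides):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # as-published parameter warning
        return o.build_scenario(country, variant=variant, **overrides)


@pytest.fixture(scope="session")
def china_scenario():
    return _scenario("china")


@pytest.fixture(scope="session")
def us_scenario():
    return _scenario("us")


@pytest.fixture(scope="session")
def china_base(china_scenario):
    return o.run_scenario(china_scenario)
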