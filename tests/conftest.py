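import pytest

from pets import clean_records, generate, default_scenario

PRESET_SEED = 11
END_YEAR = 2022


@pytest.fixture(scope="session")
def preset():
    """The two-century built-in scenario, generated once per session."""
    config = default_scenario(PRESET_SEED)
    records, truth = generate(config)
    return config, records, truth


@pytest.fixture(scope="session")
def preset_cleaned(preset):
    _, records, _ = preset
    cleaned, report = clean_records(records, end_year=END_YEAR)
    return cleaned, report
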