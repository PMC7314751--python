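import pandas as pd
import pytest

from fimsopt.features import FilterCriteria
from fimsopt.simulate import AcquisitionConfig, generate_metabolome


@pytest.fixture(scope="session")
def default_criteria():
    return FilterCriteria()


@pytest.fixture(scope="session")
def noiseless_config():
    return AcquisitionConfig(seed=42).noiseless()


@pytest.fixture(scope="session")
def noisy_config():
    return AcquisitionConfig(seed=42)


@pytest.fixture(scope="session")
def small_metabolome():
    """A small skewed metabolome for fast end-to-end tests."""
    return generate_metabolome(150, seed=11)


@pytest.fixture(scope="session")
def default_metabolome():
    """The default serum-like skewed metabolome used by the deeper tests."""
    return generate_metabolome(800, seed=42)


def make_peak_table(rows):
    """Helper: build a minimal peak table from (injection, blank, mz, intensity)."""
    df = pd.DataFrame(rows, columns=["injection", "blank", "mz", "intensity"])
    df["sample"] = "s"
    df["polarity"] = "negative"
    df["range_id"] = 0
    df["range_low"] = 0.0
    df["range_high"] = 3000.0
    df["injection_time_ms"] = 100.0
    return df
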