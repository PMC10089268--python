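import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

import habitcoach as hc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def engine_config() -> hc.EngineConfig:
    return hc.load_config()


@pytest.fixture(scope="session")
def catalogue(engine_config) -> hc.Catalogue:
    return engine_config.catalogue()


@pytest.fixture(scope="session")
def lms_table() -> hc.LMSTable:
    return hc.load_default_lms()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260105)


START = dt.date(2026, 1, 5)  # a Monday


def daily_series(values, variable_id="steps", child_id="c1", start=START):
    return hc.DailyTimeSeries(child_id, variable_id, start, np.asarray(values, dtype=float))
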