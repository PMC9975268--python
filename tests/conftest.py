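"""Shared fixtures: seeded default cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pepstress.cohort import generate_cohort
from pepstress.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort71(default_config):
    """One default cohort with resting beat windows."""
    return generate_cohort(default_config, seed=11, beats="rest")


@pytest.fixture(scope="session")
def full_beats_cohort(default_config):
    """Default cohort with beat windows spanning rest, mental and physical."""
    return generate_cohort(default_config, seed=12, beats="full")


def pool_measurements(config: GeneratorConfig, seeds) -> pd.DataFrame:
    """Measurements pooled over seeded replicate cohorts, with subject ids
    disambiguated per replicate."""
    parts = []
    for s in seeds:
        m = generate_cohort(config, int(s), beats="none").measurements
        parts.append(m.assign(subject_id=m["subject_id"] + f"_r{s}"))
    return pd.concat(parts, ignore_index=True)


@pytest.fixture(scope="session")
def pooled_measurements(default_config) -> pd.DataFrame:
    """Measurements pooled over ten seeded default cohorts."""
    return pool_measurements(default_config, range(100, 110))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
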