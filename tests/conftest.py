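import numpy as np
import pandas as pd
import pytest

from depmci import CohortConfig, simulate_cohort, annotate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=60, n_waves=4, seed=7, n_aux_features=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_annotated(small_cohort):
    return annotate_cohort(small_cohort)


@pytest.fixture(scope="session")
def medium_annotated():
    """A cohort large enough for stable windowing/splitting tests."""
    cfg = CohortConfig(n_participants=400, seed=11, n_aux_features=3)
    return annotate_cohort(simulate_cohort(cfg)), cfg
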