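import numpy as np
import pandas as pd
import pytest

import comorbtraj as ct


@pytest.fixture(scope="session")
def default_config():
    return ct.load_config()


@pytest.fixture(scope="session")
def small_cohort_tables():
    """A modest corrupted synthetic cohort shared across tests."""
    cfg = ct.load_config(n_participants=1500, seed=42)
    participants, events, truth = ct.generate_cohort(cfg)
    corrupted = ct.corrupt_events(events, truth, cfg)
    return cfg, participants, corrupted, truth


@pytest.fixture(scope="session")
def small_cohort(small_cohort_tables):
    cfg, participants, corrupted, truth = small_cohort_tables
    occurrences = ct.resolve_first_occurrences(corrupted, participants)
    return ct.build_cohort(occurrences, participants, cfg.index_condition)


def make_occurrences(rows):
    """Build an occurrence table from (pid, condition, iso_date) triples."""
    return pd.DataFrame(
        [
            {"participant_id": pid, "condition": cond, "first_date": pd.Timestamp(d)}
            for pid, cond, d in rows
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240424)
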