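import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import patsim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """Two subjects per group, 6 items per category, 8^3 grid."""
    return patsim.SimConfig(
        n_subjects_per_group=2,
        n_items_per_category=6,
        grid_shape=(8, 8, 8),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    table = patsim.make_trial_table(tiny_config)
    betas, truth = patsim.simulate_beta_patterns(tiny_config, table)
    table = patsim.simulate_memory_outcomes(truth, tiny_config, table)
    return {"config": tiny_config, "table": table, "betas": betas, "truth": truth}


@pytest.fixture(scope="session")
def one_subject(tiny_study):
    return tiny_study["betas"]["y01"]


def make_recognition_table(hits, misses, fas, crs, subject="s1", age_group="young"):
    """Recognition-only trial table with exact outcome counts."""
    rows = []
    outcomes = (
        [("old", "old", "hit")] * hits
        + [("old", "new", "miss")] * misses
        + [("new", "old", "fa")] * fas
        + [("new", "new", "cr")] * crs
    )
    for i, (status, resp, outc) in enumerate(outcomes):
        rows.append(
            {
                "subject": subject,
                "age_group": age_group,
                "phase": "recognition",
                "run": 1 + i % 2,
                "block": 0,
                "trial": i,
                "category": "face" if i % 2 == 0 else "house",
                "item": f"it{i:03d}",
                "old": status == "old",
                "onset_s": float(i),
                "response": resp,
                "outcome": outc,
            }
        )
    return pd.DataFrame(rows)
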