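import numpy as np
import pandas as pd
import pytest

from asdscreen import registry, simulate


@pytest.fixture(scope="session")
def packaged_registry():
    return registry.load_registry()


@pytest.fixture(scope="session")
def subscale_map(packaged_registry):
    _, subscales = packaged_registry
    return {s.name: s for s in subscales}


@pytest.fixture(scope="session")
def small_cohort():
    """Small balanced cohort, moderate planted signal (shared, read-only)."""
    cfg = simulate.CohortConfig(
        n_per_group={g: 25 for g in simulate.GROUPS},
        planted_items=frozenset({1, 5, 9}),
        delta=1.5,
        n_items=12,
        seed=11,
    )
    table, truth = simulate.generate_cohort(cfg)
    return cfg, table, truth


def scores_frame(cases, controls, gender="girl", age_band="child"):
    """Build a minimal scored table for the accuracy functions."""
    scores = list(cases) + list(controls)
    return pd.DataFrame(
        {
            "child_id": np.arange(len(scores)),
            "score": np.asarray(scores, dtype=float),
            "is_case": [True] * len(cases) + [False] * len(controls),
            "gender": gender,
            "age_band": age_band,
        }
    )


@pytest.fixture
def make_scores():
    return scores_frame
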