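import numpy as np
import pandas as pd
import pytest

from herdrank.config import CohortConfig, EffectSizes, MicrobiomeConfig
from herdrank.simulate import Cohort, generate_cohort, true_hierarchy


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_hierarchy(default_cohort) -> pd.DataFrame:
    return pd.concat(
        [true_hierarchy(default_cohort, p) for p in (1, 2, 3)], ignore_index=True
    )


@pytest.fixture(scope="session")
def planted_classes() -> pd.Series:
    """16 dominant + 16 submissive sample labels for the biomarker design."""
    return pd.Series(
        ["dominant"] * 16 + ["submissive"] * 16,
        index=pd.Index([f"s{i:02d}" for i in range(32)], name="sample_id"),
    )


@pytest.fixture(scope="session")
def micro_config() -> MicrobiomeConfig:
    return MicrobiomeConfig()


@pytest.fixture(scope="session")
def planted_panel() -> dict[str, float]:
    return dict(EffectSizes().planted_log2fc)


def make_bout(a, b, outcome="decisive", winner=None, confirmed=False, pen="P1",
              phase=1, day=0):
    return {
        "pen_id": pen,
        "phase": phase,
        "day": day,
        "animal_a": a,
        "animal_b": b,
        "outcome": outcome,
        "winner": winner,
        "confirmed": confirmed,
    }


@pytest.fixture
def bout_factory():
    return make_bout


@pytest.fixture
def rng():
    return np.random.default_rng(0)
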