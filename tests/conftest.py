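import numpy as np
import pandas as pd
import pytest

from rtbold.config import (
    BehaviorConfig,
    ExperimentConfig,
    GLMConfig,
    TaskDesignConfig,
    tiny_experiment,
)


@pytest.fixture
def msit_cfg() -> TaskDesignConfig:
    return TaskDesignConfig(task="msit", n_runs=4)


@pytest.fixture
def simple_cfg() -> TaskDesignConfig:
    return TaskDesignConfig(task="simple", n_runs=2)


@pytest.fixture
def glm_cfg() -> GLMConfig:
    return GLMConfig()


@pytest.fixture
def behavior_cfg() -> BehaviorConfig:
    return BehaviorConfig()


@pytest.fixture
def tiny_cfg() -> ExperimentConfig:
    return tiny_experiment(seed=7)


@pytest.fixture(scope="session")
def default_cfg() -> ExperimentConfig:
    return ExperimentConfig(seed=11)


def make_events(
    rts_ms,
    condition="congruent",
    correct=None,
    task="msit",
    run_index=0,
    soa=4.0,
    start=10.0,
):
    """Hand-built event table with evenly spaced onsets."""
    rts = np.asarray(rts_ms, dtype=float)
    n = len(rts)
    correct = np.ones(n, dtype=bool) if correct is None else np.asarray(correct, dtype=bool)
    cond = [condition] * n if isinstance(condition, str) else list(condition)
    return pd.DataFrame(
        {
            "run_index": run_index,
            "task": task,
            "onset": start + soa * np.arange(n),
            "condition": cond,
            "rt_ms": rts,
            "correct": pd.array(correct, dtype="boolean"),
            "excluded_as": "none",
        }
    )
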