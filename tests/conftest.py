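import numpy as np
import pytest

from explorebandit import (
    ModelParams,
    SessionRecord,
    TaskConfig,
    generate_schedule,
)
from explorebandit.records import MISSED


def make_session(choices, rewards, rts=None, missed=None, subject="s1", group="g"):
    """Build a SessionRecord from plain lists (single run)."""
    n = len(choices)
    choices = np.asarray(choices, dtype=int)
    if missed is None:
        missed = choices == MISSED
    rts = np.asarray(rts, dtype=float) if rts is not None else np.full(n, 0.4)
    rts = np.where(missed, np.nan, rts)
    return SessionRecord(
        subject=subject, group=group,
        run=np.ones(n, dtype=int), trial=np.arange(1, n + 1),
        choice=choices, reward=np.asarray(rewards, dtype=float),
        rt=rts, missed=np.asarray(missed, dtype=bool),
    )


def random_session(rng, n_trials=30, n_arms=4, miss_rate=0.1, subject="s1", group="g"):
    """A random (model-free) session for oracle comparisons."""
    choices = rng.integers(0, n_arms, size=n_trials)
    missed = rng.random(n_trials) < miss_rate
    choices = np.where(missed, MISSED, choices)
    rewards = np.where(missed, 0.0, rng.uniform(1, 100, size=n_trials))
    rts = rng.uniform(0.2, 1.0, size=n_trials)
    return make_session(choices, rewards, rts=rts, missed=missed,
                        subject=subject, group=group)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(TaskConfig(seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
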