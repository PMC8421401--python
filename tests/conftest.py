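import numpy as np
import pandas as pd
import pytest

from spaced_select import (PopulationConfig, ReviewEvent, ReviewLog,
                           simulate_trial)

DAY = 86400.0


def make_event(learner="u1", item="q1", session="s1", day=0.0, recall=1,
               arm="select"):
    return ReviewEvent(learner, item, session, day * DAY, recall, arm)


@pytest.fixture
def tiny_log():
    """Two learners, two arms, hand-written times (days 0..6)."""
    events = [
        make_event("alice", "q1", "a-s0", 0.0, 1, "select"),
        make_event("alice", "q2", "a-s0", 0.0, 0, "select"),
        make_event("alice", "q1", "a-s1", 3.0, 1, "select"),
        make_event("alice", "q2", "a-s1", 3.0, 1, "select"),
        make_event("alice", "q1", "a-s2", 6.0, 0, "select"),
        make_event("bob", "q1", "b-s0", 0.5, 1, "random"),
        make_event("bob", "q1", "b-s1", 2.0, 0, "random"),
        make_event("bob", "q2", "b-s1", 2.0, 1, "random"),
    ]
    return ReviewLog.from_events(events)


@pytest.fixture(scope="session")
def small_trial():
    """A small but non-trivial simulated trial shared across tests."""
    cfg = PopulationConfig(n_learners=60, n_items=25, horizon_days=25,
                           session_rate=1.0, session_size_mean=7,
                           dropout_hazard=0.02, seed=42)
    return simulate_trial(cfg)
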