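"""Session-construction policies: SELECT, difficulty order, uniform random.

The three arms of the trial are interchangeable policies that decide which
items go into a learner's next study session:

* ``select`` — ranks items by the closed-form optimal selection probability
  ``p* = (1 - m) / sqrt(q)``, where ``m`` is the current predicted recall
  probability of the item: the closer an item is to being forgotten, the
  earlier it is presented.  Items never reviewed before are presented first,
  easiest first.
* ``difficulty`` — cycles through all items in fixed order of initial
  difficulty (ascending initial forgetting rate), easiest first.
* ``random`` — uniform draws over the item universe, with replacement.

All policies are deterministic functions of (state, config, now); the random
arm draws from a per-learner seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .memory_model import HLRParams, MemoryState, recall_probability

__all__ = [
    "PolicyConfig", "LearnerSchedulerState", "select_probability",
    "rank_items_select", "sample_items_select", "next_items_difficulty",
    "next_items_random", "build_session", "learner_rng",
]


@dataclass
class PolicyConfig:
    """Arm identifier plus policy hyperparameters.

    ``q >= 1`` trades off recall probability upon review against session
    size under the select policy (results are agnostic to its value since
    the app truncates the ranked list at a user-chosen size; default 1).
    ``difficulty_order`` is the item universe sorted ascending by initial
    forgetting rate (easiest first); it defines both the difficulty arm's
    cycle and the unseen-items-first order of the select arm.
    """

    arm: str
    difficulty_order: tuple[str, ...]
    q: float = 1.0
    seed: int = 0
    stochastic: bool = False   # select arm: Bernoulli(p*) sampling instead of ranking

    def __post_init__(self):
        if self.arm not in ("select", "difficulty", "random"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if len(set(self.difficulty_order)) != len(self.difficulty_order):
            raise ValueError("difficulty_order contains duplicates")


@dataclass
class LearnerSchedulerState:
    """Per-learner scheduler persistence between sessions."""

    memory: dict[str, MemoryState] = field(default_factory=dict)
    pointer: int = 0                      # circular index, difficulty arm
    rng: np.random.Generator | None = None  # random arm stream


def learner_rng(global_seed: int, learner_id: str) -> np.random.Generator:
    """Independent, reproducible per-learner random stream."""
    h = np.uint64(0xCBF29CE484222325)  # FNV-1a over the learner id
    for byte in learner_id.encode("utf-8"):
        h = np.uint64((int(h) ^ byte) * 0x100000001B3 % (1 << 64))
    return np.random.default_rng(np.random.SeedSequence([global_seed, int(h)]))


def select_probability(m, q: float = 1.0):
    """Optimal probability of including an item with recall probability ``m``.

    ``p* = (1 - m) / sqrt(q)``, clipped to [0, 1]; maximal value 1/sqrt(q),
    zero exactly when the item is perfectly remembered (m == 1).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0) or np.any(m_arr > 1):
        raise ValueError("m must lie in [0, 1]")
    out = np.clip((1.0 - m_arr) / np.sqrt(q), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _split_seen(state: LearnerSchedulerState, config: PolicyConfig):
    seen = [i for i in config.difficulty_order
            if state.memory.get(i) is not None
            and state.memory[i].last_review_time is not None]
    unseen = [i for i in config.difficulty_order if i not in set(seen)]
    return seen, unseen


def rank_items_select(state: LearnerSchedulerState, now: float,
                      config: PolicyConfig) -> list[str]:
    """Full item ranking under the select policy at time ``now`` (days).

    Unseen items come first in ascending initial difficulty; seen items
    follow in descending selection probability (ties broken by ascending
    item id).  Deterministic.
    """
    seen, unseen = _split_seen(state, config)
    scored = []
    for item in seen:
        ms = state.memory[item]
        delta = max(now - ms.last_review_time, 0.0)
        m = recall_probability(ms.n, delta)
        scored.append((-select_probability(m, config.q), item))
    scored.sort()
    return unseen + [item for _, item in scored]


def sample_items_select(state: LearnerSchedulerState, now: float,
                        config: PolicyConfig,
                        rng: np.random.Generator) -> list[str]:
    """Stochastic select variant: include each seen item with prob. p*.

    Returns unseen items first, then the Bernoulli-sampled seen items in
    descending p*.  The deterministic ranking is the default deployed
    behaviour; this variant realizes the selection probabilities literally.
    """
    seen, unseen = _split_seen(state, config)
    kept = []
    for item in seen:
        ms = state.memory[item]
        delta = max(now - ms.last_review_time, 0.0)
        p = select_probability(recall_probability(ms.n, delta), config.q)
        if rng.random() < p:
            kept.append((-p, item))
    kept.sort()
    return unseen + [item for _, item in kept]


def next_items_difficulty(state: LearnerSchedulerState, k: int,
                          config: PolicyConfig) -> list[str]:
    """Next ``k`` items of the fixed easiest-first cycle; advances the pointer."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = config.difficulty_order
    n = len(order)
    out = [order[(state.pointer + j) % n] for j in range(k)]
    state.pointer = (state.pointer + k) % n
    return out


def next_items_random(state: LearnerSchedulerState, k: int,
                      config: PolicyConfig) -> list[str]:
    """``k`` uniform draws over the item universe, with replacement."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if state.rng is None:
        state.rng = np.random.default_rng(config.seed)
    idx = state.rng.integers(0, len(config.difficulty_order), size=k)
    return [config.difficulty_order[i] for i in idx]


def build_session(policy_output: Sequence[str], session_size: int,
                  with_replacement: bool = False) -> list[str]:
    """Cut a policy's ordering (or draw) down to the session of given size.

    For ranking policies the session is the top ``session_size`` items and
    contains no duplicates; a size exceeding the universe is truncated.
    For the with-replacement random draw the output is used as-is (it may
    contain duplicates by design).
    """
    if session_size < 1:
        raise ValueError("session_size must be >= 1")
    items = list(policy_output)
    if with_replacement:
        return items[:session_size]
    return items[:min(session_size, len(items))]
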