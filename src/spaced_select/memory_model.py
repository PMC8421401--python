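"""Exponential forgetting-curve memory model and half-life-regression fitting.

The model: a learner's probability of recalling item *i* after an interval
``delta`` (days) since the last review is

    m = exp(-n * delta)

where ``n`` (1/day) is the item's current forgetting rate.  Each review
updates the rate multiplicatively:

    n <- n * (1 - alpha)   on a successful recall  (alpha in [0, 1))
    n <- n * (1 + beta)    on a failed recall      (beta >= 0)

so after ``s`` successes and ``f`` failures the rate is the closed form
``n0 * (1-alpha)**s * (1+beta)**f`` with ``n0`` the item's initial rate
(its "initial difficulty").  Parameters are estimated by penalized least
squares of binary recall outcomes against predicted recall probability —
a count-based variant of half-life regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .core_io import ReviewLog

__all__ = [
    "MemoryState", "HLRParams", "RecallObservation", "FitConfig",
    "recall_probability", "update_forgetting_rate", "predicted_rate",
    "observations_from_log", "fit_hlr", "fit_initial_rates",
    "WeakIdentificationWarning",
]


class WeakIdentificationWarning(UserWarning):
    """An item's rate is weakly identified by the available observations."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class MemoryState:
    """Memory state of one (learner, item) pair."""

    n: float                      # forgetting rate, 1/day, > 0
    last_review_time: float | None = None   # days, None before first review
    successes: int = 0
    failures: int = 0

    def __post_init__(self):
        if not (self.n > 0 and np.isfinite(self.n)):
            raise ValueError(f"forgetting rate must be positive, got {self.n}")

    @property
    def n_reviews(self) -> int:
        return self.successes + self.failures


@dataclass
class HLRParams:
    """Fitted model parameters.

    ``n0`` maps item id to its initial forgetting rate (1/day).  ``alpha``
    and ``beta`` are the global success/failure multipliers.  Items absent
    from ``n0`` (never reviewed by anyone) fall back to the global median
    initial rate, so cold-start scheduling is always defined.
    """

    n0: dict[str, float]
    alpha: float
    beta: float
    l2: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        bad = [k for k, v in self.n0.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive n0 for items: {bad[:5]}")

    @property
    def n0_default(self) -> float:
        if not self.n0:
            raise ValueError("no fitted items to derive a default rate from")
        return float(np.median(list(self.n0.values())))

    def n0_for(self, item_id: str) -> float:
        return self.n0.get(item_id, self.n0_default) if self.n0 else None

    def to_json(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "l2": self.l2,
                "n0": {k: float(v) for k, v in self.n0.items()}}

    @classmethod
    def from_json(cls, obj: Mapping) -> "HLRParams":
        return cls(n0=dict(obj["n0"]), alpha=float(obj["alpha"]),
                   beta=float(obj["beta"]), l2=float(obj.get("l2", 0.0)))


@dataclass(frozen=True)
class RecallObservation:
    """One delta/outcome observation for fitting (not the first exposure)."""

    item_id: str
    delta: float              # days since previous review, > 0
    successes_before: int
    failures_before: int
    recall: int


# ---------------------------------------------------------------------------
# Model primitives
# ---------------------------------------------------------------------------

def recall_probability(n, delta):
    """exp(-n * delta): probability of recall after ``delta`` days at rate ``n``.

    Vectorized over both arguments. Raises ValueError on negative input.
    """
    n = np.asarray(n, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(n < 0) or np.any(delta < 0):
        raise ValueError("rate and delta must be non-negative")
    out = np.exp(-n * delta)
    return float(out) if out.ndim == 0 else out


def update_forgetting_rate(state: MemoryState, recall: int,
                           params: HLRParams,
                           review_time: float | None = None) -> MemoryState:
    """Apply one review outcome to a memory state (returns a new state)."""
    if recall not in (0, 1):
        raise ValueError(f"recall must be 0 or 1, got {recall!r}")
    if recall == 1:
        n = state.n * (1.0 - params.alpha)
        return MemoryState(n, review_time, state.successes + 1, state.failures)
    n = state.n * (1.0 + params.beta)
    return MemoryState(n, review_time, state.successes, state.failures + 1)


def predicted_rate(obs: RecallObservation, params: HLRParams) -> float:
    """Closed-form rate n0 * (1-alpha)^s * (1+beta)^f before the observed review."""
    if obs.item_id not in params.n0:
        raise KeyError(f"item {obs.item_id!r} not in fitted parameters")
    return (params.n0[obs.item_id]
            * (1.0 - params.alpha) ** obs.successes_before
            * (1.0 + params.beta) ** obs.failures_before)


# ---------------------------------------------------------------------------
# Observation extraction
# ---------------------------------------------------------------------------

def observations_from_log(log: ReviewLog) -> pd.DataFrame:
    """Extract (item, delta, counts-before, recall) observations from a log.

    The first review of each (learner, item) pair has no preceding interval
    and yields no observation (it still counts toward later success/failure
    counts).  Reviews at zero interval (the same item repeated within one
    session) likewise update the counts but are not used as observations,
    since ``delta > 0`` is required.
    """
    df = log.events
    cols = ["item_id", "delta", "successes_before", "failures_before", "recall"]
    if not len(df):
        return pd.DataFrame(columns=cols)
    grp = df.groupby(["learner_id", "question_id"], sort=False)
    prev_time = grp["time_days"].shift()
    delta = df["time_days"] - prev_time
    s_before = grp["recall"].cumsum() - df["recall"]
    f_before = grp.cumcount() - s_before
    keep = delta.notna() & (delta > 0)
    out = pd.DataFrame({
        "item_id": df.loc[keep, "question_id"],
        "delta": delta[keep],
        "successes_before": s_before[keep].astype(int),
        "failures_before": f_before[keep].astype(int),
        "recall": df.loc[keep, "recall"].astype(int),
    }).reset_index(drop=True)
    return out


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = [(o.item_id, o.delta, o.successes_before, o.failures_before, o.recall)
            for o in observations]
    return pd.DataFrame(rows, columns=["item_id", "delta", "successes_before",
                                       "failures_before", "recall"])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Configuration of the half-life-regression fit.

    l2 penalizes deviations of log n0 from a shared prior mean and the
    magnitudes of alpha and beta; tol is the optimizer's objective
    tolerance.  mu0 (prior mean of log n0) defaults to the log of the
    method-of-moments global median initial rate.
    """

    l2: float = 1e-2
    tol: float = 1e-8
    maxiter: int = 1000
    alpha_init: float = 0.1
    beta_init: float = 0.1
    mu0: float | None = None
    eps: float = 0.01          # clipping for method-of-moments initialization
    n0_bounds: tuple[float, float] = (1e-5, 1e3)


def _moments_init(obs: pd.DataFrame, items: np.ndarray, eps: float) -> np.ndarray:
    """Per-item method-of-moments initial rates from first-interval outcomes."""
    first = obs[obs["successes_before"] + obs["failures_before"] <= 1]
    init = {}
    for item, sub in first.groupby("item_id"):
        p = float(np.clip(sub["recall"].mean(), eps, 1 - eps))
        dbar = float(sub["delta"].mean())
        init[item] = -np.log(p) / max(dbar, 1e-6)
    fallback = float(np.median(list(init.values()))) if init else 0.1
    return np.array([np.clip(init.get(i, fallback), 1e-4, 50.0) for i in items])


def _warn_weak_items(obs: pd.DataFrame) -> None:
    g = obs.groupby("item_id").agg(n_out=("recall", "nunique"),
                                   n_delta=("delta", "nunique"))
    weak = g[(g["n_out"] == 1) & (g["n_delta"] == 1)].index.tolist()
    if weak:
        warnings.warn(
            f"{len(weak)} item(s) have a single distinct delta and all-identical "
            f"outcomes; their rates are weakly identified (e.g. {weak[:3]})",
            WeakIdentificationWarning, stacklevel=3)


def fit_hlr(observations, config: FitConfig | None = None) -> HLRParams:
    """Fit initial rates and update multipliers by penalized least squares.

    Minimizes ``sum (recall - exp(-n*delta))**2`` plus an L2 penalty on
    (log n0 - mu0), alpha and beta, over (log n0 per item, logit(alpha),
    log(1+beta)) with L-BFGS-B and analytic gradients.  Deterministic: the
    initialization is a method-of-moments statistic of the data.
    """
    config = config or FitConfig()
    obs = _as_frame(observations)
    if not len(obs):
        raise ValueError("no observations to fit")
    if (obs["delta"] <= 0).any():
        raise ValueError("all observation deltas must be positive")
    _warn_weak_items(obs)

    items = np.array(sorted(obs["item_id"].unique()))
    item_ix = {it: k for k, it in enumerate(items)}
    n_items = len(items)

    ix = obs["item_id"].map(item_ix).to_numpy()
    delta = obs["delta"].to_numpy(float)
    s = obs["successes_before"].to_numpy(float)
    f = obs["failures_before"].to_numpy(float)
    r = obs["recall"].to_numpy(float)

    n0_init = _moments_init(obs, items, config.eps)
    mu0 = config.mu0 if config.mu0 is not None else float(np.log(np.median(n0_init)))
    l2 = config.l2

    lo, hi = np.log(config.n0_bounds[0]), np.log(config.n0_bounds[1])
    x0 = np.concatenate([np.clip(np.log(n0_init), lo, hi),
                         [logit(config.alpha_init)],
                         [np.log1p(config.beta_init)]])
    bounds = [(lo, hi)] * n_items + [(-12.0, 12.0), (0.0, 8.0)]

    def objective(x):
        log_n0 = x[:n_items]
        a, b = x[n_items], x[n_items + 1]
        alpha = expit(a)
        one_plus_beta = np.exp(b)
        beta = one_plus_beta - 1.0
        # rate per observation and model recall probability; cap log n so
        # exp cannot overflow on long failure streaks (m is exactly 0 there
        # and the gradient contribution vanishes either way)
        log_n = log_n0[ix] + s * np.log1p(-alpha) + f * b
        log_n = np.minimum(log_n, 46.0)
        n = np.exp(log_n)
        m = np.exp(-n * delta)
        e = r - m
        loss = float(e @ e)
        pen = l2 * (float(np.sum((log_n0 - mu0) ** 2)) + alpha ** 2 + beta ** 2)
        # gradient
        dl_dn = 2.0 * e * delta * m          # d(loss)/dn per observation
        dl_dlogn = dl_dn * n
        g_logn0 = np.bincount(ix, weights=dl_dlogn, minlength=n_items)
        g_logn0 += 2.0 * l2 * (log_n0 - mu0)
        # d log n/d a = -s * alpha  (since d log(1-alpha)/da = -alpha)
        g_a = float(np.sum(dl_dlogn * (-s) * alpha))
        g_a += 2.0 * l2 * alpha * alpha * (1.0 - alpha)
        # d log n/d b = f
        g_b = float(np.sum(dl_dlogn * f))
        g_b += 2.0 * l2 * beta * one_plus_beta
        return loss + pen, np.concatenate([g_logn0, [g_a], [g_b]])

    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.maxiter, "ftol": config.tol,
                            "gtol": 1e-10})
    x = res.x
    n0 = {it: float(np.exp(x[k])) for k, it in enumerate(items)}
    return HLRParams(n0=n0, alpha=float(expit(x[n_items])),
                     beta=float(np.expm1(x[n_items + 1])), l2=l2)


def fit_initial_rates(observations, method: str = "fitted",
                      epsilon: float = 0.01) -> dict[str, float]:
    """Estimate per-item initial-difficulty rates from first-interval data.

    Uses only observations whose preceding history is exactly one review
    (the interval between an item's first and second review), so the
    estimate reflects initial difficulty rather than accumulated practice.

    method="fitted": per-item least squares of recall against exp(-n0*delta)
    (1-D problems, solved independently).  method="empirical": the
    method-of-moments statistic -log(clip(mean recall)) / (mean delta).
    """
    obs = _as_frame(observations)
    first = obs[obs["successes_before"] + obs["failures_before"] <= 1]
    if not len(first):
        raise ValueError("no first-interval observations")
    out: dict[str, float] = {}
    if method == "empirical":
        for item, sub in first.groupby("item_id"):
            p = float(np.clip(sub["recall"].mean(), epsilon, 1 - epsilon))
            out[item] = -np.log(p) / float(sub["delta"].mean())
        return out
    if method != "fitted":
        raise ValueError(f"unknown method {method!r}")
    log_grid = np.linspace(np.log(1e-4), np.log(50.0), 400)
    grid = np.exp(log_grid)
    for item, sub in first.groupby("item_id"):
        d = sub["delta"].to_numpy(float)
        r = sub["recall"].to_numpy(float)
        sse = np.square(r[None, :] - np.exp(-grid[:, None] * d[None, :])).sum(axis=1)
        k = int(np.argmin(sse))
        # refine around the best grid point
        loglo = log_grid[max(k - 1, 0)]
        loghi = log_grid[min(k + 1, len(grid) - 1)]
        fine = np.exp(np.linspace(loglo, loghi, 200))
        sse = np.square(r[None, :] - np.exp(-fine[:, None] * d[None, :])).sum(axis=1)
        out[item] = float(fine[int(np.argmin(sse))])
    return out
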