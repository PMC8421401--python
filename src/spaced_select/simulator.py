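"""In-silico randomized trial of item-selection policies.

Generates review logs with the statistical structure the analysis assumes,
with ground truth known: heterogeneous item difficulties (log-normal initial
forgetting rates), per-learner session arrivals from a homogeneous Poisson
process, geometric session sizes, binary recalls drawn from the exponential
forgetting curve, multiplicative rate updates, random assignment to one of
three policy arms, and geometric per-day dropout.

The scheduler can run in "oracle" mode (policies see the true rates — the
deployed app used pre-fitted parameters, and oracle mode isolates the value
of the policy from estimation error) or "estimated" mode (parameters refit
periodically on the accumulated log).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .core_io import COLUMNS, IntegrityError, ReviewLog, SECONDS_PER_DAY
from .memory_model import FitConfig, HLRParams, fit_hlr, observations_from_log

__all__ = ["PopulationConfig", "GroundTruth", "simulate_trial", "assign_arms",
           "replay_log"]

ARM_NAMES = ("select", "difficulty", "random")


@dataclass
class PopulationConfig:
    """Study conditions of the simulated trial.

    Defaults emulate an intensive exam-preparation population: a couple of
    study sessions per day of ~15 questions over a 100-item bank, initial
    half-lives around a week (log-normal rates), and a small constant daily
    risk of abandoning the app.
    """

    n_learners: int = 1500
    n_items: int = 100
    arm_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n0_median: float = float(np.log(2) / 7)   # 1/day; initial half-life ~1 week
    n0_sigma: float = 0.6                     # log-scale spread of difficulty
    true_alpha: float = 0.3
    true_beta: float = 0.6
    session_rate: float = 2.0                 # sessions/day (Poisson intensity)
    session_size_mean: float = 15.0           # geometric, support >= 1
    horizon_days: float = 60.0
    dropout_hazard: float = 0.02              # per-day prob. of leaving for good
    first_exposure_mode: str = "reference"    # or "always_incorrect"
    first_exposure_delta: float = 1.0         # reference interval Delta0 (days)
    q: float = 1.0
    scheduler_mode: str = "oracle"            # or "estimated"
    refit_every: int = 2000                   # sessions between refits (estimated)
    policy_map: dict | None = None            # arm label -> policy actually run
    seed: int = 0

    def validate(self) -> None:
        bad = []
        p = np.asarray(self.arm_probabilities, float)
        if len(p) != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            bad.append("arm_probabilities")
        if self.n_learners < 1:
            bad.append("n_learners")
        if self.n_items < 1:
            bad.append("n_items")
        for name in ("n0_median", "n0_sigma", "session_size_mean",
                     "horizon_days", "first_exposure_delta"):
            if getattr(self, name) <= 0:
                bad.append(name)
        if self.session_rate < 0:
            bad.append("session_rate")
        if not 0 <= self.true_alpha < 1:
            bad.append("true_alpha")
        if self.true_beta < 0:
            bad.append("true_beta")
        if not 0 <= self.dropout_hazard < 1:
            bad.append("dropout_hazard")
        if self.q < 1:
            bad.append("q")
        if self.first_exposure_mode not in ("reference", "always_incorrect"):
            bad.append("first_exposure_mode")
        if self.scheduler_mode not in ("oracle", "estimated"):
            bad.append("scheduler_mode")
        if self.policy_map is not None and any(
                v not in ARM_NAMES for v in self.policy_map.values()):
            bad.append("policy_map")
        if bad:
            raise ValueError(f"invalid configuration field(s): {', '.join(bad)}")


@dataclass
class GroundTruth:
    """Everything the generator knew: parameters, assignment, trajectories.

    ``trajectories`` has one row per log event (same order as the log):
    the event time in days exactly as used during generation, the recall
    probability ``m`` the outcome was drawn from, and the forgetting rate
    before/after the update.
    """

    n0: dict[str, float]
    alpha: float
    beta: float
    arms: dict[str, str]
    first_exposure_mode: str
    first_exposure_delta: float
    trajectories: pd.DataFrame
    config: PopulationConfig | None = None

    def params(self) -> HLRParams:
        return HLRParams(n0=dict(self.n0), alpha=self.alpha, beta=self.beta)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=tuple(key)))


def assign_arms(n_learners: int, probabilities, seed: int) -> np.ndarray:
    """i.i.d. categorical arm assignment, fixed per learner for the horizon."""
    p = np.asarray(probabilities, float)
    if p.ndim != 1 or len(p) != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("probabilities must be a 3-vector summing to 1")
    rng = _rng(seed, 1)
    return np.array(ARM_NAMES)[rng.choice(3, size=n_learners, p=p)]


def _rank_select(n_sched, last, now, n0_rank, id_rank, q):
    """Vectorized select ranking: unseen (easiest first), then descending p*."""
    seen = ~np.isnan(last)
    m = np.ones_like(n_sched)
    delta = np.where(seen, now - last, 0.0)
    m[seen] = np.exp(-n_sched[seen] * delta[seen])
    p = (1.0 - m) / np.sqrt(q)
    secondary = np.where(seen, -p, n0_rank.astype(float))
    return np.lexsort((id_rank, secondary, seen.astype(int)))


def simulate_trial(config: PopulationConfig,
                   arrival_sampler: Callable | None = None
                   ) -> tuple[ReviewLog, GroundTruth]:
    """Run the randomized trial and return the log plus its ground truth.

    ``arrival_sampler(rng, config) -> array of session times (days)`` can
    replace the homogeneous Poisson arrivals (e.g. for time-of-day or
    burst patterns); the default draws Poisson-many uniform times on the
    horizon.
    """
    config.validate()
    seed = config.seed
    n_items = config.n_items
    width = max(4, len(str(n_items)))
    items = np.array([f"q{i:0{width}d}" for i in range(n_items)])
    lwidth = max(4, len(str(config.n_learners)))

    item_rng = _rng(seed, 0)
    n0_true = config.n0_median * np.exp(config.n0_sigma
                                        * item_rng.standard_normal(n_items))
    arms = assign_arms(config.n_learners, config.arm_probabilities, seed)
    policy_map = config.policy_map or {}

    id_rank = np.arange(n_items)          # items are lexicographically ordered
    true_order = np.lexsort((id_rank, n0_true))      # easiest first
    true_n0_rank = np.empty(n_items, int)
    true_n0_rank[true_order] = np.arange(n_items)

    # --- per-learner setup -------------------------------------------------
    learners = np.array([f"u{i:0{lwidth}d}" for i in range(config.n_learners)])
    sessions = []   # (time_days, learner_index, session_index, size)
    for lix in range(config.n_learners):
        arr_rng = _rng(seed, 2, lix, 0)
        if arrival_sampler is not None:
            times = np.sort(np.asarray(arrival_sampler(arr_rng, config), float))
        else:
            count = arr_rng.poisson(config.session_rate * config.horizon_days)
            times = np.sort(arr_rng.uniform(0.0, config.horizon_days, count))
        if config.dropout_hazard > 0:
            cutoff = float(arr_rng.geometric(config.dropout_hazard))
            times = times[times < min(cutoff, config.horizon_days)]
        size_rng = _rng(seed, 2, lix, 1)
        for j, t in enumerate(times):
            size = int(size_rng.geometric(1.0 / config.session_size_mean))
            sessions.append((float(t), lix, j, size))
    sessions.sort()

    # --- mutable learner state ---------------------------------------------
    n_learn = config.n_learners
    n_true = np.tile(n0_true, (n_learn, 1))
    last = np.full((n_learn, n_items), np.nan)
    succ = np.zeros((n_learn, n_items), np.int32)
    fail = np.zeros((n_learn, n_items), np.int32)
    pointers = np.zeros(n_learn, int)
    recall_rngs = [None] * n_learn
    policy_rngs = [None] * n_learn

    estimated = config.scheduler_mode == "estimated"
    if estimated:
        # scheduler's belief before any data: flat prior rates
        sched_params = None
        prior_n0 = np.full(n_items, config.n0_median)
        n0_sched = prior_n0.copy()
        alpha_sched, beta_sched = 0.1, 0.1
        sched_order = np.lexsort((id_rank, n0_sched))
        sched_rank = np.empty(n_items, int)
        sched_rank[sched_order] = np.arange(n_items)

    rows_learner, rows_item, rows_session, rows_time = [], [], [], []
    rows_recall, rows_arm = [], []
    rows_m, rows_nb, rows_na, rows_tdays = [], [], [], []

    one_minus_a = 1.0 - config.true_alpha
    one_plus_b = 1.0 + config.true_beta
    m_first_ref = np.exp(-n0_true * config.first_exposure_delta) \
        if config.first_exposure_mode == "reference" else np.zeros(n_items)

    for s_count, (t, lix, j, size) in enumerate(sessions):
        arm = arms[lix]
        policy = policy_map.get(arm, arm)
        lid = learners[lix]

        if estimated and s_count > 0 and s_count % config.refit_every == 0 \
                and rows_learner:
            df = pd.DataFrame({"learner_id": rows_learner,
                               "question_id": rows_item,
                               "time_days": rows_tdays,
                               "recall": rows_recall})
            obs = _observations_from_frame(df)
            if len(obs) >= 10:
                sched_params = fit_hlr(obs, FitConfig())
                n0_sched = np.array([sched_params.n0.get(i, sched_params.n0_default)
                                     for i in items])
                alpha_sched, beta_sched = sched_params.alpha, sched_params.beta
                # unseen-first ordering tracks the refit; the difficulty
                # arm's cycle (sched_order) stays fixed once the trial starts
                sched_rank = np.empty(n_items, int)
                sched_rank[np.lexsort((id_rank, n0_sched))] = np.arange(n_items)

        if policy == "select":
            if estimated:
                n_belief = (n0_sched
                            * (1.0 - alpha_sched) ** succ[lix]
                            * (1.0 + beta_sched) ** fail[lix])
                order = _rank_select(n_belief, last[lix], t, sched_rank,
                                     id_rank, config.q)
            else:
                order = _rank_select(n_true[lix], last[lix], t, true_n0_rank,
                                     id_rank, config.q)
            chosen = order[:min(size, n_items)]
        elif policy == "difficulty":
            base_order = true_order if not estimated else sched_order
            k = min(size, n_items)
            ptr = pointers[lix]
            chosen = base_order[(ptr + np.arange(k)) % n_items]
            pointers[lix] = (ptr + k) % n_items
        else:  # random, with replacement
            if policy_rngs[lix] is None:
                policy_rngs[lix] = _rng(seed, 2, lix, 2)
            chosen = policy_rngs[lix].integers(0, n_items, size=size)

        if recall_rngs[lix] is None:
            recall_rngs[lix] = _rng(seed, 2, lix, 3)
        rr = recall_rngs[lix]
        sid = f"{lid}-s{j:04d}"
        draws = rr.random(len(chosen))
        for pos, ii in enumerate(chosen):
            if np.isnan(last[lix, ii]):
                m = float(m_first_ref[ii])
            else:
                m = float(np.exp(-n_true[lix, ii] * (t - last[lix, ii])))
            r = 1 if draws[pos] < m else 0
            nb = float(n_true[lix, ii])
            na = nb * one_minus_a if r else nb * one_plus_b
            n_true[lix, ii] = na
            last[lix, ii] = t
            if r:
                succ[lix, ii] += 1
            else:
                fail[lix, ii] += 1
            rows_learner.append(lid)
            rows_item.append(items[ii])
            rows_session.append(sid)
            rows_time.append(t * SECONDS_PER_DAY)
            rows_tdays.append(t)
            rows_recall.append(r)
            rows_arm.append(arm)
            rows_m.append(m)
            rows_nb.append(nb)
            rows_na.append(na)

    combined = pd.DataFrame({
        "learner_id": rows_learner, "question_id": rows_item,
        "session_id": rows_session, "time": rows_time,
        "recall": np.array(rows_recall, np.int8), "arm": rows_arm,
        "t_days": rows_tdays, "m": rows_m,
        "n_before": rows_nb, "n_after": rows_na,
    })
    combined = combined.sort_values(["learner_id", "time", "question_id"],
                                    kind="stable").reset_index(drop=True)
    log = ReviewLog(combined[COLUMNS], metadata={"generator": "simulate_trial",
                                                 "seed": seed})
    truth = GroundTruth(
        n0={it: float(v) for it, v in zip(items, n0_true)},
        alpha=config.true_alpha, beta=config.true_beta,
        arms={lid: arm for lid, arm in zip(learners, arms)},
        first_exposure_mode=config.first_exposure_mode,
        first_exposure_delta=config.first_exposure_delta,
        trajectories=combined[["learner_id", "question_id", "t_days",
                               "m", "n_before", "n_after", "recall"]].copy(),
        config=config,
    )
    return log, truth


def _observations_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """observations_from_log on a bare (chronological) event frame."""
    tcol = "time_days" if "time_days" in df.columns else "t_days"
    grp = df.groupby(["learner_id", "question_id"], sort=False)
    delta = df[tcol] - grp[tcol].shift()
    s_before = grp["recall"].cumsum() - df["recall"]
    f_before = grp.cumcount() - s_before
    keep = delta.notna() & (delta > 0)
    return pd.DataFrame({
        "item_id": df.loc[keep, "question_id"],
        "delta": delta[keep],
        "successes_before": s_before[keep].astype(int),
        "failures_before": f_before[keep].astype(int),
        "recall": df.loc[keep, "recall"].astype(int),
    }).reset_index(drop=True)


def replay_log(log: ReviewLog, truth: GroundTruth,
               time_tol: float = 1e-9) -> dict:
    """Verify that a simulated log is consistent with its ground truth.

    Re-derives every recall probability and rate update from the truth's
    parameters, the stored event times and the log's recall bits, and
    compares against the stored trajectories bit-for-bit.  A single flipped
    recall changes the rate trajectory and is reported with the first
    divergent event.
    """
    df = log.events
    traj = truth.trajectories
    if len(df) != len(traj):
        raise IntegrityError(f"log has {len(df)} events, truth has {len(traj)}")
    if len(df) == 0:
        return {"events_checked": 0, "pairs_checked": 0}
    same_key = ((df["learner_id"].to_numpy() == traj["learner_id"].to_numpy())
                & (df["question_id"].to_numpy() == traj["question_id"].to_numpy()))
    if not same_key.all():
        k = int(np.flatnonzero(~same_key)[0])
        raise IntegrityError(f"event {k}: log/truth key mismatch")
    if np.max(np.abs(df["time_days"].to_numpy()
                     - traj["t_days"].to_numpy())) > time_tol:
        raise IntegrityError("log event times diverge from truth trajectories")

    recalls = df["recall"].to_numpy()
    t_days = traj["t_days"].to_numpy()
    one_minus_a, one_plus_b = 1.0 - truth.alpha, 1.0 + truth.beta
    m_exp = traj["m"].to_numpy()
    na_exp = traj["n_after"].to_numpy()

    state_n: dict = {}
    state_last: dict = {}
    pairs = list(zip(df["learner_id"], df["question_id"]))
    for k, key in enumerate(pairs):
        if key not in state_n:
            n = truth.n0[key[1]]
            if truth.first_exposure_mode == "reference":
                m = float(np.exp(-n * truth.first_exposure_delta))
            else:
                m = 0.0
        else:
            n = state_n[key]
            m = float(np.exp(-n * (t_days[k] - state_last[key])))
        na = n * one_minus_a if recalls[k] else n * one_plus_b
        if m != m_exp[k] or na != na_exp[k]:
            raise IntegrityError(
                f"event {k} ({key[0]}, {key[1]} at day {t_days[k]:.4f}): "
                f"replayed (m={m}, n_after={na}) != stored "
                f"(m={m_exp[k]}, n_after={na_exp[k]})")
        state_n[key] = na
        state_last[key] = t_days[k]
    return {"events_checked": len(df), "pairs_checked": len(state_n)}
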