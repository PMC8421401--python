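"""Trial outcome statistics.

The primary outcome is the *normalized empirical forgetting rate* of each
(learner, question) reviewing sequence.  The chronologically last review of
a pair is treated as its test review; with ``delta`` the interval preceding
it and a small probability floor ``epsilon``, the empirical rate is

    n_hat = -log(1 - epsilon) / delta   if the test was recalled,
    n_hat = -log(epsilon) / delta       if it was forgotten,

i.e. the forgetting rate that would make the (floored) observed outcome
exactly as probable as the exponential curve predicts.  Dividing by the
item's initial-difficulty rate ``n0_hat`` makes values comparable across
items.  Sequences are then compared across arms inside cells that control
for the number of reviews and the total study period T (Mann-Whitney U
tests with Bonferroni correction), and a robust (Huber) regression of the
normalized rate on T and arm indicators quantifies the spacing effect and
the arm effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu as _scipy_mwu
from scipy.stats import rankdata

from .core_io import ReviewLog

__all__ = [
    "SequenceSummary", "ComparisonCell", "RegressionResult",
    "empirical_forgetting_rate", "half_life", "summarize_sequences",
    "bin_by_controls", "mann_whitney_u", "compare_arms", "fit_spacing_regression",
    "engagement_metrics", "evaluate_log",
]

LN2 = float(np.log(2.0))

SUMMARY_COLUMNS = ["learner_id", "question_id", "arm", "n_reviews", "T",
                   "delta_test", "test_recall", "n_hat", "n0_hat",
                   "normalized_rate", "half_life"]


# ---------------------------------------------------------------------------
# Per-sequence outcome
# ---------------------------------------------------------------------------

def empirical_forgetting_rate(delta_test, test_recall, epsilon: float = 0.01):
    """Empirical forgetting rate of a test review (vectorized)."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    delta = np.asarray(delta_test, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta_test must be positive")
    recall = np.asarray(test_recall)
    r_tilde = np.where(recall == 1, 1.0 - epsilon, epsilon)
    out = -np.log(r_tilde) / delta
    return float(out) if out.ndim == 0 else out


def half_life(n_hat):
    """Half-life in days of a forgetting rate: ln(2)/n."""
    n = np.asarray(n_hat, dtype=float)
    if np.any(n <= 0):
        raise ValueError("rate must be positive")
    out = LN2 / n
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SequenceSummary:
    """Evaluation record of one (learner, question) reviewing sequence."""

    learner_id: str
    question_id: str
    arm: str
    n_reviews: int       # reviews before the test review
    T: float             # days, first review -> test review
    delta_test: float    # days, interval preceding the test review
    test_recall: int
    n_hat: float
    n0_hat: float
    normalized_rate: float
    half_life: float


def summarize_sequences(log, n0_map: dict[str, float],
                        epsilon: float = 0.01) -> tuple[pd.DataFrame, int]:
    """Per-pair outcome summaries from a review log (or sequence map).

    The last distinct-time review of each pair is the test review.  Repeat
    presentations of an item at the same instant (a with-replacement draw
    landing twice in one session) are collapsed to the first outcome: an
    immediate repeat is not an informative memory test.  Pairs with fewer
    than two distinct-time reviews are excluded; their count is returned
    alongside the summary table.
    """
    if isinstance(log, ReviewLog):
        df = log.events
    elif isinstance(log, dict):
        if not log:
            df = pd.DataFrame(columns=["learner_id", "question_id",
                                       "time_days", "recall", "arm"])
        else:
            df = pd.concat(log.values(), ignore_index=True)
            df = df.sort_values(["learner_id", "time_days", "question_id"],
                                kind="stable")
    else:
        raise TypeError("expected a ReviewLog or a sequence map")
    if not len(df):
        return pd.DataFrame(columns=SUMMARY_COLUMNS), 0

    missing = set(df["question_id"]) - set(n0_map)
    if missing:
        raise KeyError(f"no initial-difficulty rate for item(s): "
                       f"{sorted(missing)[:5]}")

    df = df.drop_duplicates(subset=["learner_id", "question_id", "time_days"],
                            keep="first").copy()
    g0 = df.groupby(["learner_id", "question_id"], sort=True)
    # rows are time-ordered within a pair, so the last row's predecessor
    # time is the second-to-last review time
    df["prev_time"] = g0["time_days"].shift()
    g = df.groupby(["learner_id", "question_id"], sort=True)
    agg = g.agg(arm=("arm", "first"),
                n_total=("recall", "size"),
                t_first=("time_days", "min"),
                t_last=("time_days", "max"),
                test_recall=("recall", "last"),
                t_penult=("prev_time", "last"))

    n_excluded = int((agg["n_total"] < 2).sum())
    agg = agg[agg["n_total"] >= 2].reset_index()

    if not len(agg):
        return pd.DataFrame(columns=SUMMARY_COLUMNS), n_excluded
    delta_test = (agg["t_last"] - agg["t_penult"]).to_numpy()
    n_hat = empirical_forgetting_rate(delta_test,
                                      agg["test_recall"].to_numpy(), epsilon)
    n0_hat = agg["question_id"].map(n0_map).to_numpy(float)
    out = pd.DataFrame({
        "learner_id": agg["learner_id"],
        "question_id": agg["question_id"],
        "arm": agg["arm"],
        "n_reviews": (agg["n_total"] - 1).astype(int),
        "T": agg["t_last"] - agg["t_first"],
        "delta_test": delta_test,
        "test_recall": agg["test_recall"].astype(int),
        "n_hat": n_hat,
        "n0_hat": n0_hat,
        "normalized_rate": n_hat / n0_hat,
        "half_life": LN2 / n_hat,
    })
    return out, n_excluded


# ---------------------------------------------------------------------------
# Controlled comparison (cells by #reviews and T)
# ---------------------------------------------------------------------------

def bin_by_controls(summaries: pd.DataFrame,
                    n_reviews_range: tuple[int, int] = (2, 7),
                    n_T_bins: int = 3) -> pd.DataFrame:
    """Label summaries with control cells: exact #reviews x T-quantile bin.

    Within each #reviews stratum, T is cut at its empirical quantiles into
    ``n_T_bins`` bins.  With the default 2..7 reviews and terciles this
    yields up to 18 cells (36 pairwise arm contrasts).  Returns the
    restricted summary table with added ``t_bin``, ``t_lo``, ``t_hi``
    columns; every retained row belongs to exactly one cell.
    """
    if n_T_bins < 1:
        raise ValueError("n_T_bins must be >= 1")
    lo, hi = n_reviews_range
    sub = summaries[(summaries["n_reviews"] >= lo)
                    & (summaries["n_reviews"] <= hi)].copy()
    if not len(sub):
        sub["t_bin"] = pd.Series(dtype=int)
        sub["t_lo"] = sub["t_hi"] = pd.Series(dtype=float)
        return sub
    parts = []
    for k, grp in sub.groupby("n_reviews"):
        grp = grp.copy()
        if n_T_bins == 1 or grp["T"].nunique() < n_T_bins:
            grp["t_bin"] = 0
            grp["t_lo"] = grp["T"].min()
            grp["t_hi"] = grp["T"].max()
        else:
            binned = pd.qcut(grp["T"], n_T_bins, duplicates="drop")
            codes = binned.cat.codes
            grp["t_bin"] = codes
            edges = {c: (iv.left, iv.right)
                     for c, iv in zip(range(len(binned.cat.categories)),
                                      binned.cat.categories)}
            grp["t_lo"] = codes.map(lambda c: edges[c][0]).astype(float)
            grp["t_hi"] = codes.map(lambda c: edges[c][1]).astype(float)
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U of sample ``x`` against ``y`` with a two-sided p-value.

    Ties are handled with midranks.  For combined sample sizes <= 10 the
    p-value is exact (enumeration of all label assignments of the pooled
    values); larger samples use the normal approximation with tie-corrected
    variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= 10:
        center = n1 * n2 / 2.0
        d_obs = abs(u_obs - center)
        hits = total = 0
        base = n1 * (n1 + 1) / 2.0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - base
            total += 1
            if abs(u - center) >= d_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = _scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


@dataclass
class ComparisonCell:
    """Arm comparison inside one (n_reviews, T-bin) control cell."""

    n_reviews: int
    t_bin: int
    t_lo: float
    t_hi: float
    quantiles: dict            # arm -> (q25, median, q75) of normalized rate
    counts: dict               # arm -> sample size
    contrasts: dict            # "select_vs_<arm>" -> dict(U, p, significant)
    skipped: list = field(default_factory=list)


def compare_arms(labeled: pd.DataFrame, alpha_level: float = 0.05,
                 n_comparisons: int | None = None) -> dict:
    """Per-cell select-vs-baseline contrasts plus trial-level aggregates.

    Significance threshold is ``alpha_level / n_comparisons`` (Bonferroni);
    by default ``n_comparisons`` is twice the number of cells.  Aggregates:
    the fraction of contrasts where the select arm's median normalized rate
    is lowest, the fraction significant, and the median relative decrease in
    median normalized rate (and increase in median half-life) of the select
    arm against each baseline.
    """
    cell_keys = sorted(set(zip(labeled["n_reviews"], labeled["t_bin"])))
    if n_comparisons is None:
        n_comparisons = 2 * len(cell_keys)
    threshold = alpha_level / max(n_comparisons, 1)

    cells: list[ComparisonCell] = []
    lower = {"random": [], "difficulty": []}
    signif = {"random": [], "difficulty": []}
    rate_decrease = {"random": [], "difficulty": []}
    hl_increase = {"random": [], "difficulty": []}

    for k, b in cell_keys:
        sub = labeled[(labeled["n_reviews"] == k) & (labeled["t_bin"] == b)]
        quantiles, counts, contrasts, skipped = {}, {}, {}, []
        for arm, grp in sub.groupby("arm"):
            v = grp["normalized_rate"].to_numpy()
            quantiles[arm] = tuple(np.quantile(v, [0.25, 0.5, 0.75]))
            counts[arm] = len(v)
        sel = sub[sub["arm"] == "select"]["normalized_rate"].to_numpy()
        for other in ("random", "difficulty"):
            oth = sub[sub["arm"] == other]["normalized_rate"].to_numpy()
            if len(sel) == 0 or len(oth) == 0:
                skipped.append(f"select_vs_{other}")
                continue
            u, p = mann_whitney_u(sel, oth)
            sig = bool(p < threshold)
            contrasts[f"select_vs_{other}"] = {"U": u, "p": p,
                                               "significant": sig}
            med_s, med_o = float(np.median(sel)), float(np.median(oth))
            lower[other].append(med_s < med_o)
            signif[other].append(sig and med_s < med_o)
            if med_o > 0:
                rate_decrease[other].append((med_o - med_s) / med_o)
            hls = float(np.median(LN2 / sub[sub["arm"] == "select"]["n_hat"]))
            hlo = float(np.median(LN2 / sub[sub["arm"] == other]["n_hat"]))
            if hlo > 0:
                hl_increase[other].append(hls / hlo - 1.0)
        cells.append(ComparisonCell(int(k), int(b),
                                    float(sub["t_lo"].iloc[0]),
                                    float(sub["t_hi"].iloc[0]),
                                    quantiles, counts, contrasts, skipped))

    all_lower = lower["random"] + lower["difficulty"]
    all_sig = signif["random"] + signif["difficulty"]
    agg = {
        "n_cells": len(cell_keys),
        "n_comparisons": n_comparisons,
        "bonferroni_threshold": threshold,
        "frac_select_median_lowest": float(np.mean(all_lower)) if all_lower else np.nan,
        "frac_significant": float(np.mean(all_sig)) if all_sig else np.nan,
        "median_rate_decrease_vs_random":
            float(np.median(rate_decrease["random"])) if rate_decrease["random"] else np.nan,
        "median_rate_decrease_vs_difficulty":
            float(np.median(rate_decrease["difficulty"])) if rate_decrease["difficulty"] else np.nan,
        "median_half_life_increase_vs_random":
            float(np.median(hl_increase["random"])) if hl_increase["random"] else np.nan,
        "median_half_life_increase_vs_difficulty":
            float(np.median(hl_increase["difficulty"])) if hl_increase["difficulty"] else np.nan,
    }
    return {"cells": cells, "aggregates": agg}


# ---------------------------------------------------------------------------
# Spacing-effect regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Huber regression of normalized rate on arm and study period T."""

    n_reviews: int
    c: float
    w_T: float
    w_random: float
    w_difficulty: float
    T_median: float
    huber_t: float
    scale: float
    n_obs: int

    def to_dict(self) -> dict:
        return asdict(self)


def fit_spacing_regression(summaries: pd.DataFrame, n_reviews: int,
            huber_t: float = 1.345, tol: float = 1e-10,
            maxiter: int = 500) -> RegressionResult:
    """Fit normalized_rate ~ c + w_T (T - T_median) + arm indicators.

    The select arm is the reference level.  Coefficients are the Huber
    M-estimate with threshold ``huber_t``: iteratively reweighted least
    squares with the residual scale re-estimated each iteration by the
    median absolute deviation.  At convergence the coefficients minimize
    the Huber objective at the final scale (reported as ``scale``).  On
    exactly-interpolable data the least-squares solution is returned as-is.
    """
    sub = summaries[summaries["n_reviews"] == n_reviews]
    if len(sub) < 10:
        raise ValueError(f"need >= 10 summaries for n_reviews={n_reviews}, "
                         f"got {len(sub)}")
    present = set(sub["arm"])
    for arm in ("select", "random", "difficulty"):
        if arm not in present:
            raise ValueError(f"design is rank deficient: arm {arm!r} has no "
                             f"data for n_reviews={n_reviews}")
    t_median = float(sub["T"].median())
    y = sub["normalized_rate"].to_numpy(float)
    X = np.column_stack([
        np.ones(len(sub)),
        sub["T"].to_numpy(float) - t_median,
        (sub["arm"] == "random").to_numpy(float),
        (sub["arm"] == "difficulty").to_numpy(float),
    ])
    ols = sm.OLS(y, X).fit()
    resid = y - X @ ols.params
    scale = float(sm.robust.scale.mad(resid, c=0.6744897501960817, center=0.0))
    if scale <= 1e-12 * (1.0 + float(np.median(np.abs(y)))):
        params, scale = ols.params, max(scale, 0.0)
    else:
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_t))
        fit = rlm.fit(maxiter=maxiter, tol=tol, conv="coefs",
                      scale_est="mad")
        params, scale = fit.params, float(fit.scale)
    return RegressionResult(
        n_reviews=int(n_reviews), c=float(params[0]), w_T=float(params[1]),
        w_random=float(params[2]), w_difficulty=float(params[3]),
        T_median=t_median, huber_t=huber_t, scale=scale, n_obs=len(sub))


# ---------------------------------------------------------------------------
# Engagement
# ---------------------------------------------------------------------------

def engagement_metrics(log: ReviewLog, return_window: tuple[float, float] = (4.0, 7.0),
                       early_days: float = 2.0) -> dict:
    """Per-arm engagement: 4-7 day return fraction and early-stop fraction.

    A learner "returns" if some session starts within ``return_window`` days
    after their first session; a learner is an early stopper if their last
    session is within ``early_days`` of their first.  Relative differences
    against the random arm are reported for both fractions.
    """
    df = log.events
    out: dict = {"per_arm": {}, "relative_to_random": {}}
    if not len(df):
        return out
    sess = (df.drop_duplicates(subset=["learner_id", "session_id"])
            [["learner_id", "arm", "time_days"]])
    lo, hi = return_window
    for arm, grp in sess.groupby("arm"):
        returned, stopped, total = 0, 0, 0
        for _, times in grp.groupby("learner_id")["time_days"]:
            t = times.to_numpy()
            t0 = t.min()
            total += 1
            rel = t - t0
            if np.any((rel >= lo) & (rel <= hi)):
                returned += 1
            if rel.max() <= early_days:
                stopped += 1
        out["per_arm"][arm] = {
            "n_learners": total,
            "return_4_7_frac": returned / total,
            "early_stop_frac": stopped / total,
        }
    base = out["per_arm"].get("random")
    if base:
        for arm in out["per_arm"]:
            if arm == "random":
                continue
            rel = {}
            for key in ("return_4_7_frac", "early_stop_frac"):
                b = base[key]
                rel[key] = (out["per_arm"][arm][key] - b) / b if b > 0 else np.nan
            out["relative_to_random"][arm] = rel
    return out


# ---------------------------------------------------------------------------
# One-call evaluation
# ---------------------------------------------------------------------------

def evaluate_log(log: ReviewLog, n0_map: dict[str, float],
                 epsilon: float = 0.01,
                 n_reviews_range: tuple[int, int] = (2, 7),
                 n_T_bins: int = 3, alpha_level: float = 0.05) -> dict:
    """Full evaluation: summaries -> cells -> contrasts -> regressions."""
    summaries, n_excluded = summarize_sequences(log, n0_map, epsilon)
    labeled = bin_by_controls(summaries, n_reviews_range, n_T_bins)
    comparison = compare_arms(labeled, alpha_level)
    regressions = {}
    for k in range(n_reviews_range[0], n_reviews_range[1] + 1):
        try:
            regressions[k] = fit_spacing_regression(summaries, k)
        except ValueError:
            continue
    return {
        "epsilon": epsilon,
        "n_summaries": len(summaries),
        "n_excluded_single_review": n_excluded,
        "summaries": summaries,
        "cells": comparison["cells"],
        "aggregates": comparison["aggregates"],
        "regressions": regressions,
        "engagement": engagement_metrics(log),
    }
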