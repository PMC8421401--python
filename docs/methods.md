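# Methods

## Memory model

Each (learner, item) pair carries a forgetting rate `n > 0` (1/day).  The
probability of recalling the item after an interval `Δ` days since its last
review is the exponential forgetting curve `m = exp(-n·Δ)`.  A review is
always a test; its binary outcome updates the rate multiplicatively,
`n ← n(1-α)` on success and `n ← n(1+β)` on failure, so the rate before a
review is the closed form `n0 (1-α)^s (1+β)^f` given the item's initial
rate `n0` and the pair's past success/failure counts.  The model assumes
memoryless exponential decay between reviews, item-level (not
learner-level) initial difficulty, and globally shared multipliers; it does
not model item similarity, learner ability, or any benefit of spacing
beyond what the update rule induces.

**Fitting (`fit_hlr`).**  The first review of a pair has no preceding
interval and yields no observation; every later review at interval `Δ > 0`
contributes a squared-error term `(r - exp(-n·Δ))²`.  Same-instant repeats
(an item drawn twice into one session) update the counts but are not
observations.  The penalized risk adds `l2·(Σ(log n0_i - μ0)² + α² + β²)`,
with `μ0` the log of the method-of-moments global median rate, and is
minimized by L-BFGS-B with analytic gradients over `(log n0 per item,
logit α, log(1+β))`, which keeps every invariant (`n0 > 0`, `α ∈ [0,1)`,
`β ≥ 0`) by construction.  Defaults: `l2 = 0.01` (weak: data dominate at
realistic sample sizes while degenerate items stay anchored to the prior),
objective tolerance 1e-8, initialization α = β = 0.1 and per-item
method-of-moments rates from first-interval outcomes.  `log n` is capped at
46 inside the objective so that long failure streaks cannot overflow `exp`;
the recall probability there is exactly 0 either way.  Items whose
observations carry a single distinct interval and all-identical outcomes
are reported with a `WeakIdentificationWarning`.  Items never reviewed by
anyone fall back to the global median `n0` for scheduling.

## Policies

* **select** — rank items by the optimal inclusion probability
  `p* = (1-m)/√q` (descending), ties by item id; items never yet reviewed
  come first, easiest first.  Deployed behaviour is this deterministic
  ranking truncated at the learner-chosen session size; Bernoulli sampling
  by `p*` is available as an option (`sample_items_select`).  `q` defaults
  to 1 — the ranking, and hence every downstream result, is invariant to it.
* **difficulty** — a fixed circular sweep through the item universe sorted
  ascending by initial rate (easiest first).  "Circular order proportionally
  to the initial difficulty" could also be read as frequency weighting; the
  plain sorted cycle is implemented as it matches "easier questions first".
* **random** — uniform draws with replacement from the item universe, one
  independent seeded stream per learner.

## Trial simulator

One simulated learner: an arm drawn once from the assignment probabilities;
session times from a homogeneous Poisson process (intensity
`session_rate`/day) truncated at the horizon and at a geometric per-day
dropout time; geometric session sizes (support ≥ 1).  At each session the
arm's policy picks the items; each reviewed item's recall is drawn from the
true forgetting curve and the true rate is updated multiplicatively.  The
first-ever exposure of an item has no preceding interval, so its outcome is
drawn against the item's initial rate at a fixed reference interval
`Δ0 = 1` day — driving-theory content is partly known beforehand, and this
gives easy items a realistic head start (an "always incorrect" mode
exists).  All randomness fans out from one root seed through named
substreams (items, assignment, then per learner: arrivals, sizes, policy,
recalls), so components can be varied independently and runs are bit-for-bit
reproducible.  A `GroundTruth` record stores the generating parameters and
the full per-event (m, n) trajectory; `replay_log` re-derives every
probability from the stored parameters plus the log's recall bits and
confirms the trajectories bit-for-bit (event times are generated in days
and stored in the log in seconds, so replay takes the day-valued times from
the ground truth and checks the log's times against them to 1e-9 days).

By default the scheduler sees the true rates ("oracle" mode), isolating the
value of the policy from estimation error; "estimated" mode reschedules
from parameters refit on the accumulated log every `refit_every` sessions,
with a flat prior before the first refit.  The difficulty arm's cycle order
is fixed at trial start and not re-sorted after refits.

**Default study conditions.**  1500 learners over 100 items for 60 days,
assignment probabilities (⅓, ⅓, ⅓), α = 0.3, β = 0.6, initial rates
log-normal with median ln2/7 (a one-week initial half-life, log-sd 0.6),
2 sessions/day of geometric-mean size 15, dropout hazard 0.02/day, q = 1.
These emulate an intensive exam-preparation population — short daily
sessions over a moderately easy question bank with a realistic share of
early quitters; realized face validity at the defaults: overall recall
accuracy ≈ 86%, rates shrink with practice.  What the simulator does *not*
emulate: real spacing benefits beyond the update rule, item content and
similarity, time-of-day session patterns, learner-level ability, reinstalls
or multi-device usage (the arm-switch filter is exercised on purpose-built
fixtures instead).  Passing tests therefore show that the pipeline detects
the policy's effect when the model's own world is true, not that the model
is true of people.

Note a load dependence worth knowing when changing conditions: the select
arm's advantage appears when the item bank is large relative to the review
budget (as in a real ~2000-question bank).  If the budget saturates the
bank (e.g. 50 items at 30 reviews/day) all policies revisit everything
quickly and the arms converge.

## Preprocessing

Learners observed under more than one arm label (re-randomized after a
reinstall) are removed entirely; learners with less than 2 days of usage
are removed, where usage is the first-to-last event span in days with an
inclusive boundary (span exactly 2.0 is kept) — "distinct active calendar
days" is available as an option since either reading is defensible.  Review
logs store `time` in epoch seconds verbatim (so write→read round-trips are
exact) and carry a derived `time_days` column, computed once at
construction, that all analysis uses.

## Evaluation

The last distinct-time review of each pair is its test.  With `ε = 0.01`
(exposed in configuration; results should be reported alongside it), the
empirical forgetting rate is `-ln(1-ε)/Δ` on recall and `-ln(ε)/Δ` on
forgetting, normalized by the item's initial-difficulty rate `n̂0`.  `n̂0`
defaults to a per-item least-squares fit of `exp(-n0·Δ)` on first-interval
observations only (the interval between a pair's first and second review),
so accumulated practice does not contaminate the normalizer; a
method-of-moments "empirical" estimator is available as the alternative.

Controlled cells stratify on the exact number of pre-test reviews (2–7 by
default) crossed with terciles of the study period T within each stratum —
up to 18 cells and 36 select-vs-baseline contrasts, hence the Bonferroni
threshold 0.05/36.  The tercile boundaries are a package choice; other
"approximately equal T" binnings are possible.  Contrasts use the
Mann-Whitney U test with midrank tie handling: exact enumeration of label
assignments for combined samples of ≤ 10, the tie-corrected normal
approximation (scipy) otherwise.

The spacing regression per stratum,
`n̂/n̂0 = c + w_T(T - T_median) + w_random·I_random + w_difficulty·I_difficulty`,
uses the Huber M-estimator (threshold 1.345, IRLS with MAD-estimated scale
re-estimated each iteration, coefficient-change tolerance 1e-10; select is
the reference arm).  Re-estimating the scale each iteration matters: the
forgotten-test branch of the empirical rate is ~460× the recalled branch,
and a scale frozen at the initial least-squares residual MAD is inflated
enough to stop downweighting those points.  At convergence the coefficients
minimize the Huber objective at the reported final scale, which is how the
oracle test checks them.  Exactly-interpolable data short-circuit to the
least-squares solution (the MAD scale would be 0).

Engagement: per arm, the fraction of learners with a session starting 4–7
days (inclusive) after their first, and the fraction whose last session is
within 2 days of their first.

## Numerical and degenerate-input choices

* Ties in event order (same learner, time, question) keep stable input
  order; item ties in rankings break by ascending item id.
* `filter_*` operations are idempotent and return removal counts.
* Sequences with a single review are excluded from summaries and counted.
* Cells missing an arm skip (and flag) the affected contrast;
  regression strata missing an arm raise a rank-deficiency error naming it.
* `select_probability` clips to [0, 1]; `q < 1` is a domain error.
* Empty logs flow through every operation as empty results.

## Known limitations

* The memory model has no covariates beyond counts and item intercepts
  (no lexical features, no learner intercepts).
* The simulator's oracle mode bounds the policy's value from above;
  estimated mode with frequent refits is substantially slower.
* The exact-enumeration Mann-Whitney path is combinatorial and restricted
  to combined n ≤ 10 by design.
* Engagement differences across arms are only produced by the simulator if
  arm-dependent dropout is configured; the default is arm-independent.
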