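# Methods

## Engagement model

A thread is a rooted tree of posts; the *subthread* of a post is the
unique path from the thread root to that post.  When a new post responds
to post *p*, the forum's engagement value increases by one unit and the
unit is divided among the authors of *p*'s subthread:

* the post at distance *d* above *p* (with *d* = 0 for *p* itself)
  carries raw weight α^d;
* a user appearing several times keeps the weights of their K most
  recent appearances (K = ∞ by default — thread depth bounds appearances
  in practice);
* retained weights are normalised so the shares sum to exactly 1.

Credited user *u* books the share both to their capacity C(u) and to the
directed pair T(u, r) where *r* is the responder; *u* = *r* is allowed
(self-engagement).  Two invariants follow by construction and are
asserted at 1e-9 absolute tolerance throughout: Σ_u C(u) equals the total
engagement value, and Σ_r T(u, r) = C(u).

This operational, per-event formulation is the package's realisation of
the underlying cooperative-game credit assignment on coalitions of player
appearances.  It reproduces the behaviours that pin the formula down:
equal credit at α = 1; predecessors of the responded-to post discounted
by α, α², α³, …; the share of the newest four contributors of a very long
thread tending to 1 − α⁴ (0.5904 at the default α = 0.8, i.e. "about
half"); and exact conservation of each unit.  Because each response
touches only its own subthread, the ledger updates incrementally and the
total cost is O(posts × depth) — linear in posts for bounded depth, which
the runtime-scaling test verifies empirically (log–log slope ≈ 1 across
1k–32k posts).

A second, independent computation route — explicit enumeration of every
responded-to subthread over the thread's reply tree, built with networkx
shortest paths — serves as the validation oracle; engine and oracle must
agree entry-wise to 1e-9, and do so on hundreds of random forums in the
suite.

Open modelling point: the claim that a thread's originator always
accumulates the most credit in their thread is not a theorem under this
event rule (a mid-thread post with many direct replies can overtake the
root), so it is exposed as a diagnostic (`originator_dominance`), not
asserted.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | geometric discount per step up-thread | 0.8 | the value used throughout the reference analyses; concentrates ~59% of each unit on the last 4 contributors |
| K | max counted appearances per user per subthread | unbounded | the formula admits a cap; depth bounds it naturally |
| delurk gap | silence qualifying a post as delurking | 30 days | "at least a month", made exact and configurable |
| week | activity/capacity window | 7 days, anchored at first post | deterministic, timezone-free |
| Granger lag | autoregression order | 2 | the lag the reference analyses report; an AIC/BIC scan utility is provided |
| threshold grid | propensity curve support | 0 → 99th percentile, step 0.25 | comparable granularity to the published curves |

Timestamps are UTC epoch seconds; ties are broken by post id, and a reply
may share its parent's timestamp but never precede it.  Unregistered
authors are admitted with a synthetic registration at first-post time
(posting implies an account existed).

## Granger causality

Classic pairwise form: regress the target on a constant and `lag` own
lags (restricted), then additionally on `lag` lags of the candidate cause
(unrestricted); F = ((RSS_r − RSS_u)/lag)/(RSS_u/(n − 2·lag − 1)) with
(lag, n − 2·lag − 1) degrees of freedom.  Deterministic terms are
constant-only; no automatic stationarity pre-treatment is applied, but a
first-difference switch is available and recommended for visibly trending
series.  Both directions are always computed.  The implementation is
plain least squares (numpy); the suite cross-checks it against an
independent reference implementation and verifies calibration (empirical
size within [0.03, 0.07] at nominal 0.05 over 1000 white-noise
replicates) and power (≥95% detection of a lag-2 coupling with
coefficient 0.8 at n = 500).

## Propensity curves

Cumulative "at least x" construction: at each threshold the denominator
counts observations with score ≥ x, the numerator those with the outcome.
Denominators are therefore non-increasing and proportions undefined (NaN)
where the denominator is zero.  For bond formation the unit is the
ordered pair (engager, responder) with score T(i, j) and outcome "j left
a first wall note on i's profile"; the default universe is pairs with
positive targeted value, and a wider co-interaction universe (adding
zero-valued pairs at threshold 0) can be passed explicitly.  For
retention the unit is the (user, week t) observation with score = that
week's capacity and outcome = any post in week t+1; the final observed
week is excluded.  Lines are fitted by OLS with adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2); fitting refuses degenerate curves
(<3 defined points, or constant proportions).

## Synthetic forum generator

The generator's purpose is to produce data whose *statistical structure*
matches what the analyses assume, with known ground truth:

* day-stepped loop (matching daily binning); within a day, reply parents
  are sampled among posts existing at the day's start with recency
  weights exp(−decay·age), so same-day chains do not occur;
* arrivals ~ Poisson(base + gain·E_{t−2}) where E is daily engagement
  value — the planted engagement→reach arrow at lag 2;
* a lurker fraction of arrivals never posts initially; silent users
  (lurkers and dormant ex-contributors) return each day with probability
  delurk_base + delurk_gain·E_{t−1}, and permanently leave with
  probability abandon_rate (0.02/day);
* each time T(i, j) crosses a 0.5-unit level, j leaves a first wall note
  on i's page with probability logistic(β₀ + β₁·T(i, j)) (level-crossing
  trials prevent per-tick Bernoulli saturation);
* at each week's end an active user stays active with probability
  logistic(γ₀ + γ₁·capacity earned that week), else goes dormant.

All draws flow from one seeded generator; a fixed seed reproduces the
dataset byte for byte, and a truth trace records every bond trial and
retention draw with its true probability.

The permanent-churn mechanism is essential: without it every registrant
eventually returns, the engagement→arrival feedback compounds, and the
community grows without bound, leaving no stationary regime for the
causality analyses.  With it the default rates settle into a noisy steady
state of a few dozen active users (~8 responses/day after burn-in).
Default rates (2 organic arrivals/day, gain 0.15 arrivals per unit of
lag-2 engagement, 0.5 replies and 0.1 thread starts per active user-day,
70% lurker arrivals, β = (−4, 0.8), γ = (−1.2, 0.3)) were chosen once to
give a stable small community with bond and retention propensities of the
same order as published forum analyses (a few percent of pairs bonding at
moderate targeted values; next-week activity roughly doubling from its
~20% baseline for well-engaged users).  Larger arrival gains (≈0.2) push
the system past the stability boundary and are not defaults.

What the generator does **not** emulate: real forums' heavy-tailed thread
sizes and circadian/weekday rhythms, topic structure, moderator
interventions, multi-forum cross-posting, and the sheer scale of a real
platform (thousands of responses per day).  Passing tests therefore show
that the pipeline measures what it claims on data with the assumed
mechanisms — not that any particular real community obeys them.

## Validation suite design

The deeper checks run at deliberately desk-scale problem sizes, chosen as
the package's own test design: oracle equivalence on 200 random forums of
10–500 posts; conservation on 1000 random forums; Granger calibration on
1000 replicates of length-200 white noise; parameter recovery on 100
simulated 120-day forums (logistic fits of the truth trace must cover the
planted β₁ and γ₁ with their 95% CIs in ≥90% of replicates); planted
causal direction on 40 simulated 300-day forums (the engagement→reach
p-value must undercut the reverse in ≥90%); runtime scaling on forums of
1k–32k posts.

## Known limitations

* The engagement rule is the operational event-level realisation; exact
  coalition-lattice (Shapley-style) computation over all K-appearance
  coalitions is out of scope.
* Wall notes are the only bond signal; friending/following mechanics are
  not modelled.
* Delurking cannot be detected for a user's first-ever post by default
  (no prior post to measure silence from); an opt-in counts first posts
  ≥gap after registration.
* Granger tests here are bivariate; confounding by a third series (e.g.
  seasonality driving both engagement and reach) is not controlled.
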