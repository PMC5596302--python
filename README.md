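# ohf-engage

Engagement measurement and longitudinal analysis for threaded online
health forums (OHFs).

Forum managers and digital-health researchers often need more than raw
post counts: they need to know *who makes other people contribute*.  This
package implements a credit-assignment metric for that question, the event
detectors built on top of it (new-user reach, delurking, bond formation,
weekly activity), and the statistical analyses that relate them (two-way
Granger causality, propensity curves with linear fits).  A built-in
synthetic forum generator with planted causal structure makes the whole
pipeline testable end to end without access to any real platform's data.

## The metrics

A forum thread is a rooted reply tree.  Every post submitted in response
to a prior post raises the forum's **engagement value** by one unit.  That
unit is shared among the authors of the *subthread* — the root-anchored
path ending at the responded-to post — with geometric discounting: the
post at distance *d* up-thread from the responded-to post carries raw
weight α^d (α ∈ (0, 1], default 0.8), a user's retained weights (their K
most recent appearances, K unbounded by default) are summed, and the
shares are normalised to 1.  With α = 1 every post-appearance in the
subthread gets equal credit; with α < 1 credit concentrates on the most
recent contributors.  A user's accumulated share is their **engagement
capacity** C(i); the part of it earned specifically from responses
authored by user *j* is the directed **targeted engagement capacity**
T(i, j), with Σ_j T(i, j) = C(i) exactly.  Both are maintained
incrementally, one update per response, so computation is linear in the
number of posts.

On top of the ledger, the longitudinal layer asks:

* does daily engagement value Granger-cause *reach* (new registrations
  per day) and *delurking* (posts after ≥30 days of silence)?  (pairwise
  restricted/unrestricted OLS F-tests, default lag 2, constant term,
  optional first-differencing);
* does T(i, j) predict bond formation (j's first wall note on i's
  profile)?  (cumulative "at least x" propensity curves plus OLS fits
  with adjusted R²);
* does a user's weekly capacity predict their activity in the following
  week?

## Worked example

The illustrative 8-post thread — root by A, replies by B and C to the
root, then a deeper A–B–D–B branch in which B responds inside a subthread
containing their own posts — is bundled as a known-answer fixture:

```
$ python examples/01_credit_sharing.py
total engagement value: 7 (8 posts, 7 of them responses)
  capacity[A] = 3.4465
  capacity[B] = 2.6823
  capacity[D] = 0.8712
shares of one unit for a response to the A-B-D-B subthread:
  B: 0.5556
  D: 0.2710
  A: 0.1734
```

Seven of the eight posts respond to a preceding post, so the thread
contributes exactly 7 units of engagement value; those 7 units are fully
redistributed as capacity (conservation).  In the A–B–D–B subthread split,
B holds the leaf and one interior appearance (raw weights 1 and 0.64 of
the retained 2.952), so B's share 0.5556 exceeds the equal-credit 1/3 —
self-engagement at work.  C earned nothing: C's only post drew no
responses.

The other examples (`examples/02`–`05`) simulate a 6–12 month synthetic
forum and print the daily-series causality tests and the bond/retention
propensity curves, e.g. bond propensity rising from under 1% of ordered
user pairs at threshold 0 to tens of percent for strongly engaged pairs,
with an approximately linear curve (adjusted R² ≈ 0.97 on the bundled
seed).

A thin CLI mirrors the library for batch use:

```
ohf-engage simulate --seed 3 --out data/
ohf-engage engage --input data/ --out ledger/
ohf-engage report --seed 17 --out study/
```

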