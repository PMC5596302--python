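"""Engagement credit sharing: unit rule, incremental engine, oracle, windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohf_engage.engagement_core import (
    EngagementEngine,
    EngagementLedger,
    EngagementParams,
    capacities_by_enumeration,
    compute_ledger,
    credit_shares,
    ingest_post,
    normalized_capacity,
    originator_dominance,
    windowed_capacity,
)
from ohf_engage.forum_model import Post, Registration, make_dataset
from ohf_engage.synthetic_data import fixture_known_answer

from conftest import chain_thread, random_forum

A08 = EngagementParams(alpha=0.8)


def _path(authors, thread="t"):
    """Build a root-anchored path of posts with the given author sequence."""
    posts = []
    for i, a in enumerate(authors):
        posts.append(Post(f"p{i}", thread, a,
                          None if i == 0 else f"p{i-1}", i * 60))
    return posts


class TestCreditShares:
    def test_single_member_takes_whole_unit(self):
        for alpha in (0.3, 0.8, 1.0):
            shares = credit_shares(_path(["A"]), EngagementParams(alpha=alpha))
            assert shares == {"A": 1.0}

    def test_two_member_geometric_split(self):
        shares = credit_shares(_path(["A", "B"]), A08)
        assert shares["B"] == pytest.approx(1 / 1.8, abs=1e-12)
        assert shares["A"] == pytest.approx(0.8 / 1.8, abs=1e-12)

    def test_abdb_subthread_split(self):
        # authors A,B,D,B root-to-leaf: leaf-up weights 1, .8, .64, .512
        shares = credit_shares(_path(["A", "B", "D", "B"]), A08)
        assert shares["B"] == pytest.approx(1.64 / 2.952, abs=1e-12)
        assert shares["D"] == pytest.approx(0.8 / 2.952, abs=1e-12)
        assert shares["A"] == pytest.approx(0.512 / 2.952, abs=1e-12)

    def test_alpha_one_gives_equal_credit(self):
        shares = credit_shares(_path(["A", "B", "C"]), EngagementParams(alpha=1.0))
        assert shares == pytest.approx({u: 1 / 3 for u in "ABC"})

    def test_alpha_one_repeat_appearances_proportional(self):
        # m = 4 post-appearances; B appears twice -> share 2/4
        shares = credit_shares(_path(["A", "B", "C", "B"]),
                               EngagementParams(alpha=1.0))
        assert shares["B"] == pytest.approx(0.5)
        assert shares["A"] == pytest.approx(0.25)

    def test_k_truncation_keeps_most_recent_appearances(self):
        # B appears at d=0 (w=1) and d=2 (w=0.64); K=1 keeps only w=1
        shares = credit_shares(_path(["B", "A", "B"]),
                               EngagementParams(alpha=0.8, K=1))
        total = 1.0 + 0.8  # B leaf + A middle
        assert shares["B"] == pytest.approx(1.0 / total)
        assert shares["A"] == pytest.approx(0.8 / total)

    def test_empty_subthread_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            credit_shares([], A08)

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="alpha"):
                EngagementParams(alpha=alpha)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        authors=st.lists(st.sampled_from("ABCDE"), min_size=1, max_size=12),
        alpha=st.floats(0.05, 1.0),
        k=st.one_of(st.none(), st.integers(1, 4)),
    )
    def test_shares_form_a_distribution(self, authors, alpha, k):
        shares = credit_shares(_path(authors), EngagementParams(alpha=alpha, K=k))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v > 0 for v in shares.values())
        assert set(shares) == set(authors)


class TestIngest:
    def test_root_adds_no_value(self):
        ledger = EngagementLedger()
        root = Post("r", "t", "A", None, 0)
        ingest_post(ledger, root, {}, A08)
        assert ledger.total_value == 0
        assert ledger.post_counts["A"] == 1
        assert not ledger.capacity

    def test_direct_reply_gives_root_full_unit(self):
        ledger = EngagementLedger()
        root = Post("r", "t", "A", None, 0)
        reply = Post("x", "t", "B", "r", 10)
        ingest_post(ledger, root, {}, A08)
        ingest_post(ledger, reply, {"r": root}, A08)
        assert ledger.total_value == 1
        assert ledger.capacity["A"] == pytest.approx(1.0)
        assert ledger.targeted[("A", "B")] == pytest.approx(1.0)

    def test_nested_reply_splits_and_spares_bystander(self, tiny_thread):
        # D replies to B: unit split between A and B; C untouched
        ledger = compute_ledger(tiny_thread, A08)
        assert ledger.total_value == 3
        assert ledger.targeted[("B", "D")] == pytest.approx(1 / 1.8)
        assert ledger.targeted[("A", "D")] == pytest.approx(0.8 / 1.8)
        assert ledger.capacity.get("C", 0.0) == 0.0
        assert ledger.capacity["A"] == pytest.approx(2 + 0.8 / 1.8)

    def test_unordered_ingestion_rejected(self):
        ledger = EngagementLedger()
        reply = Post("x", "t", "B", "r", 10)
        with pytest.raises(ValueError, match="not ingested"):
            ingest_post(ledger, reply, {}, A08)

    def test_engine_rejects_duplicate_posts(self):
        engine = EngagementEngine(A08)
        engine.ingest(Post("r", "t", "A", None, 0))
        with pytest.raises(ValueError, match="twice"):
            engine.ingest(Post("r", "t", "A", None, 0))


class TestComputeLedger:
    def test_worked_example_value_is_seven(self):
        ds, expected = fixture_known_answer()
        ledger = compute_ledger(ds, A08)
        assert ledger.total_value == 7.0
        for u, cap in expected.capacity.items():
            assert ledger.capacity.get(u, 0.0) == pytest.approx(cap, abs=1e-9)

    def test_isolated_roots_have_zero_value(self):
        posts = [Post(f"r{i}", f"t{i}", f"u{i}", None, i) for i in range(5)]
        ledger = compute_ledger(make_dataset(posts), A08)
        assert ledger.total_value == 0
        assert not ledger.capacity

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_and_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_forum(rng, int(rng.integers(20, 150)))
        ledger = compute_ledger(ds, A08)
        assert sum(ledger.capacity.values()) == pytest.approx(
            ledger.total_value, abs=1e-9)
        by_engager = {}
        for (i, _j), v in ledger.targeted.items():
            by_engager[i] = by_engager.get(i, 0.0) + v
        for u, cap in ledger.capacity.items():
            assert by_engager.get(u, 0.0) == pytest.approx(cap, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_incremental_engine_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_forum(rng, 50)
        fast = compute_ledger(ds, A08)
        slow = capacities_by_enumeration(ds, A08)
        assert fast.total_value == slow.total_value
        assert set(fast.capacity) == set(slow.capacity)
        for u in fast.capacity:
            assert fast.capacity[u] == pytest.approx(slow.capacity[u], abs=1e-9)
        assert set(fast.targeted) == set(slow.targeted)
        for k in fast.targeted:
            assert fast.targeted[k] == pytest.approx(slow.targeted[k], abs=1e-9)

    def test_oracle_refuses_oversized_input(self, rng):
        ds = random_forum(rng, 60)
        with pytest.raises(ValueError, match="capped"):
            capacities_by_enumeration(ds, A08, max_posts=50)

    def test_chain_root_capacity_closed_form(self):
        n, alpha = 12, 0.8
        ds = chain_thread(n)
        ledger = compute_ledger(ds, EngagementParams(alpha=alpha))
        expected = sum(
            alpha ** (m - 1) / sum(alpha ** d for d in range(m))
            for m in range(1, n)
        )
        assert ledger.capacity["u0"] == pytest.approx(expected, abs=1e-12)

    def test_long_chain_last_four_share_tends_to_one_minus_alpha4(self):
        # ~half the credit at alpha=0.8 goes to the last 4 contributors
        # of a very long thread
        ds = chain_thread(200)
        posts = ds.all_posts()
        sub = posts[:-1]  # the subthread the last post responded to
        shares = credit_shares(sub, A08)
        last4 = {p.author_id for p in sub[-4:]}
        got = sum(shares[u] for u in last4)
        assert got == pytest.approx(1 - 0.8 ** 4, abs=1e-6)
        assert got == pytest.approx(0.5904, abs=1e-6)

    def test_empty_dataset_gives_empty_ledger(self):
        ledger = capacities_by_enumeration(make_dataset([]), A08)
        assert ledger.total_value == 0
        assert not ledger.capacity


class TestNormalizedCapacity:
    def test_capacity_per_post(self):
        ledger = EngagementLedger()
        ledger.capacity["A"] = 3.0
        ledger.post_counts["A"] = 6
        assert normalized_capacity(ledger) == {"A": 0.5}

    def test_zero_post_user_absent(self):
        ledger = EngagementLedger()
        ledger.capacity["lurker"] = 0.0
        assert "lurker" not in normalized_capacity(ledger)

    def test_symmetric_threads_give_equal_normalized_values(self):
        # two mirror-image threads: A and B swap roles; alpha=1
        posts = [
            Post("r1", "t1", "A", None, 0),
            Post("x1", "t1", "B", "r1", 10),
            Post("r2", "t2", "B", None, 20),
            Post("x2", "t2", "A", "r2", 30),
        ]
        ledger = compute_ledger(make_dataset(posts), EngagementParams(alpha=1.0))
        norm = normalized_capacity(ledger)
        assert norm["A"] == pytest.approx(norm["B"])


class TestWindowedCapacity:
    def test_single_window_holds_total(self, tiny_thread):
        series = windowed_capacity(tiny_thread, A08, window=7 * 86400)
        ledger = compute_ledger(tiny_thread, A08)
        for u, s in series.items():
            assert s.total == pytest.approx(ledger.capacity[u], abs=1e-9)
            assert list(s.values) == [0]

    def test_credit_dated_by_responding_post(self):
        week = 7 * 86400
        posts = [
            Post("r", "t", "A", None, 0),
            Post("x", "t", "B", "r", 60),          # week 0 response
            Post("y", "t", "C", "x", week + 60),   # week 1 response
        ]
        ds = make_dataset(posts)
        series = windowed_capacity(ds, A08, window=week)
        # A earns 1.0 in week 0 (B's reply) and 0.8/1.8 in week 1 (C's reply)
        assert series["A"].values[0] == pytest.approx(1.0)
        assert series["A"].values[1] == pytest.approx(0.8 / 1.8)
        assert series["B"].values[1] == pytest.approx(1 / 1.8)

    def test_total_over_windows_and_users_conserved(self, rng):
        ds = random_forum(rng, 120)
        series = windowed_capacity(ds, A08, window=86400)
        ledger = compute_ledger(ds, A08)
        grand = sum(s.total for s in series.values())
        assert grand == pytest.approx(ledger.total_value, abs=1e-9)

    def test_nonpositive_window_rejected(self, tiny_thread):
        with pytest.raises(ValueError, match="window"):
            windowed_capacity(tiny_thread, A08, window=0)


def test_originator_dominance_holds_on_worked_example():
    ds, _ = fixture_known_answer()
    assert originator_dominance(ds, A08) == {"thread-1": True}
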