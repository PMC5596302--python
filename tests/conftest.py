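"""Shared fixtures: small hand-built threads and random forum builders."""

from __future__ import annotations

import numpy as np
import pytest

from ohf_engage.forum_model import (
    ForumDataset,
    Post,
    Registration,
    WallNote,
    make_dataset,
)


def random_forum(
    rng: np.random.Generator,
    n_posts: int,
    n_users: int | None = None,
    n_threads: int | None = None,
    max_parent_lookback: int | None = None,
) -> ForumDataset:
    """Random reply forest, independent of the package's simulator.

    Each non-seed post picks a uniformly random existing post in its thread
    as parent (optionally restricted to the ``max_parent_lookback`` newest,
    which bounds depth growth).  Used to feed the engine/oracle equivalence
    and conservation property tests.
    """
    if n_users is None:
        n_users = max(2, n_posts // 4)
    if n_threads is None:
        n_threads = max(1, n_posts // 10)
    n_threads = min(n_threads, n_posts)
    users = [f"u{i}" for i in range(n_users)]
    posts: list[Post] = []
    thread_posts: dict[int, list[Post]] = {}
    for i in range(n_posts):
        author = users[int(rng.integers(n_users))]
        ts = 1_000_000 + i * 60
        if i < n_threads:
            t = i
            p = Post(f"p{i:05d}", f"t{t:04d}", author, None, ts)
        else:
            t = int(rng.integers(n_threads))
            pool = thread_posts[t]
            if max_parent_lookback is not None:
                pool = pool[-max_parent_lookback:]
            parent = pool[int(rng.integers(len(pool)))]
            p = Post(f"p{i:05d}", parent.thread_id, author, parent.post_id, ts)
        posts.append(p)
        thread_posts.setdefault(t, []).append(p)
    regs = [Registration(u, 999_000) for u in users]
    return make_dataset(posts, regs)


def chain_thread(n: int, distinct_authors: bool = True) -> ForumDataset:
    """Single thread where each post replies to the previous one."""
    posts = []
    for i in range(n):
        author = f"u{i}" if distinct_authors else ("a" if i % 2 else "b")
        posts.append(
            Post(f"p{i:04d}", "t0", author, None if i == 0 else f"p{i-1:04d}",
                 i * 60)
        )
    regs = [Registration(p.author_id, 0) for p in posts]
    seen = {r.user_id: r for r in regs}
    return make_dataset(posts, list(seen.values()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_thread() -> ForumDataset:
    """Root A; B and C reply to A; D replies to B (the narrative example)."""
    posts = [
        Post("a1", "t1", "A", None, 0),
        Post("b1", "t1", "B", "a1", 60),
        Post("c1", "t1", "C", "a1", 120),
        Post("d1", "t1", "D", "b1", 180),
    ]
    return make_dataset(posts, [Registration(u, 0) for u in "ABCD"])


@pytest.fixture
def dataset_with_notes(rng) -> ForumDataset:
    ds = random_forum(rng, 100, n_users=12)
    users = sorted({p.author_id for t in ds.threads for p in t.posts})
    notes = [
        WallNote(users[0], users[1], 1_000_500),
        WallNote(users[0], users[1], 1_000_900),  # repeat, same pair
        WallNote(users[1], users[0], 1_000_600),
        WallNote(users[2], users[2], 1_000_700),  # self-note
    ]
    return ForumDataset(ds.threads, ds.registrations, notes)
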