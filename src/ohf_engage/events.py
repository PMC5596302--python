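"""Observable event extraction: engagement/reach series, delurking, bonds,
weekly activity.

All series use contiguous fixed-width bins anchored at an explicit start
time (by default the dataset's first event), so bin membership is a
deterministic function of (anchor, width, timestamp) and independent of
timezone or calendar conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .forum_model import ForumDataset, Registration, WallNote

__all__ = [
    "EventSeries",
    "DelurkEvent",
    "BondEvent",
    "ActivityPanel",
    "engagement_value_series",
    "reach_series",
    "detect_delurking",
    "bond_events",
    "activity_panel",
]

DAY = 86400
WEEK = 7 * DAY


@dataclass
class EventSeries:
    """Time-binned event counts over a contiguous window."""

    name: str
    bin_seconds: int
    anchor: int  # start of bin 0 (UTC epoch seconds)
    counts: np.ndarray  # shape (n_bins,)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def bin_starts(self) -> np.ndarray:
        return self.anchor + self.bin_seconds * np.arange(self.n_bins)

    def aligned_with(self, other: "EventSeries") -> bool:
        return (
            self.bin_seconds == other.bin_seconds
            and self.anchor == other.anchor
            and self.n_bins == other.n_bins
        )


@dataclass(frozen=True)
class DelurkEvent:
    """A post by a previously active user after a long silence."""

    user_id: str
    timestamp: int
    gap_seconds: int


@dataclass(frozen=True)
class BondEvent:
    """First wall note by ``responder_id`` on ``engager_id``'s profile."""

    engager_id: str  # i — the wall owner, credited with engaging j
    responder_id: str  # j — the note author
    timestamp: int


@dataclass
class ActivityPanel:
    """Binary (user, week) activity indicators, weeks anchored at ``anchor``."""

    anchor: int
    n_weeks: int
    users: list[str]
    active: np.ndarray  # shape (n_users, n_weeks), dtype bool
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {u: k for k, u in enumerate(self.users)}

    def is_active(self, user_id: str, week: int) -> bool:
        row = self._index.get(user_id)
        if row is None or not (0 <= week < self.n_weeks):
            return False
        return bool(self.active[row, week])


def _bin_counts(times: Iterable[int], bin_seconds: int, anchor: int,
                t_end: int) -> np.ndarray:
    n_bins = max(1, -(-(max(t_end - anchor, 0) + 1) // bin_seconds))
    counts = np.zeros(n_bins, dtype=float)
    for t in times:
        idx = (t - anchor) // bin_seconds
        if 0 <= idx < n_bins:
            counts[idx] += 1
    return counts


def engagement_value_series(
    ds: ForumDataset, bin_seconds: int = DAY, anchor: int | None = None
) -> EventSeries:
    """Daily (or custom-bin) engagement value: responses per bin.

    Each post replying to a preceding post counts one unit in the bin of
    its own timestamp; the series total equals the ledger's total value.
    """
    if bin_seconds <= 0:
        raise ValueError("bin width must be positive")
    posts = ds.all_posts()
    if anchor is None:
        anchor = posts[0].timestamp if posts else ds.t_start
    t_end = max((p.timestamp for p in posts), default=anchor)
    times = [p.timestamp for p in posts if not p.is_root]
    return EventSeries("engagement_value", bin_seconds, anchor,
                       _bin_counts(times, bin_seconds, anchor, t_end))


def reach_series(
    registrations: Sequence[Registration],
    bin_seconds: int = DAY,
    anchor: int | None = None,
    t_end: int | None = None,
) -> EventSeries:
    """New-user registrations per bin (the platform's reach)."""
    if bin_seconds <= 0:
        raise ValueError("bin width must be positive")
    times = [r.registration_time for r in registrations]
    if anchor is None:
        anchor = min(times, default=0)
    if t_end is None:
        t_end = max(times, default=anchor)
    return EventSeries("reach", bin_seconds, anchor,
                       _bin_counts(times, bin_seconds, anchor, t_end))


def detect_delurking(
    ds: ForumDataset,
    gap_seconds: int = 30 * DAY,
    bin_seconds: int = DAY,
    anchor: int | None = None,
    count_first_post_after_registration_gap: bool = False,
) -> tuple[list[DelurkEvent], EventSeries]:
    """Posts by returning users after at least ``gap_seconds`` of silence.

    A user's own previous post defines the silence; the first-ever post is
    not a delurk unless ``count_first_post_after_registration_gap`` is set,
    in which case a first post at least ``gap_seconds`` after the user's
    registration also qualifies.

    Returns the events and their binned series (for causality analysis).
    """
    if gap_seconds <= 0:
        raise ValueError("gap must be positive")
    posts = ds.all_posts()
    reg_time = {r.user_id: r.registration_time for r in ds.registrations}
    last_post: dict[str, int] = {}
    events: list[DelurkEvent] = []
    for p in posts:
        prev = last_post.get(p.author_id)
        if prev is None:
            if count_first_post_after_registration_gap:
                t0 = reg_time.get(p.author_id)
                if t0 is not None and p.timestamp - t0 >= gap_seconds:
                    events.append(DelurkEvent(p.author_id, p.timestamp,
                                              p.timestamp - t0))
        elif p.timestamp - prev >= gap_seconds:
            events.append(DelurkEvent(p.author_id, p.timestamp,
                                      p.timestamp - prev))
        last_post[p.author_id] = p.timestamp
    if anchor is None:
        anchor = posts[0].timestamp if posts else ds.t_start
    t_end = max((p.timestamp for p in posts), default=anchor)
    series = EventSeries("delurking", bin_seconds, anchor,
                         _bin_counts([e.timestamp for e in events],
                                     bin_seconds, anchor, t_end))
    return events, series


def bond_events(notes: Iterable[WallNote]) -> list[BondEvent]:
    """First wall note per ordered (wall owner, author) pair; self-notes dropped."""
    first: dict[tuple[str, str], WallNote] = {}
    for n in sorted(notes, key=lambda n: (n.timestamp, n.author_id, n.wall_owner_id)):
        if n.author_id == n.wall_owner_id:
            continue
        first.setdefault((n.wall_owner_id, n.author_id), n)
    return [
        BondEvent(owner, author, n.timestamp)
        for (owner, author), n in sorted(first.items())
    ]


def activity_panel(ds: ForumDataset, anchor: int | None = None) -> ActivityPanel:
    """Binary user x week contribution indicators.

    Weeks are fixed 7-day windows anchored at the dataset's first post
    (or an explicit ``anchor``); a cell is 1 iff the user authored at least
    one post that week.  Every registered or posting user appears as a row,
    so pure lurkers contribute all-zero rows.
    """
    posts = ds.all_posts()
    if anchor is None:
        anchor = posts[0].timestamp if posts else ds.t_start
    t_end = max((p.timestamp for p in posts), default=anchor)
    n_weeks = max(1, (max(t_end - anchor, 0)) // WEEK + 1)
    users = sorted({p.author_id for p in posts}
                   | {r.user_id for r in ds.registrations})
    index = {u: k for k, u in enumerate(users)}
    active = np.zeros((len(users), n_weeks), dtype=bool)
    for p in posts:
        w = (p.timestamp - anchor) // WEEK
        if 0 <= w < n_weeks:
            active[index[p.author_id], w] = True
    return ActivityPanel(anchor, n_weeks, users, active)


def export_series_csv(series: EventSeries, out_path) -> None:
    """Write (bin_start, count) rows for one series."""
    import csv
    from pathlib import Path

    with Path(out_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_start", "count"])
        for start, c in zip(series.bin_starts(), series.counts):
            w.writerow([int(start), f"{c:.10g}"])
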