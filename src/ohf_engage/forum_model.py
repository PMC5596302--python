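"""Data model and I/O for threaded-forum activity.

A forum is a collection of threads; each thread is a rooted reply tree of
posts.  Alongside posts the model carries user registrations (for reach
analysis) and wall notes (for bond-formation analysis).  Timestamps are UTC
epoch seconds throughout; all binning downstream is done in UTC.

Two on-disk layouts are supported and round-trip losslessly:

* ``jsonl`` — ``posts.jsonl``, ``registrations.jsonl``, ``notes.jsonl``,
  one JSON object per record, epoch-second timestamps.
* ``csv`` — the same three tables as RFC-4180 UTF-8 CSV with a header row;
  timestamps are emitted as ISO-8601 UTC and either ISO-8601 or epoch
  seconds are accepted on read.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Post",
    "Thread",
    "Registration",
    "WallNote",
    "ForumDataset",
    "ReplyTree",
    "DatasetIntegrityError",
    "read_dataset",
    "write_dataset",
    "reply_tree",
]


class DatasetIntegrityError(ValueError):
    """Raised when records violate the forum invariants.

    Carries a per-row ``report`` listing every offending record.
    """

    def __init__(self, message: str, report: list[str]):
        super().__init__(message + "\n" + "\n".join(report))
        self.report = report


@dataclass(frozen=True)
class Post:
    """One forum message.  ``parent_post_id is None`` marks a thread root."""

    post_id: str
    thread_id: str
    author_id: str
    parent_post_id: str | None
    timestamp: int  # UTC epoch seconds

    @property
    def is_root(self) -> bool:
        return self.parent_post_id is None


@dataclass(frozen=True)
class Registration:
    user_id: str
    registration_time: int


@dataclass(frozen=True)
class WallNote:
    """A note by ``author_id`` on ``wall_owner_id``'s profile page."""

    author_id: str
    wall_owner_id: str
    timestamp: int


@dataclass
class Thread:
    """A rooted reply tree of posts, kept in (timestamp, post_id) order."""

    thread_id: str
    forum_id: str
    posts: list[Post] = field(default_factory=list)

    @property
    def root(self) -> Post:
        roots = [p for p in self.posts if p.is_root]
        if len(roots) != 1:
            raise DatasetIntegrityError(
                f"thread {self.thread_id}: expected exactly one root",
                [p.post_id for p in roots],
            )
        return roots[0]


@dataclass
class ReplyTree:
    """Child lists per post, children ordered by (timestamp, post_id)."""

    root_id: str
    children: dict[str, list[str]]
    parent: dict[str, str | None]
    posts_by_id: dict[str, Post]

    def path_to_root(self, post_id: str) -> list[Post]:
        """Root-to-``post_id`` subthread as a list of posts."""
        chain: list[Post] = []
        cur: str | None = post_id
        while cur is not None:
            chain.append(self.posts_by_id[cur])
            cur = self.parent[cur]
        chain.reverse()
        return chain


@dataclass
class ForumDataset:
    """Validated forum snapshot over an observation window."""

    threads: list[Thread]
    registrations: list[Registration]
    wall_notes: list[WallNote]
    t_start: int = 0
    t_end: int = 0

    def __post_init__(self) -> None:
        if self.t_end == 0 and self.t_start == 0:
            times = [p.timestamp for t in self.threads for p in t.posts]
            times += [r.registration_time for r in self.registrations]
            times += [n.timestamp for n in self.wall_notes]
            if times:
                self.t_start = min(times)
                self.t_end = max(times)

    def all_posts(self) -> list[Post]:
        """All posts, chronologically ordered (ties by post_id)."""
        posts = [p for t in self.threads for p in t.posts]
        posts.sort(key=lambda p: (p.timestamp, p.post_id))
        return posts

    @property
    def n_posts(self) -> int:
        return sum(len(t.posts) for t in self.threads)

    def registered_users(self) -> set[str]:
        return {r.user_id for r in self.registrations}


# ---------------------------------------------------------------------------
# Validation

def _validate_and_assemble(
    posts: list[Post],
    registrations: list[Registration],
    notes: list[WallNote],
    forum_ids: Mapping[str, str] | None = None,
) -> ForumDataset:
    report: list[str] = []
    by_id: dict[str, Post] = {}
    for p in posts:
        if p.post_id in by_id:
            report.append(f"post {p.post_id}: duplicate post_id")
        by_id[p.post_id] = p

    threads: dict[str, list[Post]] = {}
    for p in posts:
        threads.setdefault(p.thread_id, []).append(p)

    for tid, tposts in threads.items():
        roots = [p for p in tposts if p.is_root]
        if len(roots) != 1:
            report.append(
                f"thread {tid}: {len(roots)} roots (exactly one required)"
            )
            continue
        for p in tposts:
            if p.is_root:
                continue
            parent = by_id.get(p.parent_post_id)  # type: ignore[arg-type]
            if parent is None:
                report.append(
                    f"post {p.post_id}: parent {p.parent_post_id} not found"
                )
            elif parent.thread_id != p.thread_id:
                report.append(
                    f"post {p.post_id}: parent {parent.post_id} in a "
                    f"different thread"
                )
            elif (parent.timestamp, parent.post_id) > (p.timestamp, p.post_id):
                report.append(
                    f"post {p.post_id}: precedes its parent "
                    f"{parent.post_id}"
                )
        # acyclicity: walk up with a step budget
        for p in tposts:
            seen = set()
            cur: Post | None = p
            while cur is not None and not cur.is_root:
                if cur.post_id in seen:
                    report.append(f"thread {tid}: parent cycle at {cur.post_id}")
                    break
                seen.add(cur.post_id)
                cur = by_id.get(cur.parent_post_id)  # type: ignore[arg-type]

    reg_times: dict[str, int] = {}
    for r in registrations:
        if r.user_id in reg_times:
            report.append(f"registration {r.user_id}: duplicate user")
        reg_times[r.user_id] = r.registration_time

    if report:
        raise DatasetIntegrityError("dataset failed validation", report)

    # Unregistered authors are admitted with a synthetic registration at
    # first-post time (forums allow reading without registering, but a post
    # implies an account existed by then).
    first_post: dict[str, int] = {}
    for p in sorted(posts, key=lambda p: (p.timestamp, p.post_id)):
        first_post.setdefault(p.author_id, p.timestamp)
    synthetic = sorted(set(first_post) - set(reg_times))
    if synthetic:
        warnings.warn(
            f"{len(synthetic)} post author(s) missing from registrations; "
            "synthetic registrations added at first-post time",
            stacklevel=3,
        )
        registrations = list(registrations) + [
            Registration(u, first_post[u]) for u in synthetic
        ]
    for u, t0 in reg_times.items():
        if u in first_post and t0 > first_post[u]:
            raise DatasetIntegrityError(
                "dataset failed validation",
                [f"user {u}: registered after first post"],
            )

    thread_objs = []
    for tid in sorted(threads):
        tposts = sorted(threads[tid], key=lambda p: (p.timestamp, p.post_id))
        fid = (forum_ids or {}).get(tid, "forum")
        thread_objs.append(Thread(tid, fid, tposts))
    return ForumDataset(
        threads=thread_objs,
        registrations=sorted(registrations, key=lambda r: (r.registration_time, r.user_id)),
        wall_notes=sorted(notes, key=lambda n: (n.timestamp, n.author_id, n.wall_owner_id)),
    )


def make_dataset(
    posts: Iterable[Post],
    registrations: Iterable[Registration] = (),
    wall_notes: Iterable[WallNote] = (),
) -> ForumDataset:
    """Assemble and validate a dataset from flat record collections."""
    return _validate_and_assemble(list(posts), list(registrations), list(wall_notes))


# ---------------------------------------------------------------------------
# I/O

_POST_FIELDS = ("post_id", "thread_id", "author_id", "parent_post_id", "timestamp")
_REG_FIELDS = ("user_id", "registration_time")
_NOTE_FIELDS = ("author_id", "wall_owner_id", "timestamp")


def _parse_time(value, *, where: str) -> int:
    if value is None or value == "":
        raise ValueError(f"{where}: missing timestamp")
    if isinstance(value, (int, float)):
        return int(value)
    s = str(value)
    try:
        return int(float(s))
    except ValueError:
        pass
    dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return int(dt.timestamp())


def _iso(ts: int) -> str:
    return datetime.fromtimestamp(ts, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _require(record: Mapping, fields: Sequence[str], where: str) -> None:
    missing = [f for f in fields if f not in record]
    if missing:
        raise ValueError(f"{where}: missing required field(s) {missing}")


def _records_from_jsonl(path: Path) -> Iterator[dict]:
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path.name} line {i}: invalid JSON ({exc})") from exc


def _records_from_csv(path: Path) -> Iterator[dict]:
    with path.open(encoding="utf-8", newline="") as fh:
        yield from csv.DictReader(fh)


def read_dataset(path: str | Path, format: str = "jsonl") -> ForumDataset:
    """Read a forum dataset from a directory of JSONL or CSV tables.

    Parameters
    ----------
    path
        Directory holding ``posts.{jsonl,csv}`` and optionally
        ``registrations.*`` and ``notes.*``.
    format
        ``"jsonl"`` or ``"csv"``.

    Raises
    ------
    DatasetIntegrityError
        If any record violates the forum invariants (orphan parents,
        multiple roots, replies preceding parents, ...); the error lists
        every offending record.
    ValueError
        On parse failures or missing required fields, naming row and field.
    """
    path = Path(path)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    ext = "jsonl" if format == "jsonl" else "csv"
    reader = _records_from_jsonl if format == "jsonl" else _records_from_csv

    posts: list[Post] = []
    ppath = path / f"posts.{ext}"
    if not ppath.exists():
        raise FileNotFoundError(ppath)
    for i, rec in enumerate(reader(ppath), 1):
        where = f"posts row {i}"
        _require(rec, ("post_id", "thread_id", "author_id", "timestamp"), where)
        parent = rec.get("parent_post_id")
        if parent in ("", None):
            parent = None
        posts.append(
            Post(
                post_id=str(rec["post_id"]),
                thread_id=str(rec["thread_id"]),
                author_id=str(rec["author_id"]),
                parent_post_id=None if parent is None else str(parent),
                timestamp=_parse_time(rec["timestamp"], where=where),
            )
        )

    regs: list[Registration] = []
    rpath = path / f"registrations.{ext}"
    if rpath.exists():
        for i, rec in enumerate(reader(rpath), 1):
            where = f"registrations row {i}"
            _require(rec, _REG_FIELDS, where)
            regs.append(
                Registration(
                    str(rec["user_id"]),
                    _parse_time(rec["registration_time"], where=where),
                )
            )

    notes: list[WallNote] = []
    npath = path / f"notes.{ext}"
    if npath.exists():
        for i, rec in enumerate(reader(npath), 1):
            where = f"notes row {i}"
            _require(rec, _NOTE_FIELDS, where)
            notes.append(
                WallNote(
                    str(rec["author_id"]),
                    str(rec["wall_owner_id"]),
                    _parse_time(rec["timestamp"], where=where),
                )
            )

    return _validate_and_assemble(posts, regs, notes)


def write_dataset(ds: ForumDataset, path: str | Path, format: str = "jsonl") -> None:
    """Write ``ds`` so that :func:`read_dataset` inverts it exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    posts = ds.all_posts()
    regs = ds.registrations
    notes = ds.wall_notes

    if format == "jsonl":
        with (path / "posts.jsonl").open("w", encoding="utf-8") as fh:
            for p in posts:
                fh.write(json.dumps({
                    "post_id": p.post_id,
                    "thread_id": p.thread_id,
                    "author_id": p.author_id,
                    "parent_post_id": p.parent_post_id,
                    "timestamp": p.timestamp,
                }, ensure_ascii=False) + "\n")
        with (path / "registrations.jsonl").open("w", encoding="utf-8") as fh:
            for r in regs:
                fh.write(json.dumps({
                    "user_id": r.user_id,
                    "registration_time": r.registration_time,
                }, ensure_ascii=False) + "\n")
        with (path / "notes.jsonl").open("w", encoding="utf-8") as fh:
            for n in notes:
                fh.write(json.dumps({
                    "author_id": n.author_id,
                    "wall_owner_id": n.wall_owner_id,
                    "timestamp": n.timestamp,
                }, ensure_ascii=False) + "\n")
    elif format == "csv":
        with (path / "posts.csv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_POST_FIELDS)
            for p in posts:
                w.writerow([p.post_id, p.thread_id, p.author_id,
                            p.parent_post_id or "", _iso(p.timestamp)])
        with (path / "registrations.csv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_REG_FIELDS)
            for r in regs:
                w.writerow([r.user_id, _iso(r.registration_time)])
        with (path / "notes.csv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_NOTE_FIELDS)
            for n in notes:
                w.writerow([n.author_id, n.wall_owner_id, _iso(n.timestamp)])
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Reply trees

def reply_tree(thread: Thread) -> ReplyTree:
    """Build the rooted reply tree of a thread.

    Children are ordered by (timestamp, post_id), so iterating the tree
    reproduces the thread's chronological structure deterministically.
    """
    by_id = {p.post_id: p for p in thread.posts}
    roots = [p for p in thread.posts if p.is_root]
    if len(roots) != 1:
        raise DatasetIntegrityError(
            f"thread {thread.thread_id}: expected exactly one root",
            [p.post_id for p in roots],
        )
    children: dict[str, list[str]] = {p.post_id: [] for p in thread.posts}
    parent: dict[str, str | None] = {}
    for p in sorted(thread.posts, key=lambda p: (p.timestamp, p.post_id)):
        parent[p.post_id] = p.parent_post_id
        if p.parent_post_id is not None:
            if p.parent_post_id not in by_id:
                raise DatasetIntegrityError(
                    f"thread {thread.thread_id}: orphan parent",
                    [f"post {p.post_id}: parent {p.parent_post_id} missing"],
                )
            children[p.parent_post_id].append(p.post_id)
    # reachability doubles as the cycle check
    reached = 0
    stack = [roots[0].post_id]
    seen: set[str] = set()
    while stack:
        cur = stack.pop()
        if cur in seen:
            raise DatasetIntegrityError(
                f"thread {thread.thread_id}: cycle detected", [cur]
            )
        seen.add(cur)
        reached += 1
        stack.extend(children[cur])
    if reached != len(thread.posts):
        raise DatasetIntegrityError(
            f"thread {thread.thread_id}: {len(thread.posts) - reached} post(s) "
            "unreachable from root",
            sorted(set(by_id) - seen),
        )
    return ReplyTree(roots[0].post_id, children, parent, by_id)
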