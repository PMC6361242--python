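"""Synchronized single-stream and striped result writing, plus merging.

Results are SAM-dialect lines.  In single-stream mode all threads share one
file and one output lock.  In striped mode thread ``t`` writes only to
stripe ``t mod S`` and each stripe has its own lock, spreading output-lock
contention over ``S`` locks.  Stripes are plain SAM files named
``<prefix>.<index>.sam`` (zero-based) and can be merged by concatenation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

from blockfq.sync import BaseLock, LockDiscipline, make_lock

__all__ = [
    "StripePlan",
    "SAM_HEADER",
    "SingleFileSink",
    "StripedSink",
    "merge_stripes",
    "stripe_paths",
    "MissingStripeError",
]

#: default stripe count
DEFAULT_STRIPES = 16

#: minimal header written once at the top of every output file
SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n"


class MissingStripeError(FileNotFoundError):
    """A stripe file expected by the merge is absent."""


@dataclass(frozen=True)
class StripePlan:
    """Thread-to-stripe mapping: thread id modulo ``stripe_count``."""

    stripe_count: int = DEFAULT_STRIPES

    def __post_init__(self) -> None:
        if self.stripe_count < 1:
            raise ValueError("stripe_count must be >= 1")

    def stripe_for(self, thread_id: int) -> int:
        return thread_id % self.stripe_count


def _check_lines(lines: Sequence[str]) -> None:
    for line in lines:
        if not line.endswith("\n") or "\n" in line[:-1]:
            raise ValueError(
                "output lines must be single, newline-terminated records"
            )


class SingleFileSink:
    """All threads append to one file under one output lock."""

    def __init__(
        self,
        path: str,
        lock: "BaseLock | LockDiscipline | None" = None,
        header: Optional[str] = SAM_HEADER,
    ) -> None:
        if lock is None:
            lock = make_lock(LockDiscipline())
        elif isinstance(lock, LockDiscipline):
            lock = make_lock(lock)
        self.path = path
        self.lock = lock
        self._fh = open(path, "w")
        if header:
            self._fh.write(header)

    def write(self, thread_id: int, lines: Sequence[str]) -> None:
        """Append complete records; serialized so lines never interleave."""
        _check_lines(lines)
        with self.lock:
            self._fh.writelines(lines)

    def close(self) -> None:
        self._fh.close()

    def paths(self) -> List[str]:
        return [self.path]

    def __enter__(self) -> "SingleFileSink":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class StripedSink:
    """Each thread writes to stripe ``thread_id mod S``, one lock per stripe.

    All ``S`` stripe files are created (with headers) up front, so the file
    set is a function of the plan, not of which threads happened to write.
    """

    def __init__(
        self,
        prefix: str,
        plan: StripePlan = StripePlan(),
        lock_discipline: LockDiscipline = LockDiscipline(),
        header: Optional[str] = SAM_HEADER,
    ) -> None:
        self.prefix = prefix
        self.plan = plan
        self._paths = stripe_paths(prefix, plan.stripe_count)
        self._files = []
        self._locks: List[BaseLock] = []
        for p in self._paths:
            fh = open(p, "w")
            if header:
                fh.write(header)
            self._files.append(fh)
            self._locks.append(make_lock(lock_discipline))

    def write(self, thread_id: int, lines: Sequence[str]) -> None:
        _check_lines(lines)
        idx = self.plan.stripe_for(thread_id)
        try:
            with self._locks[idx]:
                self._files[idx].writelines(lines)
        except OSError as exc:
            raise OSError(f"write failed on stripe {idx}: {exc}") from exc

    def close(self) -> None:
        for fh in self._files:
            fh.close()

    def paths(self) -> List[str]:
        return list(self._paths)

    def __enter__(self) -> "StripedSink":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def stripe_paths(prefix: str, stripe_count: int) -> List[str]:
    """Expected stripe file names for a prefix: ``<prefix>.<i>.sam``."""
    return [f"{prefix}.{i}.sam" for i in range(stripe_count)]


def merge_stripes(
    stripes: Sequence[str],
    out_path: str,
    header: Optional[str] = SAM_HEADER,
) -> str:
    """Concatenate stripe files, in stripe order, into one file.

    Header lines (``@``-prefixed) must be identical copies across stripes;
    they are emitted once.  Raises :class:`MissingStripeError` listing any
    absent stripes.
    """
    missing = [p for p in stripes if not os.path.exists(p)]
    if missing:
        raise MissingStripeError(f"missing stripe file(s): {', '.join(missing)}")
    expected_header: Optional[List[str]] = None
    with open(out_path, "w") as out:
        for p in stripes:
            with open(p) as fh:
                lines = fh.readlines()
            head = [ln for ln in lines if ln.startswith("@")]
            body = [ln for ln in lines if not ln.startswith("@")]
            if expected_header is None:
                expected_header = head
                out.writelines(head)
            elif head != expected_header:
                raise ValueError(f"stripe {p} header differs from the first stripe's")
            out.writelines(body)
    return out_path
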