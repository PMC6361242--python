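"""Mutual-exclusion disciplines with acquisition statistics.

Three disciplines are provided, selected at run time:

``pessimistic``
    Sleep immediately when the lock is held (a standard OS mutex).
``spin``
    Optimistically busy-wait for a bounded interval (``spin_budget``),
    then fall back to sleeping.  Best when the lock turns over quickly;
    the budget bounds starvation of the holder.
``queueing``
    FIFO hand-off: waiters are granted the lock in arrival order and each
    waiter is signaled individually, so a hand-off involves only the
    releasing thread and the next waiter.  This is the contract of an
    MCS-style queueing lock; cache-line behavior is not modeled.

All locks enforce the usage contract (release only by the holder, no
re-entry) and count acquisitions, contended acquisitions and microseconds
spent waiting.
"""

from __future__ import annotations

import threading
import time
from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = [
    "LockDiscipline",
    "LockStats",
    "LockContractError",
    "BaseLock",
    "PessimisticLock",
    "SpinLock",
    "QueueingLock",
    "make_lock",
    "grant_order",
]

DISCIPLINES = ("pessimistic", "spin", "queueing")

#: default optimistic-spin interval before yielding to the OS (seconds)
DEFAULT_SPIN_BUDGET = 50e-6


class LockContractError(RuntimeError):
    """Release without holding, or acquire while already holding."""


@dataclass(frozen=True)
class LockDiscipline:
    """Run-time lock selection: kind plus the spin budget where relevant."""

    kind: str = "pessimistic"
    spin_budget: float = DEFAULT_SPIN_BUDGET

    def __post_init__(self) -> None:
        if self.kind not in DISCIPLINES:
            raise ValueError(f"unknown lock kind {self.kind!r}; choose from {DISCIPLINES}")
        if self.kind == "spin" and self.spin_budget <= 0:
            raise ValueError("spin_budget must be positive for the spin discipline")


@dataclass
class LockStats:
    acquisitions: int = 0
    contended_acquisitions: int = 0
    total_wait_us: float = 0.0


class BaseLock:
    """Shared bookkeeping: owner tracking, stats, context management."""

    def __init__(self) -> None:
        self.stats = LockStats()
        self._owner: Optional[int] = None
        self._meta = threading.Lock()  # guards stats + owner

    def acquire(self) -> None:
        raise NotImplementedError

    def release(self) -> None:
        raise NotImplementedError

    def _check_not_held(self) -> None:
        if self._owner == threading.get_ident():
            raise LockContractError("acquire while already holding the lock")

    def _take(self, waited_us: float, contended: bool) -> None:
        with self._meta:
            self._owner = threading.get_ident()
            self.stats.acquisitions += 1
            if contended:
                self.stats.contended_acquisitions += 1
                self.stats.total_wait_us += waited_us

    def _check_holder_and_clear(self) -> None:
        if self._owner != threading.get_ident():
            raise LockContractError("release by a thread that does not hold the lock")
        self._owner = None

    def __enter__(self) -> "BaseLock":
        self.acquire()
        return self

    def __exit__(self, *exc) -> None:
        self.release()


class PessimisticLock(BaseLock):
    """Go to sleep immediately if the lock is held."""

    def __init__(self) -> None:
        super().__init__()
        self._lock = threading.Lock()

    def acquire(self) -> None:
        self._check_not_held()
        if self._lock.acquire(blocking=False):
            self._take(0.0, contended=False)
            return
        t0 = time.perf_counter_ns()
        self._lock.acquire()
        self._take((time.perf_counter_ns() - t0) / 1e3, contended=True)

    def release(self) -> None:
        self._check_holder_and_clear()
        self._lock.release()


class SpinLock(BaseLock):
    """Busy-wait for ``spin_budget`` seconds, then sleep until free."""

    def __init__(self, spin_budget: float = DEFAULT_SPIN_BUDGET) -> None:
        super().__init__()
        if spin_budget <= 0:
            raise ValueError("spin_budget must be positive")
        self.spin_budget = spin_budget
        self._lock = threading.Lock()

    def acquire(self) -> None:
        self._check_not_held()
        if self._lock.acquire(blocking=False):
            self._take(0.0, contended=False)
            return
        t0 = time.perf_counter_ns()
        deadline = t0 + int(self.spin_budget * 1e9)
        # optimistic phase: poll without sleeping
        while time.perf_counter_ns() < deadline:
            if self._lock.acquire(blocking=False):
                self._take((time.perf_counter_ns() - t0) / 1e3, contended=True)
                return
        # pessimistic fallback: sleep until the holder releases
        self._lock.acquire()
        self._take((time.perf_counter_ns() - t0) / 1e3, contended=True)

    def release(self) -> None:
        self._check_holder_and_clear()
        self._lock.release()


class _Waiter:
    __slots__ = ("event", "ident")

    def __init__(self, ident: int) -> None:
        self.event = threading.Event()
        self.ident = ident


class QueueingLock(BaseLock):
    """FIFO queueing lock with per-waiter hand-off signaling.

    Waiters enqueue in arrival order; release hands the lock directly to
    the head waiter by setting that waiter's private event, so only the two
    threads involved in the hand-off communicate.  When ``record_log`` is
    set, arrival and grant orders of contended acquisitions are logged as
    ``(sequence, thread ident)`` tuples for auditing FIFO behavior.
    """

    def __init__(self, record_log: bool = False) -> None:
        super().__init__()
        self._held = False
        self._queue: deque[_Waiter] = deque()
        self._record_log = record_log
        self._seq = 0
        self.arrival_log: List[Tuple[int, int]] = []
        self.grant_log: List[Tuple[int, int]] = []

    def acquire(self) -> None:
        self._check_not_held()
        me = threading.get_ident()
        with self._meta:
            if not self._held and not self._queue:
                self._held = True
                self._owner = me
                self.stats.acquisitions += 1
                return
            waiter = _Waiter(me)
            self._queue.append(waiter)
            if self._record_log:
                self.arrival_log.append((self._seq, me))
                self._seq += 1
        t0 = time.perf_counter_ns()
        waiter.event.wait()  # hand-off: only this waiter is signaled
        waited = (time.perf_counter_ns() - t0) / 1e3
        with self._meta:
            self._owner = me
            self.stats.acquisitions += 1
            self.stats.contended_acquisitions += 1
            self.stats.total_wait_us += waited

    def release(self) -> None:
        with self._meta:
            if self._owner != threading.get_ident():
                raise LockContractError(
                    "release by a thread that does not hold the lock"
                )
            self._owner = None
            if self._queue:
                nxt = self._queue.popleft()
                if self._record_log:
                    self.grant_log.append((self._seq, nxt.ident))
                    self._seq += 1
                # ownership passes directly; _held stays True
                nxt.event.set()
            else:
                self._held = False


def make_lock(discipline: LockDiscipline, record_log: bool = False) -> BaseLock:
    """Instantiate the lock implementing ``discipline``."""
    if discipline.kind == "pessimistic":
        return PessimisticLock()
    if discipline.kind == "spin":
        return SpinLock(discipline.spin_budget)
    return QueueingLock(record_log=record_log)


def grant_order(lock: QueueingLock) -> List[int]:
    """Thread idents in the order the lock was handed to contended waiters."""
    return [ident for _, ident in lock.grant_log]
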