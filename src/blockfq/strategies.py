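"""The four synchronized input strategies, instrumented.

Each strategy prescribes exactly what happens inside the input critical
section (CS):

``O``  read *and parse* one record in the CS (one entry per record).
``D``  scan one record boundary in the CS; parse outside (one entry per
       record, but the CS does less work).
``B``  scan ``batch_size`` record boundaries in the CS; parse all of them
       outside (one entry per batch).
``L``  one fixed-size read of ``block_bytes`` in the CS; split and parse
       the block outside (one entry per block; requires blocked input).

Consumers are demand-driven: whichever thread acquires the input lock next
takes the next record/batch/block, so no static partitioning exists and
every input record is returned to exactly one consumer.

Instrumentation counts CS entries and accumulates microseconds spent
waiting for the input lock and holding it.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass, field
from typing import BinaryIO, List, Optional, Tuple

from blockfq.blocker import BlockSpec, PairingError, ValidationError, mate_base_name, split_block
from blockfq.fastq_core import (
    FastqRecord,
    MalformedRecordError,
    open_source,
    parse_record,
    scan_record_boundary,
)
from blockfq.sync import BaseLock, LockDiscipline, make_lock

__all__ = [
    "ParsingStrategy",
    "CsInstrumentation",
    "BoundaryViolationError",
    "FastqReader",
    "PairedFastqReader",
]

STRATEGY_KINDS = ("O", "D", "B", "L")

#: default B-parsing batch size
DEFAULT_BATCH_SIZE = 32


class BoundaryViolationError(ValueError):
    """L-parsing read a block that violates the blocked-file contract."""


@dataclass(frozen=True)
class ParsingStrategy:
    """Which strategy to run and its parameters.

    ``block_spec`` is required for (and only meaningful to) L-parsing.
    """

    kind: str = "B"
    batch_size: int = DEFAULT_BATCH_SIZE
    block_spec: Optional[BlockSpec] = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy {self.kind!r}; choose from {STRATEGY_KINDS}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if (self.kind == "L") != (self.block_spec is not None):
            raise ValueError("block_spec must be given iff kind == 'L'")


@dataclass
class CsInstrumentation:
    """Counts and timings of input critical-section entries."""

    entries: int = 0
    wait_us: float = 0.0
    hold_us: float = 0.0


class _SyncSource:
    """One input stream + its lock + instrumentation + consumption cap."""

    def __init__(self, stream: BinaryIO, lock: BaseLock, max_records: Optional[int]) -> None:
        self.stream = stream
        self.lock = lock
        self.cs = CsInstrumentation()
        self.remaining = max_records  # None = unlimited; guarded by the lock
        self._meta = threading.Lock()

    def _enter(self) -> int:
        t0 = time.perf_counter_ns()
        self.lock.acquire()
        t1 = time.perf_counter_ns()
        with self._meta:
            self.cs.wait_us += (t1 - t0) / 1e3
        return t1

    def _exit(self, t_acquired: int, productive: bool) -> None:
        """Leave the CS.  Only productive entries (ones that consumed
        input) are counted, so the end-of-stream probe does not inflate
        the entry count."""
        t2 = time.perf_counter_ns()
        self.lock.release()
        with self._meta:
            self.cs.hold_us += (t2 - t_acquired) / 1e3
            if productive:
                self.cs.entries += 1


class FastqReader:
    """Synchronized multi-consumer FASTQ reader under one parsing strategy.

    Any number of threads may call :meth:`next_batch` concurrently; the
    record stream is partitioned among them on demand.  ``max_records``
    caps total consumption (excess input is ignored).
    """

    def __init__(
        self,
        source: "bytes | str | BinaryIO",
        strategy: ParsingStrategy,
        lock: "BaseLock | LockDiscipline | None" = None,
        max_records: Optional[int] = None,
    ) -> None:
        if lock is None:
            lock = make_lock(LockDiscipline())
        elif isinstance(lock, LockDiscipline):
            lock = make_lock(lock)
        self.strategy = strategy
        self._src = _SyncSource(open_source(source), lock, max_records)
        self._final_block_seen = False

    @property
    def instrumentation(self) -> CsInstrumentation:
        return self._src.cs

    @property
    def lock(self) -> BaseLock:
        return self._src.lock

    # -- critical-section bodies -------------------------------------------

    def _cs_read_parse_one(self, src: _SyncSource) -> List[FastqRecord]:
        """O: read and parse a single record inside the CS."""
        if src.remaining == 0:
            return []
        buf = scan_record_boundary(src.stream)
        if buf is None:
            return []
        if src.remaining is not None:
            src.remaining -= 1
        return [parse_record(buf)]

    def _cs_scan_buffers(self, src: _SyncSource, count: int) -> List[bytes]:
        """D/B: scan ``count`` raw record buffers inside the CS."""
        bufs: List[bytes] = []
        for _ in range(count):
            if src.remaining == 0:
                break
            buf = scan_record_boundary(src.stream)
            if buf is None:
                break
            if src.remaining is not None:
                src.remaining -= 1
            bufs.append(buf)
        return bufs

    def _cs_read_block(self, src: _SyncSource) -> bytes:
        """L: one fixed-size read inside the CS."""
        if src.remaining == 0:
            return b""
        assert self.strategy.block_spec is not None
        return src.stream.read(self.strategy.block_spec.block_bytes)

    # -- public API --------------------------------------------------------

    def next_batch(self) -> List[FastqRecord]:
        """Return the next record(s); empty list at end of input.

        O and D return at most one record; B returns up to ``batch_size``;
        L returns the records of one block.  Parsing for D/B/L happens
        outside the critical section, in the calling thread.
        """
        kind = self.strategy.kind
        src = self._src
        if kind == "O":
            t = src._enter()
            got: List[FastqRecord] = []
            try:
                got = self._cs_read_parse_one(src)
                return got
            finally:
                src._exit(t, productive=bool(got))
        if kind in ("D", "B"):
            count = 1 if kind == "D" else self.strategy.batch_size
            t = src._enter()
            bufs: List[bytes] = []
            try:
                bufs = self._cs_scan_buffers(src, count)
            finally:
                src._exit(t, productive=bool(bufs))
            return [parse_record(b) for b in bufs]  # outside the CS
        # L
        spec = self.strategy.block_spec
        assert spec is not None
        take: Optional[int] = None
        t = src._enter()
        block = b""
        try:
            block = self._cs_read_block(src)
            if block:
                if self._final_block_seen:
                    raise BoundaryViolationError("data found after a short (final) block")
                if len(block) < spec.block_bytes:
                    self._final_block_seen = True
                if src.remaining is not None:
                    # a full block holds reads_per_block records; the final
                    # block may hold fewer, in which case the next read is
                    # EOF anyway, so over-decrementing is harmless
                    take = min(src.remaining, spec.reads_per_block)
                    src.remaining -= take
        finally:
            src._exit(t, productive=bool(block))
        if not block:
            return []
        # split + parse outside the CS
        try:
            records = split_block(block, spec)
        except (ValidationError, MalformedRecordError) as exc:
            raise BoundaryViolationError(str(exc)) from exc
        if len(records) < spec.reads_per_block:
            self._final_block_seen = True  # only the final block may run short
        if take is not None and len(records) > take:
            records = records[:take]
        return records

    def __iter__(self):
        while True:
            batch = self.next_batch()
            if not batch:
                return
            yield from batch


class PairedFastqReader:
    """Synchronized reader over two mate files.

    One critical-section entry takes the same amount from both files (one
    record for O/D, a batch for B, one block for L), so paired reads stay
    aligned: the reads taken from the two files in one entry belong to the
    same fragments, and for L they come from the same block index.
    """

    def __init__(
        self,
        source1: "bytes | str | BinaryIO",
        source2: "bytes | str | BinaryIO",
        strategy: ParsingStrategy,
        lock: "BaseLock | LockDiscipline | None" = None,
        max_pairs: Optional[int] = None,
    ) -> None:
        if lock is None:
            lock = make_lock(LockDiscipline())
        elif isinstance(lock, LockDiscipline):
            lock = make_lock(lock)
        self.strategy = strategy
        self.lock = lock
        self.cs = CsInstrumentation()
        self._stream1 = open_source(source1)
        self._stream2 = open_source(source2)
        self._remaining = max_pairs
        self._meta = threading.Lock()
        self._final_block_seen = False

    def _scan_n(self, stream: BinaryIO, count: int) -> List[bytes]:
        bufs: List[bytes] = []
        for _ in range(count):
            buf = scan_record_boundary(stream)
            if buf is None:
                break
            bufs.append(buf)
        return bufs

    def next_batch(self) -> List[Tuple[FastqRecord, FastqRecord]]:
        """Return mate pairs; empty list at end of input."""
        kind = self.strategy.kind
        spec = self.strategy.block_spec
        t0 = time.perf_counter_ns()
        self.lock.acquire()
        t1 = time.perf_counter_ns()
        parse_in_cs = kind == "O"
        bufs1: List[bytes] = []
        try:
            with self._meta:
                self.cs.wait_us += (t1 - t0) / 1e3
            if self._remaining == 0:
                return []
            if kind == "L":
                assert spec is not None
                raw1 = self._stream1.read(spec.block_bytes)
                raw2 = self._stream2.read(spec.block_bytes)
                if len(raw1) != len(raw2):
                    raise PairingError("paired blocked files differ in length")
                if raw1 and self._final_block_seen:
                    raise BoundaryViolationError("data found after a short (final) block")
                if raw1 and len(raw1) < spec.block_bytes:
                    self._final_block_seen = True
                bufs1 = [raw1] if raw1 else []
                bufs2: List[bytes] = [raw2] if raw2 else []
            else:
                count = 1 if kind in ("O", "D") else self.strategy.batch_size
                if self._remaining is not None:
                    count = min(count, self._remaining)
                bufs1 = self._scan_n(self._stream1, count)
                bufs2 = self._scan_n(self._stream2, count)
                if len(bufs1) != len(bufs2):
                    raise PairingError(
                        f"paired inputs ran out unevenly ({len(bufs1)} vs {len(bufs2)} records)"
                    )
                if self._remaining is not None:
                    self._remaining -= len(bufs1)
            if parse_in_cs:
                recs1 = [parse_record(b) for b in bufs1]
                recs2 = [parse_record(b) for b in bufs2]
        finally:
            t2 = time.perf_counter_ns()
            self.lock.release()
            with self._meta:
                self.cs.hold_us += (t2 - t1) / 1e3
                if bufs1:
                    self.cs.entries += 1
        if not bufs1:
            return []
        if kind == "L":
            assert spec is not None
            try:
                recs1 = split_block(bufs1[0], spec)
                recs2 = split_block(bufs2[0], spec)
            except (ValidationError, MalformedRecordError) as exc:
                raise BoundaryViolationError(str(exc)) from exc
            if len(recs1) != len(recs2):
                raise PairingError(
                    f"corresponding blocks hold {len(recs1)} vs {len(recs2)} records"
                )
            if self._remaining is not None:
                take = min(self._remaining, len(recs1))
                recs1, recs2 = recs1[:take], recs2[:take]
                with self._meta:
                    self._remaining -= take
        elif not parse_in_cs:
            recs1 = [parse_record(b) for b in bufs1]
            recs2 = [parse_record(b) for b in bufs2]
        pairs: List[Tuple[FastqRecord, FastqRecord]] = []
        for a, b in zip(recs1, recs2):
            if mate_base_name(a.name) != mate_base_name(b.name):
                raise PairingError(f"mate names disagree: {a.name!r} vs {b.name!r}")
            pairs.append((a, b))
        return pairs

    def __iter__(self):
        while True:
            batch = self.next_batch()
            if not batch:
                return
            yield from batch
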