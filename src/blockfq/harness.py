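"""Weak-scaling benchmark driver.

A *job* runs ``T`` worker threads against one shared synchronized reader
and one output sink.  Each worker loops: take a batch from the reader,
run a stand-in per-read workload (a seeded integer-mixing loop over the
read's bytes, repeated ``workload_cost`` times, its result folded into the
output line so it cannot be elided), and write the results.  Per-thread
wall-clock time is measured with microsecond resolution and excludes
one-time setup (workers start together behind a barrier).

Weak scaling holds ``reads_per_thread`` constant while the thread count
grows, so ideal scaling is constant wall time.  Throughput for a job is
``total reads / max per-thread time``; note the maximum per-thread time is
also reported separately from whole-job wall time, since the two differ by
setup and teardown.
"""

from __future__ import annotations

import json
import os
import threading
import time
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

from blockfq.blocker import BlockSpec, pad_fastq
from blockfq.fastq_core import FastqRecord
from blockfq.output import SingleFileSink, StripePlan, StripedSink
from blockfq.strategies import CsInstrumentation, FastqReader, ParsingStrategy
from blockfq.sync import LockDiscipline, LockStats, make_lock
from blockfq.synth import GeneratorSpec, generate_fastq

__all__ = [
    "ConfigurationError",
    "JobSpec",
    "JobResult",
    "ScalingTable",
    "run_job",
    "weak_scaling",
    "peak_throughput",
    "standin_workload",
    "sam_line",
]

#: default weak-scaling time limit (seconds); jobs over this are aborted
DEFAULT_TIME_LIMIT = 20 * 60.0

_MASK = (1 << 64) - 1


class ConfigurationError(ValueError):
    """Job configuration incompatible with its input."""


class NoDataError(ValueError):
    """Every row of a scaling table was aborted."""


def standin_workload(seq: bytes, cost: int, seed: int = 0) -> int:
    """Tunable per-read CPU cost: a 64-bit mixing loop over the read bytes."""
    h = (0x9E3779B97F4A7C15 ^ seed) & _MASK
    for _ in range(cost):
        for b in seq:
            h = ((h ^ b) * 0x100000001B3) & _MASK
        h ^= h >> 33
    return h


def sam_line(rec: FastqRecord, tag: int) -> str:
    """Minimal unaligned SAM record with the workload result as a tag."""
    return (
        f"{rec.name}\t4\t*\t0\t0\t*\t*\t0\t0\t"
        f"{rec.sequence.decode()}\t{rec.quality.decode()}\tXW:i:{tag & 0x7FFFFFFF}\n"
    )


@dataclass(frozen=True)
class JobSpec:
    """One benchmark job: strategy x lock x thread count x workload."""

    strategy: ParsingStrategy = ParsingStrategy(kind="B")
    lock: LockDiscipline = LockDiscipline()
    threads: int = 1
    reads_per_thread: int = 1000
    workload_cost: int = 1
    stripes: int = 0  # 0 = single output file
    workload_seed: int = 0

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.reads_per_thread < 0:
            raise ValueError("reads_per_thread must be >= 0")

    @property
    def total_reads(self) -> int:
        return self.threads * self.reads_per_thread


@dataclass
class JobResult:
    """Timings and instrumentation for one completed job."""

    spec: JobSpec
    reads_consumed: int
    per_thread_align_time_us: List[float]
    wall_time_us: float
    cs_in: CsInstrumentation
    lock_stats: LockStats
    output_paths: List[str]

    @property
    def max_thread_time_us(self) -> float:
        return max(self.per_thread_align_time_us)

    @property
    def throughput(self) -> float:
        """Reads per second, using the slowest thread's align time."""
        if self.max_thread_time_us == 0:
            return float("inf")
        return self.reads_consumed / (self.max_thread_time_us / 1e6)


def _check_input(spec: JobSpec, input_path: str) -> None:
    size = os.path.getsize(input_path)
    if spec.strategy.kind == "L":
        bs = spec.strategy.block_spec
        assert bs is not None
        if size % bs.block_bytes:
            raise ConfigurationError(
                f"L-parsing requires blocked input; size {size} is not a "
                f"multiple of block_bytes={bs.block_bytes}"
            )


def run_job(spec: JobSpec, input_path: str, out_prefix: str) -> JobResult:
    """Run one job and return its timings.

    ``input_path`` must hold at least ``spec.total_reads`` records (excess
    is ignored).  Output goes to ``<out_prefix>.sam`` or, when striped, to
    ``<out_prefix>.<i>.sam`` for each stripe ``i``.
    """
    _check_input(spec, input_path)
    input_lock = make_lock(spec.lock)
    reader = FastqReader(
        input_path, spec.strategy, lock=input_lock, max_records=spec.total_reads
    )
    if spec.stripes > 0:
        sink = StripedSink(
            out_prefix, StripePlan(spec.stripes), lock_discipline=spec.lock
        )
    else:
        sink = SingleFileSink(f"{out_prefix}.sam", lock=make_lock(spec.lock))

    barrier = threading.Barrier(spec.threads + 1)
    times_us = [0.0] * spec.threads
    consumed = [0] * spec.threads
    errors: List[BaseException] = []

    def worker(tid: int) -> None:
        try:
            barrier.wait()  # setup excluded from timing
            t0 = time.perf_counter_ns()
            while True:
                batch = reader.next_batch()
                if not batch:
                    break
                lines = []
                for rec in batch:
                    h = standin_workload(
                        rec.sequence, spec.workload_cost, spec.workload_seed
                    )
                    lines.append(sam_line(rec, h))
                sink.write(tid, lines)
                consumed[tid] += len(batch)
            times_us[tid] = (time.perf_counter_ns() - t0) / 1e3
        except BaseException as exc:  # surface worker failures to the caller
            errors.append(exc)
            barrier.abort()

    threads = [
        threading.Thread(target=worker, args=(tid,), name=f"worker-{tid}")
        for tid in range(spec.threads)
    ]
    for t in threads:
        t.start()
    barrier.wait()
    t_start = time.perf_counter_ns()
    for t in threads:
        t.join()
    wall_us = (time.perf_counter_ns() - t_start) / 1e3
    sink.close()
    if errors:
        raise errors[0]
    return JobResult(
        spec=spec,
        reads_consumed=sum(consumed),
        per_thread_align_time_us=times_us,
        wall_time_us=wall_us,
        cs_in=reader.instrumentation,
        lock_stats=input_lock.stats,
        output_paths=sink.paths(),
    )


@dataclass
class ScalingRow:
    threads: int
    reads: int
    max_thread_time_us: float
    wall_time_us: float
    throughput: float
    aborted: bool
    cs_entries: int
    mp_throughput: Optional[float] = None  # column for external MP runs

    def as_dict(self) -> dict:
        return {
            "threads": self.threads,
            "reads": self.reads,
            "max_thread_time_us": self.max_thread_time_us,
            "wall_time_us": self.wall_time_us,
            "throughput_reads_per_s": self.throughput,
            "aborted": self.aborted,
            "cs_entries": self.cs_entries,
            "mp_throughput_reads_per_s": self.mp_throughput,
        }


@dataclass
class ScalingTable:
    rows: List[ScalingRow] = field(default_factory=list)

    def to_tsv(self) -> str:
        cols = [
            "threads",
            "reads",
            "max_thread_time_us",
            "wall_time_us",
            "throughput_reads_per_s",
            "aborted",
            "cs_entries",
            "mp_throughput_reads_per_s",
        ]
        lines = ["\t".join(cols)]
        for row in self.rows:
            d = row.as_dict()
            lines.append("\t".join("" if d[c] is None else str(d[c]) for c in cols))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps([r.as_dict() for r in self.rows], indent=2)


def weak_scaling(
    thread_grid: Sequence[int],
    base: JobSpec,
    workdir: str,
    read_length: int = 100,
    seed: int = 0,
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> ScalingTable:
    """Run ``base`` at each thread count, scaling total reads with T.

    Synthetic input is generated per grid point (``T x reads_per_thread``
    reads, deterministic in ``seed``), blocked first when the strategy is
    L.  Rows whose wall time exceeds ``time_limit`` seconds are marked
    aborted.
    """
    if not thread_grid:
        raise ValueError("thread_grid must be non-empty")
    table = ScalingTable()
    for t_count in thread_grid:
        spec = replace(base, threads=t_count)
        gen = GeneratorSpec(
            record_count=spec.total_reads, read_length=read_length, seed=seed
        )
        data = generate_fastq(gen)
        if spec.strategy.kind == "L":
            assert spec.strategy.block_spec is not None
            data = pad_fastq(data, spec.strategy.block_spec)
        input_path = os.path.join(workdir, f"ws_input_t{t_count}.fastq")
        with open(input_path, "wb") as fh:
            fh.write(data)
        result = run_job(spec, input_path, os.path.join(workdir, f"ws_out_t{t_count}"))
        aborted = (result.wall_time_us / 1e6) > time_limit
        table.rows.append(
            ScalingRow(
                threads=t_count,
                reads=result.reads_consumed,
                max_thread_time_us=result.max_thread_time_us,
                wall_time_us=result.wall_time_us,
                throughput=result.throughput,
                aborted=aborted,
                cs_entries=result.cs_in.entries,
            )
        )
    return table


def peak_throughput(table: ScalingTable) -> "tuple[int, float]":
    """(threads, throughput) of the best non-aborted row; ties go to the
    lowest thread count."""
    live = [r for r in table.rows if not r.aborted]
    if not live:
        raise NoDataError("all rows aborted; no throughput to report")
    best = max(live, key=lambda r: (r.throughput, -r.threads))
    return best.threads, best.throughput
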