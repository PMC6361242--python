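"""Conversion between standard FASTQ and the padded blocked dialect.

A blocked file with spec ``(B, N)`` satisfies:

* file size is a multiple of ``B``;
* every offset that is a multiple of ``B`` holds ``@`` starting a record
  (no record spans a block boundary);
* every block holds exactly ``N`` records, except possibly the last, which
  holds between 1 and ``N`` and is still padded out to ``B`` bytes;
* padding appears only as trailing spaces on quality lines, and only on the
  last record of each block.

This lets a reader ingest the file with one fixed-size ``B``-byte read per
critical-section entry and know the record count per block up front.  For
paired files converted together with the same spec, block *i* of the two
outputs contains the same ``N`` read names, so paired ingestion can take
one block from the same offset in each file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import BinaryIO, List, Optional, Tuple

from blockfq.fastq_core import (
    FastqRecord,
    MalformedRecordError,
    TruncatedRecordError,
    iter_records,
    open_source,
    parse_record,
    scan_record_boundary,
    serialize_record,
)

__all__ = [
    "BlockSpec",
    "ValidationReport",
    "InfeasibleSpecError",
    "PairingError",
    "ValidationError",
    "pad_fastq",
    "pad_fastq_paired",
    "unpad_fastq",
    "validate_blocked",
    "max_reads_per_block",
    "mate_base_name",
]

#: smallest possible record: "@x\nA\n+\n!\n"
MIN_RECORD_BYTES = 9


class InfeasibleSpecError(ValueError):
    """Some group of N consecutive records does not fit in B bytes."""


class PairingError(ValueError):
    """Paired inputs disagree in record count or mate names."""


class ValidationError(ValueError):
    """Input claimed to be blocked does not conform to its spec."""


@dataclass(frozen=True)
class BlockSpec:
    """The ``(B bytes, N reads)`` contract of a blocked file."""

    block_bytes: int
    reads_per_block: int

    def __post_init__(self) -> None:
        if self.block_bytes <= 0 or self.reads_per_block <= 0:
            raise ValueError("block_bytes and reads_per_block must be positive")
        if self.block_bytes < self.reads_per_block * MIN_RECORD_BYTES:
            raise ValueError(
                f"block_bytes={self.block_bytes} cannot hold "
                f"{self.reads_per_block} records of >= {MIN_RECORD_BYTES} bytes"
            )


@dataclass
class ValidationReport:
    """Per-block conformance findings for a blocked file."""

    blocks_checked: int = 0
    records_found: int = 0
    violations: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def mate_base_name(name: str) -> str:
    """Read name with a trailing ``/1`` or ``/2`` mate suffix removed."""
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def _grouped_blocks(records: List[FastqRecord], spec: BlockSpec) -> bytes:
    """Serialize records into padded B-byte blocks, N per block."""
    out = bytearray()
    n, B = spec.reads_per_block, spec.block_bytes
    for start in range(0, len(records), n):
        group = records[start : start + n]
        sizes = [r.unpadded_size for r in group]
        used = sum(sizes)
        if used > B:
            raise InfeasibleSpecError(
                f"block {start // n}: {len(group)} records occupy {used} bytes "
                f"> block_bytes={B}"
            )
        for rec in group[:-1]:
            out += serialize_record(rec)
        # all padding for the block rides on its last record's quality line
        out += serialize_record(group[-1], pad_to=sizes[-1] + (B - used))
    return bytes(out)


def pad_fastq(data: "bytes | str | BinaryIO", spec: BlockSpec) -> bytes:
    """Convert standard FASTQ to blocked FASTQ under ``spec``.

    Output length is ``ceil(records / N) * B`` bytes; the final block is
    padded to a full ``B`` bytes even when it holds fewer than ``N`` records.
    """
    stream = open_source(data)
    records = list(iter_records(stream))
    return _grouped_blocks(records, spec)


def pad_fastq_paired(
    end1: "bytes | str | BinaryIO",
    end2: "bytes | str | BinaryIO",
    spec: BlockSpec,
) -> Tuple[bytes, bytes]:
    """Convert a pair of FASTQ files with one shared spec.

    Because both files are grouped ``N`` records at a time, corresponding
    blocks of the two outputs contain reads of the same fragments.
    """
    recs1 = list(iter_records(open_source(end1)))
    recs2 = list(iter_records(open_source(end2)))
    if len(recs1) != len(recs2):
        raise PairingError(
            f"paired inputs differ in record count: {len(recs1)} vs {len(recs2)}"
        )
    for i, (a, b) in enumerate(zip(recs1, recs2)):
        if mate_base_name(a.name) != mate_base_name(b.name):
            raise PairingError(
                f"record {i}: mate names disagree ({a.name!r} vs {b.name!r})"
            )
    return _grouped_blocks(recs1, spec), _grouped_blocks(recs2, spec)


def split_block(block: bytes, spec: BlockSpec, *, index: int = 0) -> List[FastqRecord]:
    """Parse the records of one conforming B-byte (or final, shorter) block."""
    if not block.startswith(b"@"):
        raise ValidationError(f"block {index} does not start with '@'")
    stream = io.BytesIO(block)
    records: List[FastqRecord] = []
    while True:
        try:
            buf = scan_record_boundary(stream)
        except TruncatedRecordError as exc:
            raise ValidationError(f"block {index}: {exc}") from exc
        if buf is None:
            break
        records.append(parse_record(buf))
    if len(records) > spec.reads_per_block:
        raise ValidationError(
            f"block {index}: {len(records)} records > reads_per_block="
            f"{spec.reads_per_block}"
        )
    return records


def unpad_fastq(blocked: "bytes | str | BinaryIO", spec: BlockSpec) -> bytes:
    """Strip padding from a blocked file, recovering canonical FASTQ.

    Raises :class:`ValidationError` naming the first offending block if the
    input does not conform to ``spec``.
    """
    stream = open_source(blocked)
    data = stream.read()
    B = spec.block_bytes
    if len(data) % B:
        raise ValidationError(
            f"file size {len(data)} is not a multiple of block_bytes={B}"
        )
    n_blocks = len(data) // B
    out = bytearray()
    for i in range(n_blocks):
        block = data[i * B : (i + 1) * B]
        try:
            records = split_block(block, spec, index=i)
        except MalformedRecordError as exc:
            raise ValidationError(f"block {i}: {exc}") from exc
        if not records:
            raise ValidationError(f"block {i}: no records")
        if i < n_blocks - 1 and len(records) != spec.reads_per_block:
            raise ValidationError(
                f"block {i}: {len(records)} records, expected "
                f"{spec.reads_per_block} in a non-final block"
            )
        for rec in records:
            out += serialize_record(rec)
    return bytes(out)


def validate_blocked(data: "bytes | str | BinaryIO", spec: BlockSpec) -> ValidationReport:
    """Scan a file for conformance to ``spec``; violations are collected,
    not raised."""
    stream = open_source(data)
    raw = stream.read()
    report = ValidationReport()
    B = spec.block_bytes
    if len(raw) % B:
        report.violations.append(
            (-1, f"file size {len(raw)} not divisible by block_bytes={B}")
        )
    n_blocks = len(raw) // B
    for i in range(n_blocks):
        block = raw[i * B : (i + 1) * B]
        report.blocks_checked += 1
        if not block.startswith(b"@"):
            report.violations.append((i, "block does not start with '@'"))
            continue
        try:
            records = split_block(block, spec, index=i)
        except (ValidationError, MalformedRecordError) as exc:
            report.violations.append((i, str(exc)))
            continue
        report.records_found += len(records)
        if i < n_blocks - 1 and len(records) != spec.reads_per_block:
            report.violations.append(
                (i, f"{len(records)} records, expected {spec.reads_per_block}")
            )
        if i == n_blocks - 1 and not records:
            report.violations.append((i, "final block holds no records"))
    return report


def max_reads_per_block(sample: List[FastqRecord], block_bytes: int) -> int:
    """Largest N such that every window of N consecutive sample records fits
    in ``block_bytes``.

    Checked against concrete windows, not a worst-case bound, so
    variable-length names pack as tightly as the sample allows.
    """
    if not sample:
        raise ValueError("sample must be non-empty")
    sizes = [r.unpadded_size for r in sample]
    if max(sizes) > block_bytes:
        raise InfeasibleSpecError(
            f"largest record ({max(sizes)} bytes) exceeds block_bytes={block_bytes}"
        )
    prefix = [0]
    for s in sizes:
        prefix.append(prefix[-1] + s)
    best = 1
    for n in range(2, len(sizes) + 1):
        worst = max(prefix[i + n] - prefix[i] for i in range(len(sizes) - n + 1))
        if worst > block_bytes:
            break
        best = n
    return best
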