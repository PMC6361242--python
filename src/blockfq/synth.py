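"""Deterministic synthetic FASTQ generation.

Reads are uniform draws over ``ACGT`` with either a fixed quality character
or seeded quality draws; the same :class:`GeneratorSpec` always produces
byte-identical output.  Paired output writes two files whose record *i*
share a name (``<prefix><i>/1`` and ``/2``), so generated pairs always
satisfy the pairing precondition of the blocked converter.  Default names
are short (``read<ordinal>``) so realistic block parameters such as
``B=12288, N=44`` (100 nt reads) and ``B=12288, N=70`` (50 nt reads)
are feasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import BinaryIO, List, Optional, Tuple, Union

import numpy as np

from blockfq.fastq_core import FastqRecord, iter_records, open_source, serialize_record

__all__ = ["GeneratorSpec", "generate_fastq", "generate_records", "truncate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: printable Phred+33 range used for random qualities
_QMIN, _QMAX = 33, 74


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one deterministic synthetic read set."""

    record_count: int
    read_length: Union[int, Tuple[int, int]] = 100
    name_prefix: str = "read"
    seed: int = 0
    paired: bool = False
    quality_char: Optional[str] = "I"  # None = seeded random qualities
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.record_count < 0:
            raise ValueError("record_count must be >= 0")
        if isinstance(self.read_length, int):
            if self.read_length < 1:
                raise ValueError("read_length must be >= 1")
        else:
            lo, hi = self.read_length
            if not (1 <= lo <= hi):
                raise ValueError("read_length range must satisfy 1 <= lo <= hi")


def _lengths(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.read_length, int):
        return np.full(spec.record_count, spec.read_length, dtype=np.int64)
    lo, hi = spec.read_length
    return rng.integers(lo, hi + 1, size=spec.record_count)


def _one_end(spec: GeneratorSpec, rng: np.random.Generator, mate: Optional[int]) -> List[FastqRecord]:
    lengths = _lengths(spec, rng)
    records: List[FastqRecord] = []
    for i, ln in enumerate(lengths):
        seq = _BASES[rng.integers(0, 4, size=int(ln))].tobytes()
        if spec.quality_char is not None:
            qual = spec.quality_char.encode() * int(ln)
        else:
            qual = rng.integers(_QMIN, _QMAX + 1, size=int(ln)).astype(np.uint8).tobytes()
        name = f"{spec.name_prefix}{i}"
        if mate is not None:
            name += f"/{mate}"
        records.append(
            FastqRecord(name=name, sequence=seq, quality=qual, comment=spec.comment)
        )
    return records


def generate_records(spec: GeneratorSpec) -> "List[FastqRecord] | Tuple[List[FastqRecord], List[FastqRecord]]":
    """Generate the record list(s) described by ``spec`` (two for paired)."""
    rng = np.random.default_rng(spec.seed)
    if not spec.paired:
        return _one_end(spec, rng, mate=None)
    end1 = _one_end(spec, rng, mate=1)
    end2 = _one_end(spec, rng, mate=2)
    return end1, end2


def generate_fastq(spec: GeneratorSpec) -> "bytes | Tuple[bytes, bytes]":
    """Serialize the generated read set; one byte string, or two for paired."""
    if not spec.paired:
        recs = generate_records(spec)
        return b"".join(serialize_record(r) for r in recs)
    end1, end2 = generate_records(spec)
    return (
        b"".join(serialize_record(r) for r in end1),
        b"".join(serialize_record(r) for r in end2),
    )


def truncate_reads(data: "bytes | str | BinaryIO", new_length: int) -> bytes:
    """Cut every read to ``new_length`` by removing the 3' suffix.

    Names are unchanged.  A read shorter than ``new_length`` is an error
    naming the record.
    """
    if new_length < 1:
        raise ValueError("new_length must be >= 1")
    out = bytearray()
    for rec in iter_records(open_source(data)):
        if len(rec.sequence) < new_length:
            raise ValueError(
                f"record {rec.name!r} is {len(rec.sequence)} nt, "
                f"shorter than new_length={new_length}"
            )
        out += serialize_record(
            FastqRecord(
                name=rec.name,
                sequence=rec.sequence[:new_length],
                quality=rec.quality[:new_length],
                comment=rec.comment,
                plus_text=rec.plus_text,
            )
        )
    return bytes(out)
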