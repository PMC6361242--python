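import io
from collections import Counter

import pytest

from blockfq.fastq_core import FastqRecord, iter_records, serialize_record
from blockfq.synth import GeneratorSpec, generate_fastq


def make_record(name: str, length: int, qual_char: str = "I") -> FastqRecord:
    return FastqRecord(
        name=name, sequence=b"A" * length, quality=qual_char.encode() * length
    )


def record_key(rec: FastqRecord):
    return (rec.name, rec.sequence, rec.quality)


def record_multiset(data: bytes) -> Counter:
    """Single-threaded linear-parse oracle: multiset of record keys."""
    return Counter(record_key(r) for r in iter_records(io.BytesIO(data)))


@pytest.fixture
def small_fastq() -> bytes:
    """Ten 20 nt reads with short names."""
    return generate_fastq(GeneratorSpec(record_count=10, read_length=20, seed=3))


@pytest.fixture
def paired_fastq():
    """100 paired 100 nt reads, deterministic."""
    return generate_fastq(
        GeneratorSpec(record_count=100, read_length=100, seed=11, paired=True)
    )
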