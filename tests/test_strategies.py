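import threading
from collections import Counter

import pytest

from blockfq.blocker import BlockSpec, PairingError, pad_fastq, pad_fastq_paired
from blockfq.fastq_core import MalformedRecordError
from blockfq.strategies import (
    BoundaryViolationError,
    FastqReader,
    PairedFastqReader,
    ParsingStrategy,
)
from blockfq.sync import LockDiscipline
from blockfq.synth import GeneratorSpec, generate_fastq
from tests.conftest import record_key, record_multiset

STRATEGIES = ["O", "D", "B", "L"]
L_SPEC = BlockSpec(2560, 16)


def make_strategy(kind: str, batch_size: int = 32) -> ParsingStrategy:
    if kind == "L":
        return ParsingStrategy(kind="L", block_spec=L_SPEC)
    return ParsingStrategy(kind=kind, batch_size=batch_size)


def input_for(kind: str, data: bytes) -> bytes:
    return pad_fastq(data, L_SPEC) if kind == "L" else data


def drain_concurrently(reader, n_threads: int):
    out = [[] for _ in range(n_threads)]
    errors = []

    def worker(i):
        try:
            while True:
                batch = reader.next_batch()
                if not batch:
                    return
                out[i].extend(batch)
        except BaseException as exc:
            errors.append(exc)

    threads = [threading.Thread(target=worker, args=(i,)) for i in range(n_threads)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if errors:
        raise errors[0]
    return [rec for chunk in out for rec in chunk]


@pytest.fixture(scope="module")
def fastq_1000() -> bytes:
    return generate_fastq(GeneratorSpec(record_count=1000, read_length=60, seed=21))


class TestBatchShapes:
    def test_o_and_d_return_single_records(self, fastq_1000):
        for kind in ("O", "D"):
            reader = FastqReader(fastq_1000, make_strategy(kind))
            batch = reader.next_batch()
            assert len(batch) == 1

    def test_b_returns_batches(self, fastq_1000):
        reader = FastqReader(fastq_1000, make_strategy("B"))
        assert len(reader.next_batch()) == 32

    def test_b_final_batch_short(self):
        data = generate_fastq(GeneratorSpec(record_count=40, read_length=20, seed=1))
        reader = FastqReader(data, make_strategy("B"))
        sizes = []
        while True:
            batch = reader.next_batch()
            if not batch:
                break
            sizes.append(len(batch))
        assert sizes == [32, 8]

    def test_l_returns_block_contents(self, fastq_1000):
        blocked = pad_fastq(fastq_1000, L_SPEC)
        reader = FastqReader(blocked, make_strategy("L"))
        assert len(reader.next_batch()) == L_SPEC.reads_per_block


class TestEntryCountLaws:
    @pytest.mark.parametrize("n_records", [1, 31, 32, 100, 1000])
    def test_o_d_entries_equal_record_count(self, n_records):
        data = generate_fastq(GeneratorSpec(record_count=n_records, read_length=20, seed=2))
        for kind in ("O", "D"):
            reader = FastqReader(data, make_strategy(kind))
            assert len(list(reader)) == n_records
            assert reader.instrumentation.entries == n_records

    @pytest.mark.parametrize("n_records", [1, 31, 32, 33, 100, 3200])
    def test_b_entries_equal_ceil_batches(self, n_records):
        data = generate_fastq(GeneratorSpec(record_count=n_records, read_length=20, seed=2))
        reader = FastqReader(data, make_strategy("B"))
        assert len(list(reader)) == n_records
        assert reader.instrumentation.entries == -(-n_records // 32)

    @pytest.mark.parametrize("n_records", [1, 16, 17, 160, 500])
    def test_l_entries_equal_block_count(self, n_records):
        data = generate_fastq(GeneratorSpec(record_count=n_records, read_length=20, seed=2))
        blocked = pad_fastq(data, L_SPEC)
        reader = FastqReader(blocked, make_strategy("L"))
        assert len(list(reader)) == n_records
        expected_blocks = len(blocked) // L_SPEC.block_bytes
        assert reader.instrumentation.entries == expected_blocks

    def test_ten_block_file_ten_entries(self):
        data = generate_fastq(GeneratorSpec(record_count=160, read_length=20, seed=3))
        blocked = pad_fastq(data, L_SPEC)
        assert len(blocked) // L_SPEC.block_bytes == 10
        reader = FastqReader(blocked, make_strategy("L"))
        list(reader)
        assert reader.instrumentation.entries == 10


class TestStrategyEquivalence:
    @pytest.mark.parametrize("kind", STRATEGIES)
    @pytest.mark.parametrize("n_threads", [1, 2, 8])
    def test_multiset_equals_single_thread_oracle(self, kind, n_threads, fastq_1000):
        oracle = record_multiset(fastq_1000)
        reader = FastqReader(input_for(kind, fastq_1000), make_strategy(kind))
        records = drain_concurrently(reader, n_threads)
        assert Counter(record_key(r) for r in records) == oracle

    @pytest.mark.parametrize("kind", STRATEGIES)
    def test_single_thread_preserves_order(self, kind, fastq_1000):
        oracle = [record_key(r) for r in FastqReader(fastq_1000, make_strategy("O"))]
        reader = FastqReader(input_for(kind, fastq_1000), make_strategy(kind))
        assert [record_key(r) for r in reader] == oracle


class TestHoldTimeOrdering:
    def test_d_hold_per_record_not_above_o(self):
        # smoke property with generous tolerance, not a benchmark
        data = generate_fastq(GeneratorSpec(record_count=4000, read_length=100, seed=5))
        holds = {}
        for kind in ("O", "D"):
            reader = FastqReader(data, make_strategy(kind))
            n = len(list(reader))
            holds[kind] = reader.instrumentation.hold_us / n
        assert holds["D"] <= holds["O"] * 1.25


class TestErrors:
    def test_malformed_record_raised_outside_cs(self):
        bad = b"@r1\nACGT\n+\nIII\n"  # length mismatch
        reader = FastqReader(bad, make_strategy("D"))
        with pytest.raises(MalformedRecordError):
            reader.next_batch()
        # the CS itself completed: the boundary scan counted an entry
        assert reader.instrumentation.entries == 1

    def test_l_on_standard_fastq_raises(self, fastq_1000):
        blocked = fastq_1000 + b" " * (-len(fastq_1000) % L_SPEC.block_bytes)
        reader = FastqReader(blocked, make_strategy("L"))
        with pytest.raises(BoundaryViolationError):
            while reader.next_batch():
                pass

    def test_max_records_caps_consumption(self, fastq_1000):
        for kind in STRATEGIES:
            reader = FastqReader(
                input_for(kind, fastq_1000), make_strategy(kind), max_records=100
            )
            assert len(list(reader)) == 100

    def test_strategy_config_validation(self):
        with pytest.raises(ValueError):
            ParsingStrategy(kind="X")
        with pytest.raises(ValueError):
            ParsingStrategy(kind="B", batch_size=0)
        with pytest.raises(ValueError):
            ParsingStrategy(kind="L")  # missing block_spec
        with pytest.raises(ValueError):
            ParsingStrategy(kind="B", block_spec=L_SPEC)


@pytest.fixture(scope="module")
def paired_data():
    return generate_fastq(
        GeneratorSpec(record_count=200, read_length=50, seed=13, paired=True)
    )


class TestPaired:
    @pytest.mark.parametrize("kind", STRATEGIES)
    def test_pairs_are_mates(self, kind, paired_data):
        d1, d2 = paired_data
        if kind == "L":
            d1, d2 = pad_fastq_paired(d1, d2, L_SPEC)
        reader = PairedFastqReader(d1, d2, make_strategy(kind))
        pairs = list(reader)
        assert len(pairs) == 200
        # oracle: join on base name
        for a, b in pairs:
            assert a.name.endswith("/1") and b.name.endswith("/2")
            assert a.name[:-2] == b.name[:-2]

    def test_equal_single_record_files(self):
        d1 = b"@f/1\nAC\n+\n!!\n"
        d2 = b"@f/2\nGG\n+\n##\n"
        reader = PairedFastqReader(d1, d2, make_strategy("O"))
        assert len(list(reader)) == 1

    def test_shuffled_end2_raises(self, paired_data):
        d1, d2 = paired_data
        # reverse the records of end 2
        from blockfq.fastq_core import iter_records, serialize_record
        import io

        recs2 = list(iter_records(io.BytesIO(d2)))
        shuffled = b"".join(serialize_record(r) for r in reversed(recs2))
        reader = PairedFastqReader(d1, shuffled, make_strategy("B"))
        with pytest.raises(PairingError):
            list(reader)

    def test_l_blocks_share_index(self, paired_data):
        d1, d2 = paired_data
        b1, b2 = pad_fastq_paired(d1, d2, L_SPEC)
        reader = PairedFastqReader(b1, b2, make_strategy("L"))
        batches = []
        while True:
            batch = reader.next_batch()
            if not batch:
                break
            batches.append(batch)
        n_blocks = len(b1) // L_SPEC.block_bytes
        assert len(batches) == n_blocks
        assert reader.cs.entries == n_blocks

    @pytest.mark.parametrize("n_threads", [1, 4])
    def test_concurrent_paired_consumption(self, n_threads, paired_data):
        d1, d2 = paired_data
        reader = PairedFastqReader(d1, d2, make_strategy("B"))
        pairs = drain_concurrently(reader, n_threads)
        assert len(pairs) == 200
        names = Counter(a.name for a, _ in pairs)
        assert all(v == 1 for v in names.values())
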