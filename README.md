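# blockfq

Tooling for scalable multithreaded FASTQ ingestion:

* a padded **blocked FASTQ** dialect in which every `B`-byte block starts a
  record and holds exactly `N` records (the final block may hold fewer), so
  a reader can ingest the file with one fixed-size read per critical-section
  entry — and paired files blocked together stay mate-synchronized block by
  block;
* four **synchronized parsing strategies** — `O` (read + parse in the
  critical section), `D` (scan in the CS, parse outside), `B` (batch of
  boundary scans per CS entry, default batch 32), `L` (one `B`-byte read per
  CS entry on blocked input) — for single and paired input, with
  per-critical-section instrumentation;
* three **lock disciplines** (pessimistic, bounded optimistic spin, FIFO
  queueing with per-waiter hand-off) selectable at run time;
* **striped SAM output** (thread id mod S files, default S=16, one lock per
  stripe) and stripe merging;
* a deterministic **synthetic FASTQ generator** and a **weak-scaling
  benchmark harness** with per-thread microsecond timing and a tunable
  stand-in per-read workload.

## CLI

```sh
# deterministic synthetic reads (paired, then 3'-truncated copies)
blockfq generate r1.fastq --n 1000 --length 100 --seed 7 --paired --out2 r2.fastq
blockfq generate s1.fastq --n 1000 --length 100 --seed 7 --truncate-to 50

# convert to / from blocked FASTQ; validate exits 0 iff conforming
blockfq pad r1.fastq b1.fastq --block-bytes 12288 --reads-per-block 44 \
        --in2 r2.fastq --out2 b2.fastq
blockfq validate b1.fastq --block-bytes 12288 --reads-per-block 44
blockfq unpad b1.fastq restored.fastq --block-bytes 12288 --reads-per-block 44

# weak-scaling benchmark (threads grid; total reads scale with T)
blockfq bench --strategy L --lock queueing -t 1 -t 2 -t 4 \
        --block-bytes 12288 --reads-per-block 44 \
        --reads-per-thread 2000 --stripes 16 --workdir bench_out

# concatenate stripe files <prefix>.<i>.sam into one SAM file
blockfq merge bench_out/ws_out_t4 merged.sam --stripes 16
```

`bench` prints a tab-delimited table (per-row max per-thread time, wall
time, throughput in reads/s, CS entries) plus the peak-throughput row;
`--json-out` writes the same table as JSON. Rows slower than
`--time-limit` seconds (default 1200) are marked aborted. Throughput uses
the *maximum per-thread* align time as denominator; whole-job wall time is
reported alongside it.

## Library

```python
from blockfq import (BlockSpec, FastqReader, ParsingStrategy, pad_fastq_paired)

b1, b2 = pad_fastq_paired(open("r1.fastq","rb"), open("r2.fastq","rb"),
                          BlockSpec(block_bytes=12288, reads_per_block=44))
reader = FastqReader(b1, ParsingStrategy(kind="L",
                                         block_spec=BlockSpec(12288, 44)))
for record in reader:          # safe to drain from many threads
    ...
reader.instrumentation         # CS entries / wait / hold (microseconds)
```

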