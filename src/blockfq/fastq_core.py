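"""FASTQ record model, boundary scanning, parsing and serialization.

The on-disk unit is a 4-line record::

    @name[ comment]\\n
    SEQUENCE\\n
    +[plus_text]\\n
    QUALITY[padding spaces]\\n

Trailing spaces on the quality line are *padding* bytes, tolerated on read
and stripped before the sequence/quality length invariant is checked.  This
is the only place padding may appear; it keeps each record at exactly four
newlines so boundary scanning by newline counting works unchanged on padded
files.  Line endings are LF only: a carriage return anywhere makes the
record malformed, because blocked-file arithmetic requires the newline to be
a single byte.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import BinaryIO, Iterator, Optional

__all__ = [
    "FastqRecord",
    "MalformedRecordError",
    "TruncatedRecordError",
    "InfeasiblePaddingError",
    "scan_record_boundary",
    "scan_records",
    "parse_record",
    "serialize_record",
    "iter_records",
]


_WS = re.compile(r"[ \t]")


class MalformedRecordError(ValueError):
    """A 4-line buffer does not satisfy the FASTQ record grammar."""


class TruncatedRecordError(ValueError):
    """End of stream reached mid-record (fewer than four newlines left)."""


class InfeasiblePaddingError(ValueError):
    """Requested padded size is smaller than the record's unpadded size."""


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read.

    ``name`` excludes the leading ``@``; ``comment`` is the text after the
    first whitespace of the header line, if any; ``plus_text`` is the text
    after ``+`` on the third line, if any.  ``sequence`` and ``quality`` are
    byte strings of equal length (quality is stored pad-stripped).
    """

    name: str
    sequence: bytes
    quality: bytes
    comment: Optional[str] = None
    plus_text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise MalformedRecordError("record name must be non-empty")
        if len(self.sequence) != len(self.quality):
            raise MalformedRecordError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)} for record {self.name!r}"
            )

    @property
    def unpadded_size(self) -> int:
        """Serialized byte count with no padding."""
        header = 1 + len(self.name.encode())
        if self.comment is not None:
            header += 1 + len(self.comment.encode())
        plus = 1 + (len(self.plus_text.encode()) if self.plus_text is not None else 0)
        return header + 1 + len(self.sequence) + 1 + plus + 1 + len(self.quality) + 1


def scan_record_boundary(stream: BinaryIO) -> Optional[bytes]:
    """Read the raw bytes of one record (up to and including the 4th newline).

    Returns ``None`` at end of stream.  Raises :class:`TruncatedRecordError`
    if the stream ends mid-record with non-whitespace content remaining.
    This is the newline-counting boundary scan shared by the deferred
    parsing strategies; no validation of record content happens here.
    """
    first = stream.readline()
    if not first:
        return None
    lines = [first]
    for _ in range(3):
        line = stream.readline()
        if line:
            lines.append(line)
    buf = b"".join(lines)
    if len(lines) < 4 or not lines[-1].endswith(b"\n"):
        if not buf.strip():
            return None
        nl = buf.count(b"\n")
        raise TruncatedRecordError(f"stream ended mid-record after {nl} newline(s)")
    return buf


def scan_records(stream: BinaryIO) -> Iterator[bytes]:
    """Yield raw record buffers until end of stream."""
    while True:
        buf = scan_record_boundary(stream)
        if buf is None:
            return
        yield buf


def parse_record(buf: bytes) -> FastqRecord:
    """Parse one raw 4-line buffer into a :class:`FastqRecord`.

    Trailing spaces on the quality line are stripped (padding tolerance).
    """
    if b"\r" in buf:
        raise MalformedRecordError("carriage return in record; LF line endings required")
    lines = buf.split(b"\n")
    if len(lines) != 5 or lines[4] != b"":
        raise MalformedRecordError(
            f"record buffer must contain exactly 4 newline-terminated lines, got {len(lines) - 1}"
        )
    header, seq, plus, qual = lines[:4]
    if not header.startswith(b"@"):
        raise MalformedRecordError(f"header line does not start with '@': {header[:20]!r}")
    if not plus.startswith(b"+"):
        raise MalformedRecordError(f"third line does not start with '+': {plus[:20]!r}")
    name_comment = header[1:].decode()
    parts = _WS.split(name_comment, maxsplit=1)
    name = parts[0]
    comment = parts[1] if len(parts) == 2 else ""
    if b" " in seq or b"\t" in seq:
        raise MalformedRecordError(f"sequence contains whitespace in record {name!r}")
    qual = qual.rstrip(b" ")
    plus_text = plus[1:].decode() or None
    try:
        return FastqRecord(
            name=name,
            sequence=seq,
            quality=qual,
            comment=comment or None,
            plus_text=plus_text,
        )
    except MalformedRecordError as exc:
        raise MalformedRecordError(str(exc)) from None


def serialize_record(rec: FastqRecord, pad_to: Optional[int] = None) -> bytes:
    """Serialize a record, optionally space-padding it to ``pad_to`` bytes.

    Pad spaces are inserted at the end of the quality line, immediately
    before the final newline, so the padded record still has exactly four
    newlines and parses back to ``rec``.
    """
    header = b"@" + rec.name.encode()
    if rec.comment is not None:
        header += b" " + rec.comment.encode()
    plus = b"+" + (rec.plus_text.encode() if rec.plus_text is not None else b"")
    body = header + b"\n" + rec.sequence + b"\n" + plus + b"\n" + rec.quality
    unpadded = len(body) + 1
    if pad_to is None:
        return body + b"\n"
    if pad_to < unpadded:
        raise InfeasiblePaddingError(
            f"cannot pad record {rec.name!r} of {unpadded} bytes down to {pad_to}"
        )
    return body + b" " * (pad_to - unpadded) + b"\n"


def iter_records(stream: BinaryIO) -> Iterator[FastqRecord]:
    """Parse a whole FASTQ stream record by record."""
    for buf in scan_records(stream):
        yield parse_record(buf)


def open_source(data: "bytes | str | BinaryIO") -> BinaryIO:
    """Coerce bytes / path / open stream to a binary stream."""
    if isinstance(data, bytes):
        return io.BytesIO(data)
    if isinstance(data, str):
        return open(data, "rb")
    return data
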