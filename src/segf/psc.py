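"""Paired soft-clipped contig (PSC) extraction.

Each read is reduced to a tracked pair of fixed-length segments: trim
``trim_len`` low-quality bases from both ends, keep the next ``remain_len``
bases from each side (head and tail), discard the middle. A read whose head
and tail land in two different panel genes spans a fusion junction; the
discarded middle absorbs any inserted linker, which is what lets the caller
see "complex" three-part fusions.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple

from .io_formats import Read

DEFAULT_TRIM_LEN = 10
DEFAULT_REMAIN_LEN = 35


class PSCPair(NamedTuple):
    read_id: str
    head: str
    tail: str
    trim_len: int
    remain_len: int


class PSCSkip(NamedTuple):
    read_id: str
    reason: str  # 'too_short' | 'ambiguous_base'


def extract_psc(
    read: Read,
    trim_len: int = DEFAULT_TRIM_LEN,
    remain_len: int = DEFAULT_REMAIN_LEN,
) -> PSCPair | PSCSkip:
    """Extract the head/tail segment pair from one read.

    head = seq[trim_len : trim_len + remain_len];
    tail = seq[L - trim_len - remain_len : L - trim_len].

    Reads shorter than 2*(trim_len + remain_len) are skipped (the two
    segments would overlap or run into the trimmed flanks), as are reads
    with an N inside either segment: an ambiguous base can never survive
    the downstream 100%-identity filter. Skips are data, not errors.
    """
    if trim_len < 0:
        raise ValueError(f"trim_len must be >= 0, got {trim_len}")
    if remain_len < 1:
        raise ValueError(f"remain_len must be >= 1, got {remain_len}")
    length = len(read.seq)
    if length < 2 * (trim_len + remain_len):
        return PSCSkip(read_id=read.id, reason="too_short")
    head = read.seq[trim_len : trim_len + remain_len]
    tail = read.seq[length - trim_len - remain_len : length - trim_len]
    if "N" in head or "N" in tail:
        return PSCSkip(read_id=read.id, reason="ambiguous_base")
    return PSCPair(
        read_id=read.id, head=head, tail=tail, trim_len=trim_len, remain_len=remain_len
    )


def psc_stream(
    reads: Iterable[Read],
    trim_len: int = DEFAULT_TRIM_LEN,
    remain_len: int = DEFAULT_REMAIN_LEN,
    counters: dict | None = None,
) -> Iterator[PSCPair]:
    """Yield PSC pairs for a read stream, tallying skips into ``counters``."""
    for read in reads:
        result = extract_psc(read, trim_len=trim_len, remain_len=remain_len)
        if isinstance(result, PSCSkip):
            if counters is not None:
                counters[f"skipped_{result.reason}"] = (
                    counters.get(f"skipped_{result.reason}", 0) + 1
                )
            continue
        yield result


def dedup_pscs(
    pairs: Iterable[PSCPair], counters: dict | None = None
) -> Iterator[PSCPair]:
    """Drop pairs whose (head, tail) sequence combination was already seen.

    Off by default in the pipeline; identical molecules sequenced under
    distinct read ids otherwise each count toward fusion support.
    """
    seen: set[tuple[str, str]] = set()
    kept = removed = 0
    for pair in pairs:
        key = (pair.head, pair.tail)
        if key in seen:
            removed += 1
            if counters is not None:
                counters["dedup_removed"] = removed
            continue
        seen.add(key)
        kept += 1
        if counters is not None:
            counters["dedup_kept"] = kept
        yield pair
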