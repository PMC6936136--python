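"""Assign mapped alignment records to overlapping genomic bins.

Bin ``i`` on a chromosome spans ``[i*S, (i+1)*S + V)`` in 0-based half-open
coordinates (truncated at the chromosome end), so consecutive bins share
exactly ``V`` bases. The overlap guarantees that any interval of length at
most ``V + 1`` is fully contained in at least one bin, which is what lets a
boundary-spanning transcript be assembled completely in at least one bin.

Records are assigned by their full reference span (skipped intronic ``N``
segments included), not by start position alone, so junction evidence
reaches every bin an isoform could be assembled in. Sequence payloads are
stripped before shuffling because assembly does not use them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import total_ordering
from typing import Iterable, Iterator

from splicebin.align import AlignmentRecord

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_BIN_OVERLAP = 100_000


class BinningError(ValueError):
    pass


@total_ordering
@dataclass(frozen=True)
class BinName:
    chrom: str
    index: int

    def __str__(self) -> str:
        return f"{self.chrom}:{self.index}"

    def __lt__(self, other: "BinName") -> bool:
        return (self.chrom, self.index) < (other.chrom, other.index)

    @classmethod
    def parse(cls, text: str) -> "BinName":
        chrom, _, idx = text.rpartition(":")
        if not chrom or not idx.isdigit():
            raise BinningError(f"cannot parse bin name {text!r}")
        return cls(chrom, int(idx))


@dataclass(frozen=True)
class BinScheme:
    """Bin geometry: core size S, right-side overlap extension V < S."""

    bin_size: int = DEFAULT_BIN_SIZE
    overlap: int = DEFAULT_BIN_OVERLAP
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise BinningError(f"bin_size must be positive, got {self.bin_size}")
        if not 0 <= self.overlap < self.bin_size:
            raise BinningError(
                f"overlap must satisfy 0 <= V < S, got V={self.overlap}, S={self.bin_size}"
            )

    def n_bins(self, chrom: str) -> int:
        length = self._chrom_length(chrom)
        return max(1, math.ceil(length / self.bin_size))

    def _chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise BinningError(f"unknown chromosome {chrom!r}") from None

    def interval(self, name: BinName) -> tuple[int, int]:
        """0-based half-open span of a bin, truncated at the chromosome end."""
        length = self._chrom_length(name.chrom)
        start = name.index * self.bin_size
        end = min((name.index + 1) * self.bin_size + self.overlap, length)
        if start >= length:
            raise BinningError(f"bin {name} starts beyond chromosome end {length}")
        return start, end

    def is_last(self, name: BinName) -> bool:
        return name.index == self.n_bins(name.chrom) - 1

    def all_bins(self) -> Iterator[BinName]:
        for chrom in self.chrom_lengths:
            for i in range(self.n_bins(chrom)):
                yield BinName(chrom, i)


def reference_span(record: AlignmentRecord) -> tuple[int, int]:
    """0-based half-open genomic interval consumed by a mapped record.

    Soft clips and insertions consume no reference; M, D and N do.
    """
    if not record.is_mapped:
        raise BinningError(f"record {record.qname!r} is unmapped and has no reference span")
    start = record.pos - 1
    return start, start + record.reference_length()


def bins_for_record(record: AlignmentRecord, scheme: BinScheme) -> list[BinName]:
    """Exactly the bins whose spans intersect the record's reference span."""
    start, end = reference_span(record)
    assert record.chrom is not None
    n = scheme.n_bins(record.chrom)
    lo = max(0, (start - scheme.overlap) // scheme.bin_size)
    hi = min(n - 1, (end - 1) // scheme.bin_size)
    names = [BinName(record.chrom, i) for i in range(lo, hi + 1)]
    if not names:
        raise BinningError(f"record {record.qname!r} span [{start},{end}) hit no bins")
    return names


def strip_record(record: AlignmentRecord) -> AlignmentRecord:
    """Drop the sequence/quality payload; all other fields are unchanged."""
    if record.seq == "*" and record.qual == "*":
        return record
    return replace(record, seq="*", qual="*")


def emit_binned(
    records: Iterable[AlignmentRecord], scheme: BinScheme
) -> Iterator[tuple[BinName, AlignmentRecord]]:
    """Per-record multi-bin emission; unmapped records are dropped."""
    for record in records:
        if not record.is_mapped:
            continue
        stripped = strip_record(record)
        for name in bins_for_record(record, scheme):
            yield name, stripped


def _record_sort_key(record: AlignmentRecord) -> tuple:
    return (record.pos, record.qname, record.flag, record.cigar_string)


def partition_records(
    emissions: Iterable[tuple[BinName, AlignmentRecord]]
) -> dict[BinName, list[AlignmentRecord]]:
    """Group emitted records by bin and coordinate-sort within each bin.

    The per-bin sort key (pos, qname, flag, cigar) is a total order over
    distinct records, so the grouped output is independent of the input
    arrival order and of the degree of parallelism upstream.
    """
    groups: dict[BinName, list[AlignmentRecord]] = {}
    for name, record in emissions:
        groups.setdefault(name, []).append(record)
    for records in groups.values():
        records.sort(key=_record_sort_key)
    return dict(sorted(groups.items()))
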