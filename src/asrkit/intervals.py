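"""Genomic interval arithmetic in 1-based inclusive coordinates.

All coordinates follow the GFF convention: ``start`` and ``end`` are
1-based and both inclusive, so an interval's length is
``end - start + 1``. No half-open conversion is exposed anywhere in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["GenomicInterval", "interval_length", "union_length", "merge_intervals"]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A closed genomic interval on one sequence.

    Parameters
    ----------
    seqid
        Sequence (chromosome/scaffold) identifier.
    start, end
        1-based inclusive coordinates; ``1 <= start <= end``.
    strand
        ``"+"``, ``"-"`` or ``"."``. Strand never affects length
        arithmetic; it is carried for provenance only.
    """

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return end - start + 1


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals, per seqid.

    Returns a list of disjoint intervals sorted by (seqid, start).
    Strand is discarded in the merged output (set to ``"."``): bases of
    one gene are counted once regardless of strand annotation.
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seqid, []).append(iv)

    merged: list[GenomicInterval] = []
    for seqid in sorted(by_seq):
        ivs = sorted(by_seq[seqid], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(seqid, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(seqid, cur_start, cur_end))
    return merged


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct genomic positions covered by >= 1 interval.

    Seqid-aware: identical coordinates on different sequences count
    separately. Strand is ignored. An empty collection has union 0.
    """
    return sum(iv.length for iv in merge_intervals(intervals))
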