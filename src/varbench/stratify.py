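"""Interval algebra for stratification regions.

A benchmarking run scores variants only inside an evaluation region —
typically the intersection of a truth set's high-confidence regions with a
region of interest (ROI) such as "coding exons of clinically relevant genes
± 20 bp of splice site". Negative-agreement metrics additionally need the
*total base count* of that region, so the region container here keeps its
intervals merged and sorted at all times and derives the base count from
them.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Book-ended intervals (``end == start`` of the next) are coalesced, matching
``bedtools merge`` semantics.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field


Interval = tuple[str, int, int]


@dataclass(frozen=True)
class RegionSet:
    """A merged, sorted set of genomic intervals.

    Construct via :func:`merge` (or the classmethods) rather than directly,
    so the invariants — non-overlapping, ``start < end``, sorted by
    ``(chrom, start)`` — always hold.
    """

    intervals: tuple[Interval, ...] = field(default=())

    @property
    def total_bases(self) -> int:
        """Sum of interval lengths; the region-of-interest base count."""
        return sum(end - start for _, start, end in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if ``[start, end)`` on ``chrom`` lies fully inside one interval.

        Zero-length queries (``start == end``) test point containment of
        ``start``.
        """
        keys = [(c, s) for c, s, _ in self.intervals]
        i = bisect.bisect_right(keys, (chrom, start)) - 1
        if i < 0:
            return False
        c, s, e = self.intervals[i]
        if c != chrom:
            return False
        return s <= start and max(end, start + 1) <= e

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position falls inside the region."""
        return self.contains_interval(chrom, pos0, pos0 + 1)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, _, _ in self.intervals:
            seen.setdefault(c)
        return list(seen)


def merge(intervals: Iterable[Interval]) -> RegionSet:
    """Union raw intervals into a :class:`RegionSet`.

    Overlapping or book-ended intervals on the same chromosome coalesce.
    Raises ``ValueError`` on ``start >= end`` or negative coordinates.
    """
    items = sorted(intervals)
    merged: list[Interval] = []
    for chrom, start, end in items:
        if start < 0 or start >= end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return RegionSet(tuple(merged))


def pad(regions: RegionSet, flank: int,
        contig_lengths: dict[str, int] | None = None) -> RegionSet:
    """Extend every interval by ``flank`` bp on both sides and re-merge.

    The canonical use is extending exons by 20 bp to include canonical and
    non-canonical splice sites. Starts clamp at 0; ends clamp at the contig
    length when ``contig_lengths`` is given.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for chrom, start, end in regions:
        lo = max(0, start - flank)
        hi = end + flank
        if contig_lengths and chrom in contig_lengths:
            hi = min(hi, contig_lengths[chrom])
        out.append((chrom, lo, hi))
    return merge(out)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Standard interval intersection of two merged sets (commutative)."""
    out: list[Interval] = []
    ai = bi = 0
    xs, ys = a.intervals, b.intervals
    while ai < len(xs) and bi < len(ys):
        ca, sa, ea = xs[ai]
        cb, sb, eb = ys[bi]
        if ca != cb:
            if ca < cb:
                ai += 1
            else:
                bi += 1
            continue
        lo, hi = max(sa, sb), min(ea, eb)
        if lo < hi:
            out.append((ca, lo, hi))
        if ea <= eb:
            ai += 1
        else:
            bi += 1
    return RegionSet(tuple(out))


def union(a: RegionSet, b: RegionSet) -> RegionSet:
    return merge(list(a) + list(b))


def build_clinical_roi(pathogenic_sites: Iterable[tuple[str, int]],
                       exons: RegionSet,
                       flank: int = 20,
                       deep_intronic: RegionSet | None = None) -> RegionSet:
    """Construct the clinically relevant region set.

    Selects exon intervals containing at least one known pathogenic site
    (sites given as 1-based ``(chrom, pos)``), pads the selected intervals by
    ``flank`` bp to pick up splice sites, and unions in deep-intronic
    intervals (unpadded). Deterministic; an empty result is allowed.
    """
    # 1-based site -> 0-based point; the off-by-one lives here and only here.
    points = {(chrom, pos - 1) for chrom, pos in pathogenic_sites}
    selected = [
        (chrom, start, end)
        for chrom, start, end in exons
        if any(c == chrom and start <= p < end for c, p in points)
    ]
    roi = pad(merge(selected), flank)
    if deep_intronic:
        roi = union(roi, deep_intronic)
    return roi
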