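"""Partitioning the genome into segments.

Breakpoints come from two sources: the start and end of each interval of
strictly overlapping discordant alignment parts (so the two ends of a
discordant pair land in different segments), and the starting point of each
zero-coverage run (so genes separated by unexpressed sequence fall into
separate connected components of the segment graph).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alignments import AlignedPart


@dataclass(frozen=True)
class Segment:
    """A genome interval; ``id`` increases in (chromosome, start) order."""

    id: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True, order=True)
class SegmentEnd:
    """One endpoint of a segment: head = lower coordinate, tail = higher."""

    segment_id: int
    side: str

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"bad side {self.side!r}")


def merge_discordant_intervals(
    discordant_parts: Iterable[AlignedPart],
) -> list[tuple[str, int, int]]:
    """Maximal intervals of strictly overlapping discordant part spans.

    Book-ended spans ([100,200) and [200,300)) are *not* merged: only spans
    that share at least one base coalesce.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in discordant_parts:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:  # strict overlap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def _zero_coverage_starts(
    spans: Sequence[tuple[int, int]], chrom_len: int
) -> list[int]:
    """Start of each maximal zero-coverage run, given covered spans."""
    if not spans:
        return [0]
    events = sorted(spans)
    starts: list[int] = []
    cov_end = 0  # end of the covered prefix seen so far
    for s, e in events:
        if s > cov_end:
            starts.append(cov_end)
        cov_end = max(cov_end, e)
    if cov_end < chrom_len:
        starts.append(cov_end)
    return starts


def find_breakpoints(
    all_parts: Iterable[AlignedPart],
    discordant_intervals: Iterable[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
) -> dict[str, list[int]]:
    """Per-chromosome sorted breakpoint positions.

    Breakpoints are the endpoints of discordant-pileup intervals plus the
    start of every zero-coverage run.  Coverage counts every aligned part
    (concordant and discordant); the intronic gap between split parts of a
    spliced read contributes no coverage.  Positions 0 and the chromosome
    length are implicit boundaries and excluded.
    """
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for p in all_parts:
        if p.chrom not in chrom_lengths:
            raise ValueError(f"part on unknown chromosome {p.chrom!r}")
        if p.end > chrom_lengths[p.chrom]:
            raise ValueError(
                f"part [{p.start},{p.end}) beyond length of {p.chrom} "
                f"({chrom_lengths[p.chrom]}): inconsistent header"
            )
        spans[p.chrom].append((p.start, p.end))

    bps: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for chrom, s, e in discordant_intervals:
        bps[chrom].update((s, e))
    for chrom, length in chrom_lengths.items():
        bps[chrom].update(_zero_coverage_starts(spans[chrom], length))
    return {
        chrom: sorted(p for p in positions if 0 < p < chrom_lengths[chrom])
        for chrom, positions in bps.items()
    }


def partition_genome(
    breakpoints: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
) -> list[Segment]:
    """Tile each chromosome into segments delimited by its breakpoints.

    Chromosomes are taken in the order of ``chrom_lengths`` (the alignment
    header order); ids increase along that order.
    """
    segments: list[Segment] = []
    sid = 0
    for chrom, length in chrom_lengths.items():
        cuts = sorted({p for p in breakpoints.get(chrom, ()) if 0 < p < length})
        bounds = [0, *cuts, length]
        for s, e in zip(bounds, bounds[1:]):
            segments.append(Segment(id=sid, chrom=chrom, start=s, end=e))
            sid += 1
    return segments


class SegmentIndex:
    """Locate the segment containing a genome position, by binary search."""

    def __init__(self, segments: Sequence[Segment]):
        self.segments = list(segments)
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in self._by_chrom.items():
            segs.sort(key=lambda s: s.start)
            self._starts[chrom] = [s.start for s in segs]

    def locate(self, chrom: str, pos: int) -> Segment | None:
        segs = self._by_chrom.get(chrom)
        if not segs:
            return None
        i = bisect_right(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        seg = segs[i]
        return seg if seg.start <= pos < seg.end else None

    def __getitem__(self, segment_id: int) -> Segment:
        return self.segments[segment_id]

    def __len__(self) -> int:
        return len(self.segments)


def write_bed(segments: Iterable[Segment], path: str) -> None:
    """Export segments as BED (0-based half-open), for debugging."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\tseg{seg.id}\n")
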