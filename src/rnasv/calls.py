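"""Extracting TSV calls from an optimally rearranged segment graph.

A TSV is an edge that is incompatible with the reference arrangement but
compatible with its component's optimal arrangement: a junction the data
support that the reference genome cannot explain.  Each call is a pair of
oriented breakpoints.  The side label records which flank of the junction is
retained: ``tail`` means the sequence upstream (left, lower coordinates) of
the breakpoint is joined into the variant ('+' in BEDPE output), ``head``
means the downstream flank is ('-').
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .gsg import Arrangement, Edge, EndpointPair, SegmentGraph, compatible
from .ilp import Solution
from .segmentation import HEAD, TAIL, Segment


@dataclass(frozen=True, order=True)
class Breakpoint:
    chrom: str
    pos: int  # junction coordinate, 0-based half-open: a tail-side breakpoint
    # at pos means bases < pos are retained; a head-side one means bases >= pos
    side: str

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"bad side {self.side!r}")


@dataclass(frozen=True)
class TSVCall:
    bp1: Breakpoint
    bp2: Breakpoint
    support: int
    component_id: int = -1

    def __post_init__(self) -> None:
        if (self.bp2.chrom, self.bp2.pos) < (self.bp1.chrom, self.bp1.pos):
            raise ValueError("breakpoints must be in lexicographic order")

    @classmethod
    def ordered(cls, bp1: Breakpoint, bp2: Breakpoint, support: int, component_id: int = -1) -> "TSVCall":
        if (bp2.chrom, bp2.pos) < (bp1.chrom, bp1.pos):
            bp1, bp2 = bp2, bp1
        return cls(bp1=bp1, bp2=bp2, support=support, component_id=component_id)


def refine_breakpoint(edge: Edge, segment_a: Segment, segment_b: Segment, *, min_shared: int = 3) -> tuple[int, int]:
    """Exact breakpoint coordinates for both sides of an edge.

    If at least ``min_shared`` supporting alignments share a junction-side
    coordinate (the read-part end on a tail side, the start on a head side),
    that coordinate is the breakpoint; the most frequent such coordinate
    wins, ties going to the smaller one.  Otherwise the segment boundary on
    that side is reported.
    """
    out = []
    for end, seg, coords in (
        (edge.end_a, segment_a, edge.support_a),
        (edge.end_b, segment_b, edge.support_b),
    ):
        fallback = seg.end if end.side == TAIL else seg.start
        best = None
        for coord, cnt in Counter(coords).items():
            if cnt >= min_shared and (best is None or (-cnt, coord) < (-best[1], best[0])):
                best = (coord, cnt)
        out.append(best[0] if best is not None else fallback)
    return out[0], out[1]


def _novel_adjacency_edges(gc: SegmentGraph, sol: Solution) -> list[EndpointPair]:
    """Satisfied discordant edges, one per realized novel adjacency.

    A rearranged genome is a single sequence, so each junction it creates is
    one physical adjacency — but spliced and mate-gapped reads also connect
    segments *across* a junction (splice-like pass-through), yielding extra
    satisfied discordant edges that straddle the same junction.  Those
    redundant edges span a wider stretch of the arrangement: their endpoint
    rank interval contains the direct junction edge's.  Accepting edges
    innermost first (shortest rank interval, then higher support) and
    suppressing any edge whose interval contains an accepted edge's
    interval keeps one call per junction.
    """
    ranks = sol.arrangement.order
    candidates = [
        k for k in sol.satisfied if not gc.edges[k].reference_concordant
    ]

    def interval(k: EndpointPair) -> tuple[int, int]:
        lo, hi = sorted((ranks[k[0].segment_id], ranks[k[1].segment_id]))
        return lo, hi

    candidates.sort(
        key=lambda k: (interval(k)[1] - interval(k)[0], -gc.edges[k].raw_count, k)
    )
    accepted: list[tuple[EndpointPair, tuple[int, int]]] = []
    for k in candidates:
        lo, hi = interval(k)
        if any(lo <= alo and ahi <= hi for _, (alo, ahi) in accepted):
            continue
        accepted.append((k, (lo, hi)))
    return sorted(k for k, _ in accepted)


def call_tsvs(
    g: SegmentGraph,
    solutions: Sequence[tuple[SegmentGraph, Solution]],
    *,
    min_shared: int = 3,
) -> list[TSVCall]:
    """Initially-discordant edges realized by the optimal arrangements.

    Every reported edge is re-checked to be compatible with its component's
    arrangement and incompatible with the reference arrangement; of the
    satisfied discordant edges explaining one junction, only the direct
    (highest-support, innermost) one is reported.
    """
    reference = Arrangement.reference(g.segments)
    by_id = {s.id: s for s in g.segments}
    calls: list[TSVCall] = []
    for comp_id, (gc, sol) in enumerate(solutions):
        for key in _novel_adjacency_edges(gc, sol):
            edge = gc.edges[key]
            assert compatible(key, sol.arrangement), "satisfied edge fails its own arrangement"
            assert not compatible(key, reference), "reference-compatible edge marked discordant"
            seg_a = by_id[edge.end_a.segment_id]
            seg_b = by_id[edge.end_b.segment_id]
            pos_a, pos_b = refine_breakpoint(edge, seg_a, seg_b, min_shared=min_shared)
            calls.append(
                TSVCall.ordered(
                    Breakpoint(seg_a.chrom, pos_a, edge.end_a.side),
                    Breakpoint(seg_b.chrom, pos_b, edge.end_b.side),
                    support=edge.raw_count,
                    component_id=comp_id,
                )
            )
    calls.sort(key=lambda c: (c.bp1, c.bp2, -c.support))
    return calls


def _strand(side: str) -> str:
    return "+" if side == TAIL else "-"


def _interval(bp: Breakpoint) -> tuple[int, int]:
    # tail: last retained base is pos-1; head: first retained base is pos
    return (max(bp.pos - 1, 0), bp.pos) if bp.side == TAIL else (bp.pos, bp.pos + 1)


def write_predictions(calls: Iterable[TSVCall], out: IO[str]) -> None:
    """Write calls as BEDPE: one junction per line, deterministically sorted.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score(support)
    strand1 strand2, 0-based half-open, '+' = upstream flank retained.
    """
    out.write(
        "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tstrand1\tstrand2\n"
    )
    ordered = sorted(calls, key=lambda c: (c.bp1, c.bp2, -c.support))
    for i, c in enumerate(ordered):
        s1, e1 = _interval(c.bp1)
        s2, e2 = _interval(c.bp2)
        out.write(
            f"{c.bp1.chrom}\t{s1}\t{e1}\t{c.bp2.chrom}\t{s2}\t{e2}\t"
            f"tsv_{i}\t{c.support}\t{_strand(c.bp1.side)}\t{_strand(c.bp2.side)}\n"
        )


def read_predictions(path: str) -> list[TSVCall]:
    """Read calls back from the BEDPE produced by :func:`write_predictions`."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            side1 = TAIL if f[8].strip() == "+" else HEAD
            side2 = TAIL if f[9].strip() == "+" else HEAD
            pos1 = int(f[2]) if side1 == TAIL else int(f[1])
            pos2 = int(f[5]) if side2 == TAIL else int(f[4])
            calls.append(
                TSVCall.ordered(
                    Breakpoint(f[0], pos1, side1),
                    Breakpoint(f[3], pos2, side2),
                    support=int(f[7]),
                )
            )
    return calls
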