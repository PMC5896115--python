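"""The genome segment graph (GSG).

Vertices are the two endpoints (head/tail) of every genome segment.  Each
read connection contributes an edge between two segment ends such that
traversing the segments along the edge spells a sequence onto which the read
aligns concordantly.  Multi-edges collapse into one weighted edge; the weight
of a reference-discordant edge is its support count times the discordant
weight coefficient alpha (the assumed normal/tumor transcript ratio).

An *arrangement* is a permutation of segments plus a per-segment orientation
bit.  Edge compatibility with an arrangement follows the endpoint-orientation
identity: for edge (u_i, v_j),

    1 - f(v_j) = 1[pi(v) < pi(u)] = f(u_i),

with f(u_head) = y_u and f(u_tail) = 1 - y_u.  The reference arrangement is
identity order, all segments head-first, with segments additionally grouped
by chromosome: an edge joining two chromosomes can never be realized by the
unrearranged reference, mirroring the same-chromosome requirement of
pair-level concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignments import AlignedPart, PairAlignment, FORWARD
from .segmentation import HEAD, TAIL, Segment, SegmentEnd, SegmentIndex

EndpointPair = tuple[SegmentEnd, SegmentEnd]


@dataclass
class Arrangement:
    """A permutation of segments plus per-segment orientation bits.

    ``order`` maps segment id -> rank; ``orient`` maps segment id -> 1 for
    head-first (forward) or 0 for inverted.  ``group`` optionally maps each
    segment to the sequence (chromosome) it belongs to; edges across groups
    are incompatible.  Arrangements produced by the optimizer have no groups:
    a rearranged component is a single sequence.
    """

    order: dict[int, int]
    orient: dict[int, int]
    group: dict[int, object] | None = None

    @classmethod
    def reference(cls, segments: Sequence[Segment], *, split_chromosomes: bool = True) -> "Arrangement":
        """Identity order, all head-first, grouped by chromosome."""
        order = {s.id: i for i, s in enumerate(sorted(segments, key=lambda s: s.id))}
        orient = {s.id: 1 for s in segments}
        group = {s.id: s.chrom for s in segments} if split_chromosomes else None
        return cls(order=order, orient=orient, group=group)

    def reversed_flipped(self) -> "Arrangement":
        """The reverse-complement arrangement: reversed order, all bits flipped."""
        n = len(self.order)
        return Arrangement(
            order={u: n - 1 - r for u, r in self.order.items()},
            orient={u: 1 - b for u, b in self.orient.items()},
            group=dict(self.group) if self.group is not None else None,
        )

    def f(self, end: SegmentEnd) -> int:
        y = self.orient[end.segment_id]
        return y if end.side == HEAD else 1 - y


def compatible(edge_endpoints: EndpointPair, arr: Arrangement) -> bool:
    """Is the adjacency asserted by this edge realized by the arrangement?"""
    u_i, v_j = edge_endpoints
    for end in (u_i, v_j):
        if end.segment_id not in arr.order:
            raise KeyError(f"segment {end.segment_id} not in arrangement")
    if arr.group is not None and arr.group[u_i.segment_id] != arr.group[v_j.segment_id]:
        return False
    ind = 1 if arr.order[v_j.segment_id] < arr.order[u_i.segment_id] else 0
    return arr.f(u_i) == ind and 1 - arr.f(v_j) == ind


@dataclass
class Edge:
    """A collapsed, weighted connection between two segment ends.

    ``support_a`` / ``support_b`` record, per supporting connection, the
    junction-side coordinate of the read part at each endpoint (part end for
    a tail side, part start for a head side); breakpoint refinement uses
    them.
    """

    end_a: SegmentEnd
    end_b: SegmentEnd
    raw_count: int = 0
    reference_concordant: bool = False
    support_a: list[int] = field(default_factory=list)
    support_b: list[int] = field(default_factory=list)

    @property
    def key(self) -> EndpointPair:
        return (self.end_a, self.end_b)

    def weight(self, alpha: float) -> float:
        return self.raw_count * (1.0 if self.reference_concordant else alpha)


@dataclass
class SegmentGraph:
    """Weighted undirected graph over segment ends."""

    segments: list[Segment]
    edges: dict[EndpointPair, Edge]
    alpha: float = 1.0

    def segment(self, segment_id: int) -> Segment:
        return self._by_id[segment_id]

    @property
    def _by_id(self) -> dict[int, Segment]:
        return {s.id: s for s in self.segments}

    def discordant_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if not e.reference_concordant]

    def total_weight(self) -> float:
        return sum(e.weight(self.alpha) for e in self.edges.values())


def _canonical(
    end_a: SegmentEnd, end_b: SegmentEnd, coord_a: int, coord_b: int
) -> tuple[SegmentEnd, SegmentEnd, int, int]:
    if end_a.segment_id > end_b.segment_id:
        return end_b, end_a, coord_b, coord_a
    return end_a, end_b, coord_a, coord_b


def edge_for_connection(
    part_a: AlignedPart,
    part_b: AlignedPart,
    index: SegmentIndex,
) -> tuple[SegmentEnd, SegmentEnd, int, int] | None:
    """Endpoint pair (plus junction coordinates) for one read connection.

    ``part_a`` precedes ``part_b`` in read layout; orientations are as
    aligned, in mate-pair convention (an intra-end split connection must
    flip ``part_b``'s orientation first; :func:`edges_from_pair` does).
    The side at each endpoint follows the part orientation: a forward part
    exits/enters through its segment's tail, a reverse part through its
    head.  Connections falling inside a single segment carry no
    rearrangement signal and yield ``None``.
    """
    ends: list[SegmentEnd] = []
    coords: list[int] = []
    for part in (part_a, part_b):
        if part.is_forward:
            side, coord = TAIL, part.end
            anchor = part.end - 1
        else:
            side, coord = HEAD, part.start
            anchor = part.start
        seg = index.locate(part.chrom, anchor)
        if seg is None:
            return None
        ends.append(SegmentEnd(seg.id, side))
        coords.append(coord)
    if ends[0].segment_id == ends[1].segment_id:
        return None
    return _canonical(ends[0], ends[1], coords[0], coords[1])


def _flip(part: AlignedPart) -> AlignedPart:
    return AlignedPart(
        chrom=part.chrom,
        start=part.start,
        end=part.end,
        orientation="-" if part.is_forward else "+",
        query_offset=part.query_offset,
    )


def edges_from_pair(
    pair: PairAlignment, index: SegmentIndex
) -> list[tuple[SegmentEnd, SegmentEnd, int, int]]:
    """All endpoint connections generated by one read pair.

    One connection per consecutive split-part pair within each end, plus one
    mate connection between the last part of the first end and the first
    part of the second end.  Split connections continue in the same read
    orientation, so the downstream part is flipped into mate convention
    before the side rule applies.
    """
    out = []
    for end in (pair.first, pair.second):
        for a, b in zip(end.parts, end.parts[1:]):
            conn = edge_for_connection(a, _flip(b), index)
            if conn is not None:
                out.append(conn)
    conn = edge_for_connection(pair.first.parts[-1], pair.second.parts[0], index)
    if conn is not None:
        out.append(conn)
    return out


def build_graph(
    pairs: Iterable[PairAlignment],
    segments: Sequence[Segment],
    alpha: float = 1.0,
) -> SegmentGraph:
    """Aggregate read connections into a weighted genome segment graph."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    index = SegmentIndex(segments)
    reference = Arrangement.reference(segments)
    edges: dict[EndpointPair, Edge] = {}
    for pair in pairs:
        for end_a, end_b, coord_a, coord_b in edges_from_pair(pair, index):
            key = (end_a, end_b)
            edge = edges.get(key)
            if edge is None:
                edge = Edge(
                    end_a=end_a,
                    end_b=end_b,
                    reference_concordant=compatible(key, reference),
                )
                edges[key] = edge
            edge.raw_count += 1
            edge.support_a.append(coord_a)
            edge.support_b.append(coord_b)
    return SegmentGraph(segments=list(segments), edges=edges, alpha=alpha)


def _discordant_adjacency(g: SegmentGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for e in g.discordant_edges():
        u, v = e.end_a.segment_id, e.end_b.segment_id
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def _runs(segment_ids: set[int], by_id: Mapping[int, Segment], max_gap: int = 2) -> list[tuple[int, int]]:
    """Group discordant-incident segments into genome-consecutive runs.

    Segments on one chromosome whose ids differ by at most ``max_gap`` fall
    into one run; a run is reported as its (min id, max id) span.
    """
    runs: list[tuple[int, int]] = []
    for sid in sorted(segment_ids):
        if runs and sid - runs[-1][1] <= max_gap and by_id[sid].chrom == by_id[runs[-1][1]].chrom:
            runs[-1] = (runs[-1][0], sid)
        else:
            runs.append((sid, sid))
    return runs


def _interleaving_keys(g: SegmentGraph) -> set[EndpointPair]:
    """Edges to drop under the interleaving filter.

    Discordant edges between two runs of genome-consecutive segments are
    grouped by their side-type signature — which end of each run they
    attach to.  A single rearrangement joining the two regions produces at
    most two signatures: one junction gives one; a block excised from one
    region and traversed inside the other's transcript gives the
    (tail, head) + (head, tail) pair; an inversion spanning the runs gives
    (tail, tail) + (head, head).  Spliced or mate-gapped pass-through
    evidence of a junction repeats its signature and never adds one.
    Three or more signatures between one pair of runs mean the regions are
    woven together with inconsistent orientations — the interleaved-exon
    pattern typical of multi-mapping and alignment artifacts — and all
    discordant edges between the two runs are removed.
    """
    by_id = {s.id: s for s in g.segments}
    disc = g.discordant_edges()
    incident = {e.end_a.segment_id for e in disc} | {e.end_b.segment_id for e in disc}
    runs = _runs(incident, by_id)
    run_of = {}
    for ri, (lo, hi) in enumerate(runs):
        for sid in range(lo, hi + 1):
            run_of[sid] = ri

    pair_edges: dict[tuple[int, int], list[Edge]] = {}
    for e in disc:
        ra = run_of.get(e.end_a.segment_id)
        rb = run_of.get(e.end_b.segment_id)
        if ra is None or rb is None or ra == rb:
            continue
        pair_edges.setdefault((min(ra, rb), max(ra, rb)), []).append(e)

    drop: set[EndpointPair] = set()
    for (ra, rb), es in pair_edges.items():
        # canonical edge order (end_a in the lower-id segment) also puts
        # end_a in the lower run, so the signature is well defined
        signatures = {(e.end_a.side, e.end_b.side) for e in es}
        if len(signatures) >= 3:
            drop.update(e.key for e in es)
    return drop


def filter_graph(g: SegmentGraph, theta: int = 5, gamma: int = 5) -> SegmentGraph:
    """Remove obvious false-positive edges.

    Applied in order: (1) edges with read support below ``theta`` (the raw
    count, so theta does not interact with alpha); (2) all discordant edges
    of segments with more than ``gamma`` distinct discordant neighbor
    segments (low-mappability artifacts; the concordant backbone survives);
    (3) interleaving discordant edges between two runs of consecutive
    segments.
    """
    if theta < 0 or gamma < 1:
        raise ValueError("need theta >= 0 and gamma >= 1")
    edges = {k: e for k, e in g.edges.items() if e.raw_count >= theta}
    g1 = SegmentGraph(segments=g.segments, edges=edges, alpha=g.alpha)

    adj = _discordant_adjacency(g1)
    offending = {sid for sid, nbrs in adj.items() if len(nbrs) > gamma}
    edges = {
        k: e
        for k, e in g1.edges.items()
        if e.reference_concordant
        or (e.end_a.segment_id not in offending and e.end_b.segment_id not in offending)
    }
    g2 = SegmentGraph(segments=g.segments, edges=edges, alpha=g.alpha)

    drop = _interleaving_keys(g2)
    edges = {k: e for k, e in g2.edges.items() if k not in drop}
    return SegmentGraph(segments=g.segments, edges=edges, alpha=g.alpha)


def write_graph_tsv(g: SegmentGraph, path: str) -> None:
    """Serialize edges as TSV: seg_a side_a seg_b side_b raw_count weight concordant."""
    with open(path, "w") as fh:
        fh.write("seg_a\tside_a\tseg_b\tside_b\traw_count\tweight\tconcordant\n")
        for key in sorted(g.edges):
            e = g.edges[key]
            fh.write(
                f"{e.end_a.segment_id}\t{e.end_a.side}\t{e.end_b.segment_id}\t"
                f"{e.end_b.side}\t{e.raw_count}\t{e.weight(g.alpha):g}\t"
                f"{int(e.reference_concordant)}\n"
            )
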