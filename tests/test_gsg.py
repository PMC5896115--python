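"""Genome segment graph: edge construction, compatibility, filters."""

import numpy as np
import pytest

from rnasv.alignments import AlignedPart, PairAlignment, ReadAlignment
from rnasv.gsg import (
    Arrangement,
    build_graph,
    compatible,
    edge_for_connection,
    edges_from_pair,
    filter_graph,
)
from rnasv.segmentation import HEAD, TAIL, Segment, SegmentEnd, SegmentIndex
from conftest import random_component, random_arrangement

# ten 100-bp segments on one chromosome
SEGMENTS = [Segment(id=i, chrom="chr1", start=i * 100, end=(i + 1) * 100) for i in range(10)]
INDEX = SegmentIndex(SEGMENTS)
REF = Arrangement.reference(SEGMENTS)


def part(seg_idx, ori, lo=20, hi=80, chrom="chr1", off=0):
    base = seg_idx * 100
    return AlignedPart(chrom, base + lo, base + hi, ori, query_offset=off)


def pair_of(p1, p2):
    return PairAlignment("r", ReadAlignment.of([p1]), ReadAlignment.of([p2]))


class TestEdgeForConnection:
    @pytest.mark.parametrize(
        "ori_a, ori_b, sides",
        [
            ("+", "-", (TAIL, HEAD)),  # innie pair: right end of u to left end of v
            ("+", "+", (TAIL, TAIL)),  # both forward: u tail to v tail
            ("-", "-", (HEAD, HEAD)),  # both reverse: u head to v head
            ("-", "+", (HEAD, TAIL)),  # facing away: u head to v tail
        ],
    )
    def test_orientation_cases(self, ori_a, ori_b, sides):
        got = edge_for_connection(part(2, ori_a), part(5, ori_b), INDEX)
        end_a, end_b, _, _ = got
        assert (end_a.segment_id, end_b.segment_id) == (2, 5)
        assert (end_a.side, end_b.side) == sides

    def test_same_segment_yields_no_edge(self):
        assert edge_for_connection(part(3, "+", 10, 40), part(3, "-", 60, 90), INDEX) is None

    def test_canonicalization_swaps_to_ascending_ids(self):
        got = edge_for_connection(part(7, "+"), part(2, "-"), INDEX)
        end_a, end_b, _, _ = got
        assert end_a.segment_id == 2 and end_b.segment_id == 7

    def test_role_swap_gives_same_edge(self):
        a, b = part(2, "+"), part(5, "-")
        e1 = edge_for_connection(a, b, INDEX)
        e2 = edge_for_connection(b, a, INDEX)
        assert e1[:2] == e2[:2]

    def test_junction_coordinates_follow_sides(self):
        end_a, end_b, coord_a, coord_b = edge_for_connection(part(2, "+"), part(5, "-"), INDEX)
        assert coord_a == 280  # tail side: part end
        assert coord_b == 520  # head side: part start


class TestEdgesFromPair:
    def test_unsplit_concordant_pair_gives_tail_head(self):
        conns = edges_from_pair(pair_of(part(2, "+"), part(5, "-")), INDEX)
        assert len(conns) == 1
        end_a, end_b, _, _ = conns[0]
        assert (end_a.side, end_b.side) == (TAIL, HEAD)

    def test_split_end_plus_mate_gives_two_connections(self):
        # mate1 split across segments 1 and 3 (spliced), mate2 in segment 5
        first = ReadAlignment.of([part(1, "+", off=0), part(3, "+", off=50)])
        second = ReadAlignment.of([part(5, "-")])
        conns = edges_from_pair(PairAlignment("r", first, second), INDEX)
        keys = {(a.segment_id, a.side, b.segment_id, b.side) for a, b, _, _ in conns}
        # splice connection is tail-head (concordant), mate connection too
        assert keys == {(1, TAIL, 3, HEAD), (3, TAIL, 5, HEAD)}

    def test_pair_inside_one_segment_gives_nothing(self):
        conns = edges_from_pair(pair_of(part(4, "+", 5, 45), part(4, "-", 50, 95)), INDEX)
        assert conns == []


class TestCompatible:
    def test_tail_head_reference(self):
        key = (SegmentEnd(2, TAIL), SegmentEnd(5, HEAD))
        assert compatible(key, REF)

    def test_tail_tail_needs_partner_inverted(self):
        key = (SegmentEnd(2, TAIL), SegmentEnd(5, TAIL))
        assert not compatible(key, REF)
        arr = Arrangement.reference(SEGMENTS)
        arr.orient[5] = 0
        assert compatible(key, arr)

    def test_head_tail_with_reordered_segments(self):
        # v placed before u, both forward: u's head follows v's tail
        key = (SegmentEnd(2, HEAD), SegmentEnd(5, TAIL))
        arr = Arrangement.reference(SEGMENTS)
        arr.order[5], arr.order[2] = arr.order[2], arr.order[5]
        assert compatible(key, arr)

    def test_cross_group_edges_never_reference_compatible(self):
        segs = [
            Segment(id=0, chrom="chr1", start=0, end=100),
            Segment(id=1, chrom="chr2", start=0, end=100),
        ]
        ref = Arrangement.reference(segs)
        assert not compatible((SegmentEnd(0, TAIL), SegmentEnd(1, HEAD)), ref)

    def test_unknown_segment_raises(self):
        with pytest.raises(KeyError):
            compatible((SegmentEnd(2, TAIL), SegmentEnd(99, HEAD)), REF)


class TestConcordanceCompatibilityEquivalence:
    """Pair-level concordance == reference compatibility of the mate edge."""

    def test_random_pairs(self, rng):
        segs = [
            Segment(id=i, chrom=("chr1" if i < 5 else "chr2"), start=(i % 5) * 100, end=(i % 5 + 1) * 100)
            for i in range(10)
        ]
        index = SegmentIndex(segs)
        ref = Arrangement.reference(segs)
        checked = 0
        for _ in range(500):
            i, j = rng.choice(10, size=2, replace=False)
            p1 = AlignedPart(segs[i].chrom, segs[i].start + 20, segs[i].start + 80,
                             "+" if rng.random() < 0.5 else "-")
            p2 = AlignedPart(segs[j].chrom, segs[j].start + 20, segs[j].start + 80,
                             "+" if rng.random() < 0.5 else "-")
            pair = pair_of(p1, p2)
            conns = edges_from_pair(pair, index)
            if len(conns) != 1:
                continue
            checked += 1
            assert pair.concordant == compatible(conns[0][:2], ref), (p1, p2)
        assert checked > 300


class TestBuildGraph:
    def test_discordant_edge_weight_scaled_by_alpha(self):
        pairs = [pair_of(part(2, "+"), part(5, "+")) for _ in range(5)]
        g = build_graph(pairs, SEGMENTS, alpha=2.0)
        (edge,) = g.edges.values()
        assert edge.raw_count == 5
        assert not edge.reference_concordant
        assert edge.weight(g.alpha) == 10.0

    def test_concordant_edge_weight_unscaled(self):
        pairs = [pair_of(part(2, "+"), part(3, "-")) for _ in range(7)]
        g = build_graph(pairs, SEGMENTS, alpha=2.0)
        (edge,) = g.edges.values()
        assert edge.reference_concordant
        assert edge.weight(g.alpha) == 7.0

    def test_within_segment_pairs_give_empty_graph(self):
        pairs = [pair_of(part(4, "+", 5, 45), part(4, "-", 50, 95))]
        g = build_graph(pairs, SEGMENTS)
        assert len(g.edges) == 0

    def test_aggregation_conserves_connection_count(self, rng):
        pairs = []
        for _ in range(100):
            i, j = rng.choice(10, size=2, replace=False)
            pairs.append(pair_of(part(int(i), "+"), part(int(j), "-")))
        g = build_graph(pairs, SEGMENTS)
        n_conns = sum(len(edges_from_pair(p, INDEX)) for p in pairs)
        assert sum(e.raw_count for e in g.edges.values()) == n_conns


class TestFilterGraph:
    def _graph(self, pair_counts, alpha=1.0):
        pairs = []
        for (i, oi, j, oj), n in pair_counts.items():
            pairs.extend(pair_of(part(i, oi), part(j, oj)) for _ in range(n))
        return build_graph(pairs, SEGMENTS, alpha=alpha)

    def test_theta_is_strict_on_raw_count(self):
        g = self._graph({(1, "+", 4, "+"): 2, (2, "+", 5, "+"): 3})
        out = filter_graph(g, theta=3, gamma=5)
        assert len(out.edges) == 1
        (edge,) = out.edges.values()
        assert edge.raw_count == 3

    def test_theta_ignores_alpha_scaling(self):
        # alpha=5 lifts weight to 10 but raw support 2 still fails theta=3
        g = self._graph({(1, "+", 4, "+"): 2}, alpha=5.0)
        assert len(filter_graph(g, theta=3, gamma=5).edges) == 0

    def test_degree_filter_counts_distinct_discordant_neighbors(self):
        g = self._graph({
            (4, "+", 6, "+"): 5, (4, "+", 7, "+"): 5, (4, "+", 8, "+"): 5,
            (4, "+", 5, "-"): 5,  # concordant backbone edge survives
        })
        out = filter_graph(g, theta=1, gamma=2)
        kept = list(out.edges.values())
        assert len(kept) == 1 and kept[0].reference_concordant

    def test_interleaving_mixed_signatures_removed(self):
        # two runs joined with three incompatible orientation signatures
        g = self._graph({
            (1, "+", 6, "+"): 5,
            (2, "-", 7, "-"): 5,
            (2, "-", 7, "+"): 5,   # head-tail
        })
        out = filter_graph(g, theta=1, gamma=5)
        assert len(out.discordant_edges()) == 0

    def test_single_rearrangement_signatures_kept(self):
        # inversion-like: tail-tail + head-head between two runs only
        g = self._graph({(1, "+", 6, "+"): 5, (2, "-", 7, "-"): 5})
        out = filter_graph(g, theta=1, gamma=5)
        assert len(out.discordant_edges()) == 2

    def test_clean_graph_unchanged_and_idempotent(self):
        g = self._graph({(2, "+", 5, "-"): 6, (1, "+", 6, "+"): 5})
        once = filter_graph(g, theta=3, gamma=5)
        twice = filter_graph(once, theta=3, gamma=5)
        assert set(once.edges) == set(g.edges) == set(twice.edges)

    def test_filtering_is_monotone(self, rng):
        for _ in range(20):
            gc = random_component(rng)
            out = filter_graph(gc, theta=int(rng.integers(0, 5)), gamma=int(rng.integers(1, 4)))
            assert set(out.edges) <= set(gc.edges)


class TestReversalSymmetry:
    def test_compatibility_invariant_under_reversal(self, rng):
        for _ in range(50):
            gc = random_component(rng)
            arr = random_arrangement(rng, gc.segments)
            rev = arr.reversed_flipped()
            for key in gc.edges:
                assert compatible(key, arr) == compatible(key, rev)
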