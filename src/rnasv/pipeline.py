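"""End-to-end TSV prediction: alignments in, breakpoint calls out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignments import PairAlignment, chrom_lengths_from_path, read_pairs_from_path
from .calls import TSVCall, call_tsvs
from .gsg import SegmentGraph, build_graph, filter_graph
from .ilp import Solution, solve_graph
from .segmentation import (
    Segment,
    find_breakpoints,
    merge_discordant_intervals,
    partition_genome,
)

log = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    calls: list[TSVCall]
    segments: list[Segment]
    graph: SegmentGraph          # unfiltered
    filtered: SegmentGraph
    solutions: list[tuple[SegmentGraph, Solution]]


def predict_from_pairs(
    pairs: Sequence[PairAlignment],
    chrom_lengths: Mapping[str, int],
    *,
    alpha: float = 1.0,
    theta: int = 5,
    gamma: int = 5,
    max_component: int = 200,
    min_shared: int = 3,
) -> PredictionResult:
    """Run segmentation, graph construction, rearrangement, and calling.

    ``alpha`` up-weights discordant edges (assumed normal/tumor transcript
    ratio), ``theta`` is the minimum read support per edge, ``gamma`` the
    maximum number of distinct discordant neighbor segments, and
    ``max_component`` caps the component size handed to the solver.
    """
    all_parts = [p for pair in pairs for end in (pair.first, pair.second) for p in end.parts]
    discordant_parts = [
        p
        for pair in pairs
        if not pair.concordant
        for end in (pair.first, pair.second)
        for p in end.parts
    ]
    intervals = merge_discordant_intervals(discordant_parts)
    breakpoints = find_breakpoints(all_parts, intervals, chrom_lengths)
    segments = partition_genome(breakpoints, chrom_lengths)
    log.info("%d segments from %d pairs (%d discordant intervals)",
             len(segments), len(pairs), len(intervals))

    graph = build_graph(pairs, segments, alpha=alpha)
    filtered = filter_graph(graph, theta=theta, gamma=gamma)
    log.info("graph: %d edges, %d after filtering (theta=%d gamma=%d)",
             len(graph.edges), len(filtered.edges), theta, gamma)

    solutions = solve_graph(filtered, max_segments=max_component)
    n_rearranged = sum(
        1
        for gc, sol in solutions
        if any(not gc.edges[k].reference_concordant for k in sol.satisfied)
    )
    log.info("solved %d components; %d contain realized rearrangements",
             len(solutions), n_rearranged)

    calls = call_tsvs(filtered, solutions, min_shared=min_shared)
    return PredictionResult(
        calls=calls,
        segments=segments,
        graph=graph,
        filtered=filtered,
        solutions=solutions,
    )


def predict_from_sam(
    path: str,
    *,
    min_mapq: int = 0,
    include_duplicates: bool = False,
    **kwargs,
) -> PredictionResult:
    """Predict TSVs directly from a SAM/BAM file."""
    pairs = read_pairs_from_path(
        path, min_mapq=min_mapq, include_duplicates=include_duplicates
    )
    chrom_lengths = chrom_lengths_from_path(path)
    return predict_from_pairs(pairs, chrom_lengths, **kwargs)
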