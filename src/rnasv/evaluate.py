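"""Scoring predicted TSVs against ground truth.

A prediction matches a truth record when both breakpoints are on the right
chromosomes within a window (default 30 kb — generous because the true
breakpoint may sit in an intron or other unexpressed sequence while the
RNA-derived breakpoint lands at the nearest expressed base) and the
retained-flank orientations agree.  Each truth record consumes at most one
prediction, nearest first.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

from .calls import Breakpoint, TSVCall
from .segmentation import HEAD, TAIL
from .simulate import GeneModel

DEFAULT_WINDOW_BP = 30_000


@dataclass(frozen=True)
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0


def _bp_close(a: Breakpoint, b: Breakpoint, window_bp: int) -> bool:
    return a.chrom == b.chrom and a.side == b.side and abs(a.pos - b.pos) <= window_bp


def _call_distance(p: TSVCall, t: TSVCall, window_bp: int) -> int | None:
    best = None
    for pa, pb in ((p.bp1, p.bp2), (p.bp2, p.bp1)):
        if _bp_close(pa, t.bp1, window_bp) and _bp_close(pb, t.bp2, window_bp):
            d = abs(pa.pos - t.bp1.pos) + abs(pb.pos - t.bp2.pos)
            if best is None or d < best:
                best = d
    return best


def match(
    pred: Sequence[TSVCall], truth: Sequence[TSVCall], window_bp: int = DEFAULT_WINDOW_BP
) -> MatchResult:
    """Greedy nearest-first matching of predictions to truth records."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    candidates = []
    for pi, p in enumerate(pred):
        for ti, t in enumerate(truth):
            d = _call_distance(p, t, window_bp)
            if d is not None:
                candidates.append((d, pi, ti))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    for _, pi, ti in candidates:
        if pi not in used_p and ti not in used_t:
            used_p.add(pi)
            used_t.add(ti)
    tp = len(used_p)
    return MatchResult(
        true_positives=tp,
        false_positives=len(pred) - tp,
        false_negatives=len(truth) - tp,
    )


def partner_entropy(
    calls: Sequence[TSVCall],
    min_recurrence: int = 3,
    *,
    bin_bp: int = 10_000,
    base: float = 2.0,
) -> dict[Hashable, float]:
    """Shannon entropy of each recurrent breakpoint's partner distribution.

    Breakpoints are binned to ``bin_bp`` for recurrence counting (nearby
    coordinates across samples count as the same breakpoint).  For every
    binned breakpoint occurring at least ``min_recurrence`` times, the
    empirical distribution of its partner bins is formed and its entropy
    (default base 2, i.e. bits) returned.  Zero entropy means the breakpoint
    always rejoins the same partner.
    """
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")

    def key(bp: Breakpoint) -> tuple[str, int]:
        return (bp.chrom, bp.pos // bin_bp)

    partners: dict[tuple[str, int], Counter] = {}
    for c in calls:
        partners.setdefault(key(c.bp1), Counter())[key(c.bp2)] += 1
        partners.setdefault(key(c.bp2), Counter())[key(c.bp1)] += 1
    out: dict[Hashable, float] = {}
    for k, ctr in partners.items():
        total = sum(ctr.values())
        if total < min_recurrence:
            continue
        h = -sum((n / total) * math.log(n / total, base) for n in ctr.values())
        out[k] = h + 0.0  # normalize -0.0 for the degenerate distribution
    return out


def tag_fusion_genes(
    calls: Sequence[TSVCall], annotation: Sequence[GeneModel]
) -> list[str]:
    """Label each call ``fusion-gene`` or ``non-fusion-gene`` (reporting only).

    A fusion-gene TSV has both breakpoints inside annotated genes, joined so
    that one gene contributes its 5' portion and the other its 3' portion on
    their sense strands; everything else (intergenic partner, anti-sense
    join) is non-fusion-gene.
    """

    def gene_at(bp: Breakpoint) -> GeneModel | None:
        for g in annotation:
            if g.chrom == bp.chrom and g.start <= bp.pos <= g.end:
                return g
        return None

    def is_donor(bp: Breakpoint, g: GeneModel) -> bool:
        # retained flank reads toward the junction on the gene's sense strand
        return (bp.side == TAIL) == (g.strand == "+")

    labels = []
    for c in calls:
        g1, g2 = gene_at(c.bp1), gene_at(c.bp2)
        if g1 is not None and g2 is not None and is_donor(c.bp1, g1) != is_donor(c.bp2, g2):
            labels.append("fusion-gene")
        else:
            labels.append("non-fusion-gene")
    return labels


def write_metrics(result: MatchResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"true_positives\t{result.true_positives}\n")
        fh.write(f"false_positives\t{result.false_positives}\n")
        fh.write(f"false_negatives\t{result.false_negatives}\n")
        fh.write(f"precision\t{result.precision:.6g}\n")
        fh.write(f"sensitivity\t{result.sensitivity:.6g}\n")
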