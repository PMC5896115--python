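"""Paired-end / split-read alignment records and concordance classification.

RNA-seq read pairs aligned to a genome are classified as *concordant*
(consistent with the reference layout: one forward and one reverse mate on a
single chromosome, forward mate leftmost, split parts in order) or
*discordant* (everything else).  Discordant pairs are the raw evidence for
transcriptomic structural variants; concordant pairs define the reference
backbone they compete against.

Coordinates are 0-based half-open throughout.  SAM input (1-based) is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class AlignedPart:
    """One aligned stretch of one read end.

    ``query_offset`` is the position of this stretch within the read sequence
    (leading clip length, strand-adjusted); it orders split parts by their
    position in the read.
    """

    chrom: str
    start: int
    end: int
    orientation: str
    query_offset: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty part [{self.start},{self.end})")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def is_forward(self) -> bool:
        return self.orientation == FORWARD


@dataclass(frozen=True)
class ReadAlignment:
    """All aligned parts of one read end, ordered by position in the read."""

    parts: tuple[AlignedPart, ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("read end with no aligned parts")
        offs = [p.query_offset for p in self.parts]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("parts must be strictly ordered by query offset")

    @classmethod
    def of(cls, parts: Sequence[AlignedPart]) -> "ReadAlignment":
        return cls(tuple(sorted(parts, key=lambda p: p.query_offset)))


@dataclass(frozen=True)
class PairAlignment:
    """The two ends of one read pair, with derived concordance status."""

    read_name: str
    first: ReadAlignment
    second: ReadAlignment
    concordant: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "concordant", pair_concordant(self))


def split_concordant(read: ReadAlignment) -> bool:
    """Is a (possibly split) single end consistent with the reference?

    All parts must share one chromosome and one orientation, and genome start
    positions must strictly increase along the read for forward parts
    (strictly decrease for reverse parts).  Forward-ordered gaps of any size
    are allowed: introns look like large forward gaps in RNA-seq.  An unsplit
    end is trivially concordant.
    """
    parts = read.parts
    if len(parts) == 1:
        return True
    first = parts[0]
    if any(p.chrom != first.chrom or p.orientation != first.orientation for p in parts):
        return False
    starts = [p.start for p in parts]
    if first.is_forward:
        return all(a < b for a, b in zip(starts, starts[1:]))
    return all(a > b for a, b in zip(starts, starts[1:]))


def pair_concordant(pair: PairAlignment) -> bool:
    """Is a paired-end alignment consistent with the reference layout?

    Both ends must individually be split-concordant, all parts of both ends
    must share one chromosome, the two ends must have opposite orientations,
    and the leftmost part of the forward-oriented end must not start after the
    leftmost part of the reverse end.  The two ends may overlap (short
    fragments), hence <= rather than < on the leftmost starts.
    """
    a, b = pair.first, pair.second
    if not (split_concordant(a) and split_concordant(b)):
        return False
    chroms = {p.chrom for p in a.parts} | {p.chrom for p in b.parts}
    if len(chroms) != 1:
        return False
    ori_a = a.parts[0].orientation
    ori_b = b.parts[0].orientation
    if ori_a == ori_b:
        return False
    fwd, rev = (a, b) if ori_a == FORWARD else (b, a)
    fwd_leftmost = min(p.start for p in fwd.parts)
    rev_leftmost = min(p.start for p in rev.parts)
    return fwd_leftmost <= rev_leftmost


def _query_offset(rec) -> int:
    """Leading clip length of a SAM record, strand-adjusted.

    For a reverse-strand record the stored sequence is the reverse complement
    of the read, so the clip at the *end* of the CIGAR is the leading clip in
    read coordinates.
    """
    cig = rec.cigartuples
    if not cig:
        return 0
    # CIGAR ops 4 = soft clip, 5 = hard clip
    if rec.is_reverse:
        lead = 0
        for op, ln in reversed(cig):
            if op in (4, 5):
                lead += ln
            else:
                break
    else:
        lead = 0
        for op, ln in cig:
            if op in (4, 5):
                lead += ln
            else:
                break
    return lead


def read_alignment_groups(
    alignment_stream: Iterable,
    *,
    min_mapq: int = 0,
    include_duplicates: bool = False,
) -> Iterator[PairAlignment]:
    """Group SAM records into :class:`PairAlignment` objects.

    ``alignment_stream`` yields pysam ``AlignedSegment`` records; split parts
    of one end appear as primary + supplementary records sharing the read
    name and mate flag.  Secondary and unmapped records are dropped, as are
    pairs with only one mapped end.  Records are buffered per read name, so
    the stream need not be coordinate sorted, but all records of one pair
    must eventually appear.
    """
    buckets: dict[str, dict[int, list[AlignedPart]]] = {}
    for rec in alignment_stream:
        try:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if not include_duplicates and (rec.is_duplicate or rec.is_qcfail):
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if not rec.is_paired:
                continue
            mate = 2 if rec.is_read2 else 1
            part = AlignedPart(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                orientation=REVERSE if rec.is_reverse else FORWARD,
                query_offset=_query_offset(rec),
            )
        except (ValueError, TypeError) as exc:  # malformed record
            log.warning("skipping malformed record %s: %s", getattr(rec, "query_name", "?"), exc)
            continue
        buckets.setdefault(rec.query_name, {1: [], 2: []})[mate].append(part)

    for name, ends in buckets.items():
        if not ends[1] or not ends[2]:
            continue
        try:
            yield PairAlignment(
                read_name=name,
                first=ReadAlignment.of(ends[1]),
                second=ReadAlignment.of(ends[2]),
            )
        except ValueError as exc:
            log.warning("skipping unusable pair %s: %s", name, exc)


def read_pairs_from_path(path: str, **kwargs) -> list[PairAlignment]:
    """Read all usable pairs from a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return list(read_alignment_groups(fh, **kwargs))


def chrom_lengths_from_path(path: str) -> dict[str, int]:
    """Chromosome name -> length from a SAM/BAM header, in header order."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))
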