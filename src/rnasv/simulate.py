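"""Synthetic rearranged genomes and analytically derived RNA-seq alignments.

The generator mirrors the role-swap evaluation design for RNA-seq structural
variant callers: structural variants transform an *original* genome (which
carries the gene annotation and is the one transcribed) into a *rearranged*
genome, and the rearranged genome serves as the alignment reference.  Read
pairs are sampled from spliced transcripts of the original genome and their
alignments to the rearranged reference are computed exactly through the
SV coordinate maps — split parts arise at exon junctions and at SV
junctions, with no aligner in the loop.

Five SV types are planted: deletion, inversion, insertion (novel sequence),
tandem duplication, and inter-chromosomal translocation (cut-and-paste).
Not every SV junction is observable from RNA-seq: a junction is a
ground-truth TSV only if both transcript-adjacent bases have images in the
rearranged genome and the implied adjacency is discordant.  Deleted bases
have no image (reads are clipped); duplication and novel-insertion junctions
map to forward gaps that are indistinguishable from introns.  Inversions and
translocations produce the detectable junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import AlignedPart, PairAlignment, ReadAlignment
from .calls import Breakpoint, TSVCall
from .segmentation import HEAD, TAIL

log = logging.getLogger(__name__)

SV_TYPES = ("deletion", "inversion", "insertion", "duplication", "translocation")

_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError("exons must be sorted and disjoint")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class SVRecord:
    """One planted structural variant, in original-genome coordinates."""

    type: str
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None  # translocation target
    dest_pos: int | None = None    # translocation / insertion point
    novel_length: int = 0          # insertion only


@dataclass
class _Block:
    """A stretch of a rearranged chromosome.

    ``primary`` marks the canonical image of its source interval; duplicate
    copies are non-primary so the source-to-rearranged map stays a function.
    Novel (insertion) blocks have no source.
    """

    src_chrom: str | None
    src_start: int
    src_end: int
    strand: str = "+"
    novel_seq: str | None = None
    primary: bool = True

    @property
    def length(self) -> int:
        if self.novel_seq is not None:
            return len(self.novel_seq)
        return self.src_end - self.src_start


class GenomeMap:
    """Base-level correspondence between original and rearranged genomes."""

    def __init__(self, blocks: Mapping[str, Sequence[_Block]]):
        self.blocks = {c: list(bs) for c, bs in blocks.items()}
        self._fwd: dict[str, tuple[list[int], list[tuple[int, int, str, int, str]]]] = {}
        fwd_entries: dict[str, list[tuple[int, int, str, int, str]]] = {}
        self._layout: dict[str, list[tuple[int, int, _Block]]] = {}
        for re_chrom, bs in self.blocks.items():
            off = 0
            layout = []
            for b in bs:
                layout.append((off, off + b.length, b))
                if b.primary and b.src_chrom is not None:
                    fwd_entries.setdefault(b.src_chrom, []).append(
                        (b.src_start, b.src_end, re_chrom, off, b.strand)
                    )
                off += b.length
            self._layout[re_chrom] = layout
        for c, entries in fwd_entries.items():
            entries.sort()
            self._fwd[c] = ([e[0] for e in entries], entries)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: (lay[-1][1] if lay else 0) for c, lay in self._layout.items()}

    def forward(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Original (chrom, pos) -> (rearranged chrom, pos, block strand)."""
        from bisect import bisect_right

        if chrom not in self._fwd:
            return None
        starts, entries = self._fwd[chrom]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        s, e, rc, roff, strand = entries[i]
        if not (s <= pos < e):
            return None
        if strand == "+":
            return rc, roff + (pos - s), "+"
        return rc, roff + (e - 1 - pos), "-"

    def backward(self, re_chrom: str, pos: int) -> tuple[str, int] | None:
        """Rearranged (chrom, pos) -> original (chrom, pos); None for novel."""
        for off, end, b in self._layout[re_chrom]:
            if off <= pos < end:
                if b.src_chrom is None:
                    return None
                if b.strand == "+":
                    return b.src_chrom, b.src_start + (pos - off)
                return b.src_chrom, b.src_end - 1 - (pos - off)
        return None

    def materialize(self, genome: Mapping[str, str]) -> dict[str, str]:
        out = {}
        for re_chrom, bs in self.blocks.items():
            parts = []
            for b in bs:
                if b.novel_seq is not None:
                    parts.append(b.novel_seq)
                else:
                    seq = genome[b.src_chrom][b.src_start:b.src_end]
                    parts.append(revcomp(seq) if b.strand == "-" else seq)
            out[re_chrom] = "".join(parts)
        return out


def make_genome(
    n_chroms: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 20,
    exon_geometry: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneModel]]:
    """A random multi-chromosome genome with non-overlapping gene models.

    ``exon_geometry`` accepts ``n_exons``, ``exon_len`` and ``intron_len``
    (defaults 5 / 150 / 300 bp).  Genes are separated by zero-expression
    gaps so that, absent SV evidence, they fall into separate connected
    components of the segment graph.  Deterministic under ``seed``.
    """
    geom = {"n_exons": 5, "exon_len": 150, "intron_len": 300}
    if exon_geometry:
        geom.update(exon_geometry)
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for ci in range(n_chroms):
        genome[f"chr{ci + 1}"] = "".join(
            rng.choice(list("ACGT"), size=chrom_len)
        )
    gene_span = geom["n_exons"] * geom["exon_len"] + (geom["n_exons"] - 1) * geom["intron_len"]
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    genes: list[GeneModel] = []
    gid = 0
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        slack = chrom_len - count * gene_span
        if slack < (count + 1) * 500:
            raise ValueError("cannot pack genes with >=500 bp zero-expression gaps")
        # random gap sizes >= 500 summing to at most the slack
        w = rng.random(count + 1)
        gaps = 500 + np.floor(w / w.sum() * (slack - (count + 1) * 500)).astype(int)
        pos = 0
        for gi in range(count):
            pos += int(gaps[gi])
            exons = tuple(
                (
                    pos + k * (geom["exon_len"] + geom["intron_len"]),
                    pos + k * (geom["exon_len"] + geom["intron_len"]) + geom["exon_len"],
                )
                for k in range(geom["n_exons"])
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid}", chrom, strand, exons))
            gid += 1
            pos += gene_span
    return genome, genes


def _locate_block(blocks: Mapping[str, list[_Block]], chrom: str, start: int, end: int):
    """Find (rearranged chrom, index) of the primary + block containing [start,end)."""
    for re_chrom, bs in blocks.items():
        for i, b in enumerate(bs):
            if (
                b.primary
                and b.novel_seq is None
                and b.strand == "+"
                and b.src_chrom == chrom
                and b.src_start <= start
                and end <= b.src_end
            ):
                return re_chrom, i
    raise ValueError(f"no intact block contains {chrom}:{start}-{end}; SVs overlap?")


def _split(b: _Block, at: int) -> tuple[_Block, _Block]:
    left = _Block(b.src_chrom, b.src_start, at, b.strand, None, b.primary)
    right = _Block(b.src_chrom, at, b.src_end, b.strand, None, b.primary)
    return left, right


def _carve(blocks: dict[str, list[_Block]], chrom: str, start: int, end: int):
    """Split so that [start,end) is exactly one block; return its address."""
    re_chrom, i = _locate_block(blocks, chrom, start, end)
    b = blocks[re_chrom][i]
    pieces: list[_Block] = []
    if start > b.src_start:
        left, b = _split(b, start)
        pieces.append(left)
    mid_idx = len(pieces)
    if end < b.src_end:
        b, right = _split(b, end)
        pieces.extend([b, right])
    else:
        pieces.append(b)
    blocks[re_chrom][i : i + 1] = [p for p in pieces if p.length > 0]
    # locate the carved middle block again (robust to dropped empties)
    for j, blk in enumerate(blocks[re_chrom]):
        if blk.src_chrom == chrom and blk.src_start == start and blk.src_end == end and blk.primary:
            return re_chrom, j
    raise AssertionError("carved block vanished")


def plant_svs(
    genome: Mapping[str, str],
    annotation: Sequence[GeneModel],
    counts_per_type: Mapping[str, int],
    seed: int = 0,
    *,
    sv_len_range: tuple[int, int] = (600, 2500),
    insertion_len_range: tuple[int, int] = (200, 800),
    margin: int = 500,
    max_tries: int = 2000,
) -> tuple[dict[str, str], list[SVRecord], GenomeMap]:
    """Plant gene-hitting SVs and build the rearranged genome.

    SV source intervals start inside a gene (so each SV hits the
    transcriptome), are pairwise disjoint with a ``margin`` buffer (junction
    read pileups of different SVs never overlap), and never nest.  Returns
    the rearranged sequences, the SV records, and the base-level coordinate
    map between the two genomes.
    """
    rng = np.random.default_rng(seed)
    unknown = set(counts_per_type) - set(SV_TYPES)
    if unknown:
        raise ValueError(f"unknown SV types: {sorted(unknown)}")
    claimed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def free(chrom: str, s: int, e: int) -> bool:
        return all(e + margin <= cs or ce + margin <= s for cs, ce in claimed[chrom])

    def claim(chrom: str, s: int, e: int) -> None:
        claimed[chrom].append((s, e))

    genes = list(annotation)
    svs: list[SVRecord] = []
    order = [t for t in SV_TYPES for _ in range(counts_per_type.get(t, 0))]
    rng.shuffle(order)
    for sv_type in order:
        placed = False
        for _ in range(max_tries):
            gene = genes[int(rng.integers(len(genes)))]
            chrom = gene.chrom
            s = int(rng.integers(gene.start, gene.end - 1))
            if sv_type == "insertion":
                ln = int(rng.integers(*insertion_len_range))
                if not free(chrom, s, s + 1):
                    continue
                claim(chrom, s, s + 1)
                svs.append(SVRecord("insertion", chrom, s, s, novel_length=ln))
                placed = True
                break
            ln = int(rng.integers(*sv_len_range))
            e = s + ln
            if e >= len(genome[chrom]) - margin or not free(chrom, s, e):
                continue
            if sv_type == "translocation":
                others = [c for c in genome if c != chrom] or [chrom]
                dest_chrom = others[int(rng.integers(len(others)))]
                dpos = int(rng.integers(margin, len(genome[dest_chrom]) - margin))
                if dest_chrom == chrom and s - margin <= dpos <= e + margin:
                    continue
                if not free(dest_chrom, dpos, dpos + 1):
                    continue
                claim(chrom, s, e)
                claim(dest_chrom, dpos, dpos + 1)
                svs.append(SVRecord("translocation", chrom, s, e, dest_chrom=dest_chrom, dest_pos=dpos))
            else:
                claim(chrom, s, e)
                svs.append(SVRecord(sv_type, chrom, s, e))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a {sv_type} without overlap")

    blocks: dict[str, list[_Block]] = {
        c: [_Block(c, 0, len(seq))] for c, seq in genome.items()
    }
    for sv in svs:
        if sv.type == "deletion":
            rc, i = _carve(blocks, sv.chrom, sv.start, sv.end)
            del blocks[rc][i]
        elif sv.type == "inversion":
            rc, i = _carve(blocks, sv.chrom, sv.start, sv.end)
            blocks[rc][i].strand = "-"
        elif sv.type == "duplication":
            rc, i = _carve(blocks, sv.chrom, sv.start, sv.end)
            b = blocks[rc][i]
            copy = _Block(b.src_chrom, b.src_start, b.src_end, b.strand, None, primary=False)
            blocks[rc].insert(i + 1, copy)
        elif sv.type == "insertion":
            rc, i = _carve_point(blocks, sv.chrom, sv.start)
            novel = "".join(rng.choice(list("ACGT"), size=sv.novel_length))
            blocks[rc].insert(i, _Block(None, 0, 0, "+", novel_seq=novel))
        elif sv.type == "translocation":
            rc, i = _carve(blocks, sv.chrom, sv.start, sv.end)
            moved = blocks[rc].pop(i)
            dc, j = _carve_point(blocks, sv.dest_chrom, sv.dest_pos)
            blocks[dc].insert(j, moved)
    gmap = GenomeMap(blocks)
    return gmap.materialize(genome), svs, gmap


def _carve_point(blocks: dict[str, list[_Block]], chrom: str, pos: int):
    """Split so a block boundary falls at original position ``pos``."""
    re_chrom, i = _locate_block(blocks, chrom, pos, pos)
    b = blocks[re_chrom][i]
    if pos == b.src_start:
        return re_chrom, i
    if pos == b.src_end:
        return re_chrom, i + 1
    left, right = _split(b, pos)
    blocks[re_chrom][i : i + 1] = [left, right]
    return re_chrom, i + 1


def _transcript_mapping(
    gene: GeneModel, gmap: GenomeMap
) -> list[tuple[str, int, str] | None]:
    """Per transcript base: (rearranged chrom, pos, effective orientation).

    The effective orientation composes the gene strand (direction the
    transcript walks the original genome) with the strand of the block the
    base lands in; it is the strand an aligner would assign to a read
    traversing this base in transcript order.  ``None`` marks bases with no
    image (deleted in the rearranged genome).
    """
    positions: list[int] = []
    for s, e in gene.exons:
        positions.extend(range(s, e))
    if gene.strand == "-":
        positions.reverse()
    walk = 1 if gene.strand == "+" else -1
    out: list[tuple[str, int, str] | None] = []
    for p in positions:
        img = gmap.forward(gene.chrom, p)
        if img is None:
            out.append(None)
            continue
        rc, q, bstrand = img
        block_dir = 1 if bstrand == "+" else -1
        out.append((rc, q, "+" if walk * block_dir > 0 else "-"))
    return out


def _adjacency_breakpoints(
    a: tuple[str, int, str], b: tuple[str, int, str]
) -> tuple[Breakpoint, Breakpoint] | None:
    """TSV breakpoints for a transcript adjacency, or None if concordant."""
    (c1, q1, o1), (c2, q2, o2) = a, b
    if c1 == c2 and o1 == o2 == "+" and q2 > q1:
        return None
    if c1 == c2 and o1 == o2 == "-" and q2 < q1:
        return None
    bp1 = Breakpoint(c1, q1 + 1, TAIL) if o1 == "+" else Breakpoint(c1, q1, HEAD)
    bp2 = Breakpoint(c2, q2, HEAD) if o2 == "+" else Breakpoint(c2, q2 + 1, TAIL)
    return bp1, bp2


def true_tsvs(annotation: Sequence[GeneModel], gmap: GenomeMap) -> list[TSVCall]:
    """Ground-truth TSVs: transcript adjacencies broken by the rearrangement.

    For every pair of bases adjacent in a spliced transcript, the pair is a
    TSV when both bases have images in the rearranged (alignment-reference)
    genome and the images do not form a same-chromosome, same-orientation,
    correctly ordered adjacency (forward gaps of any size are intron-like
    and concordant).  Junctions with an unmapped side are undetectable from
    RNA-seq alignments and are not ground truth.
    """
    seen: set[tuple[Breakpoint, Breakpoint]] = set()
    out: list[TSVCall] = []
    for gene in annotation:
        tmap = _transcript_mapping(gene, gmap)
        for a, b in zip(tmap, tmap[1:]):
            if a is None or b is None:
                continue
            bps = _adjacency_breakpoints(a, b)
            if bps is None:
                continue
            call = TSVCall.ordered(bps[0], bps[1], support=0)
            key = (call.bp1, call.bp2)
            if key not in seen:
                seen.add(key)
                out.append(call)
    out.sort(key=lambda c: (c.bp1, c.bp2))
    return out


def _parts_from_bases(
    bases: Sequence[tuple[str, int, str] | None], min_part_len: int
) -> list[AlignedPart]:
    """Compress per-base images (in read order) into aligned parts."""
    parts: list[AlignedPart] = []
    run_start = None
    for i in range(len(bases) + 1):
        cur = bases[i] if i < len(bases) else None
        if run_start is not None:
            prev = bases[i - 1]
            contiguous = (
                cur is not None
                and cur[0] == prev[0]
                and cur[2] == prev[2]
                and cur[1] == prev[1] + (1 if prev[2] == "+" else -1)
            )
            if not contiguous:
                first, last = bases[run_start], bases[i - 1]
                if i - run_start >= min_part_len:
                    if first[2] == "+":
                        start, end = first[1], last[1] + 1
                    else:
                        start, end = last[1], first[1] + 1
                    parts.append(
                        AlignedPart(first[0], start, end, first[2], query_offset=run_start)
                    )
                run_start = None
        if run_start is None and cur is not None:
            run_start = i
    return parts


def _flip_base(b):
    return None if b is None else (b[0], b[1], "-" if b[2] == "+" else "+")


def emit_alignments(
    annotation: Sequence[GeneModel],
    gmap: GenomeMap,
    *,
    read_len: int = 100,
    frag_len: int = 300,
    coverage: float = 30.0,
    noise_rate: float = 0.0,
    seed: int = 0,
    min_part_len: int = 12,
    expression: Mapping[str, float] | None = None,
) -> list[PairAlignment]:
    """Paired-end alignments of transcript fragments to the rearranged genome.

    Fragments are sampled uniformly from each spliced transcript, with a
    per-gene Poisson count of mean ``coverage * transcript_length /
    (2 * read_len)`` (times an optional per-gene ``expression`` multiplier,
    emulating heterogeneous transcript mixtures).  Each end's alignment is
    computed exactly through the coordinate map; stretches shorter than
    ``min_part_len`` are clipped, ends with no alignable stretch drop the
    pair.  ``noise_rate`` adds uniformly random read pairs at that rate to
    exercise the graph filters.  Deterministic under ``seed``.
    """
    if read_len >= frag_len:
        raise ValueError("read_len must be < frag_len")
    rng = np.random.default_rng(seed)
    chrom_lengths = gmap.chrom_lengths()
    pairs: list[PairAlignment] = []
    n_frags_total = 0
    for gene in annotation:
        T = gene.transcript_length
        if T < frag_len:
            continue
        mult = expression.get(gene.gene_id, 1.0) if expression else 1.0
        lam = mult * coverage * T / (2.0 * read_len)
        n = int(rng.poisson(lam))
        n_frags_total += n
        tmap = _transcript_mapping(gene, gmap)
        starts = rng.integers(0, T - frag_len + 1, size=n)
        for fi, fs in enumerate(starts):
            fs = int(fs)
            r1 = tmap[fs : fs + read_len]
            r2 = [_flip_base(b) for b in reversed(tmap[fs + frag_len - read_len : fs + frag_len])]
            p1 = _parts_from_bases(r1, min_part_len)
            p2 = _parts_from_bases(r2, min_part_len)
            if not p1 or not p2:
                continue
            pairs.append(
                PairAlignment(
                    read_name=f"{gene.gene_id}_f{fi}",
                    first=ReadAlignment.of(p1),
                    second=ReadAlignment.of(p2),
                )
            )
    n_noise = int(rng.poisson(noise_rate * n_frags_total)) if noise_rate > 0 else 0
    chroms = list(chrom_lengths)
    for ni in range(n_noise):
        ends = []
        for _ in range(2):
            c = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, max(chrom_lengths[c] - read_len, 1)))
            ori = "+" if rng.random() < 0.5 else "-"
            ends.append(
                ReadAlignment.of([AlignedPart(c, pos, pos + read_len, ori, query_offset=0)])
            )
        pairs.append(PairAlignment(read_name=f"noise_{ni}", first=ends[0], second=ends[1]))
    return pairs


@dataclass
class SimulatedDataset:
    """Everything one replicate of the synthetic protocol produces."""

    genome: dict[str, str]
    annotation: list[GeneModel]
    rearranged: dict[str, str]
    svs: list[SVRecord]
    gmap: GenomeMap
    chrom_lengths: dict[str, int]
    pairs: list[PairAlignment]
    truth: list[TSVCall] = field(default_factory=list)


def simulate_dataset(
    *,
    n_chroms: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 20,
    counts_per_type: Mapping[str, int] | None = None,
    read_len: int = 100,
    frag_len: int = 300,
    coverage: float = 30.0,
    noise_rate: float = 0.0,
    seed: int = 0,
    exon_geometry: Mapping[str, int] | None = None,
) -> SimulatedDataset:
    """One full replicate: genome, planted SVs, truth, and alignments.

    The default SV mix plants six gene-hitting SVs covering all five types
    (two inversions, one translocation, and one each of the junction-silent
    deletion / insertion / duplication types).
    """
    if counts_per_type is None:
        counts_per_type = {
            "deletion": 1,
            "inversion": 2,
            "insertion": 1,
            "duplication": 1,
            "translocation": 1,
        }
    genome, annotation = make_genome(
        n_chroms=n_chroms, chrom_len=chrom_len, n_genes=n_genes,
        exon_geometry=exon_geometry, seed=seed,
    )
    if any(counts_per_type.values()):
        rearranged, svs, gmap = plant_svs(genome, annotation, counts_per_type, seed=seed + 1)
    else:
        blocks = {c: [_Block(c, 0, len(s))] for c, s in genome.items()}
        gmap = GenomeMap(blocks)
        rearranged, svs = gmap.materialize(genome), []
    pairs = emit_alignments(
        annotation, gmap,
        read_len=read_len, frag_len=frag_len, coverage=coverage,
        noise_rate=noise_rate, seed=seed + 2,
    )
    return SimulatedDataset(
        genome=genome,
        annotation=annotation,
        rearranged=rearranged,
        svs=svs,
        gmap=gmap,
        chrom_lengths=gmap.chrom_lengths(),
        pairs=pairs,
        truth=true_tsvs(annotation, gmap),
    )


# ---------------------------------------------------------------------------
# file export


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(annotation: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_sam(
    pairs: Iterable[PairAlignment],
    chrom_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write pairs as SAM records; split parts become supplementary records."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
        }
    )
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for pair in pairs:
            ends = (pair.first, pair.second)
            for ei, end in enumerate(ends):
                mate = ends[1 - ei]
                read_len = max(p.query_offset + (p.end - p.start) for p in end.parts)
                for pi, part in enumerate(end.parts):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = pair.read_name
                    rec.flag = (
                        0x1
                        | (0x40 if ei == 0 else 0x80)
                        | (0x10 if part.orientation == "-" else 0)
                        | (0x20 if mate.parts[0].orientation == "-" else 0)
                        | (0x800 if pi > 0 else 0)
                    )
                    rec.reference_id = tid[part.chrom]
                    rec.reference_start = part.start
                    rec.mapping_quality = 60
                    plen = part.end - part.start
                    lead = part.query_offset
                    trail = read_len - lead - plen
                    if part.orientation == "-":
                        lead, trail = trail, lead
                    cigar = []
                    if lead:
                        cigar.append((4, lead))
                    cigar.append((0, plen))
                    if trail:
                        cigar.append((4, trail))
                    rec.cigartuples = cigar
                    rec.next_reference_id = tid[mate.parts[0].chrom]
                    rec.next_reference_start = mate.parts[0].start
                    out.write(rec)


def write_truth_bedpe(truth: Sequence[TSVCall], path: str) -> None:
    from .calls import write_predictions

    with open(path, "w") as fh:
        write_predictions(truth, fh)
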