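# Methods

`rnasv` detects transcriptomic structural variants (TSVs) — rearrangements
observable in transcribed sequence — directly from paired-end RNA-seq
alignments, without gene annotation. The central idea is to treat detection
as a genome rearrangement problem: partition the reference into segments,
record every adjacency the read alignments assert between segment ends as a
weighted graph edge, and find the ordering and orientation of segments that
makes the largest possible weight of edges consistent. Junctions that the
optimal rearrangement realizes but the reference does not are the reported
TSVs. Because concordant and discordant evidence compete inside one
objective, no global read-support threshold has to arbitrate between
highly and lowly expressed loci.

## Alignment concordance

Alignments are decomposed into *parts* (maximal aligned stretches; split
alignments arrive as supplementary SAM records, spliced stretches as
separate parts). A split end is concordant when all parts share one
chromosome and orientation and their start positions are strictly monotone
along the read (increasing on `+`, decreasing on `-`); forward gaps of any
size are allowed, since introns are indistinguishable from small deletions
in RNA-seq. A pair is concordant when both ends are split-concordant, all
parts share one chromosome, the ends have opposite orientations, and the
forward end's leftmost start is at or before the reverse end's leftmost
start (`<=`, so fully overlapping short fragments stay concordant).
Internally all coordinates are 0-based half-open; SAM input is converted on
read, and the query offset of each part (its position within the read) is
recovered from the strand-adjusted leading clip of the CIGAR.

## Segments

Breakpoints come from two sources: the start and end of every interval of
*strictly* overlapping discordant parts (book-ended spans are not merged),
so that the two sides of a junction pileup fall into different segments;
and the starting point of every zero-coverage run, so that genes separated
by unexpressed sequence end up in separate connected components. Coverage
counts all aligned parts, concordant and discordant; the gap between
spliced parts contributes none. Segments tile each chromosome exactly and
carry ids in genome order. There is no minimum segment length.

## The genome segment graph

Each segment contributes two vertices, head (lower coordinate) and tail.
Every read pair generates one connection per consecutive split-part pair
within each end plus one mate connection (last part of end one, first part
of end two); the side attached at each endpoint follows the part
orientation — a forward part connects through its segment's tail, a reverse
part through its head, with intra-end continuation parts first flipped into
mate convention. Connections within one segment are dropped. Multi-edges
collapse; an edge's weight is its supporting-alignment count, multiplied by
the discordant-weight coefficient `alpha` when the edge is not
reference-concordant. `alpha` (default 1, i.e. off) models the
normal-to-tumor transcript ratio: above 1 it lets minority tumor junctions
survive the competition with the concordant majority. Per-connection
junction coordinates (part end on a tail side, part start on a head side)
are retained on each edge for breakpoint refinement.

An arrangement is a permutation `pi` of segments plus per-segment
orientation bits (`f(s_h) + f(s_t) = 1`). An edge `(u_i, v_j)` is
compatible with `(pi, f)` iff

    1 - f(v_j) = 1[pi(v) < pi(u)] = f(u_i).

The reference arrangement is identity order, all head-first, with segments
grouped by chromosome; an edge between groups is never
reference-compatible. The grouping is required for pair-level concordance
and edge-level reference compatibility to coincide exactly: a correctly
oriented pair straddling two chromosomes is discordant, and without groups
the pure orientation identity would count its edge as reference-compatible
whenever the chromosome order happened to agree. Arrangements produced by
the optimizer carry no groups — a rearranged component is one sequence.

## Filters

Applied in order, before optimization:

1. **Support (`theta`, default 5).** Edges with raw support below `theta`
   are removed. `theta` applies to the raw count, not the `alpha`-scaled
   weight, so the two parameters do not interact; it plays the role of the
   read-support threshold of conventional SV callers.
2. **Degree (`gamma`, default 5).** A segment with discordant edges to more
   than `gamma` distinct partner segments is treated as a low-mappability
   artifact and loses all its discordant edges; concordant backbone edges
   survive, so genes are not disconnected.
3. **Interleaving.** Discordant-incident segments are grouped into runs of
   genome-consecutive segments (id gap at most 2, one chromosome). For each
   pair of runs, the discordant edges between them are classified by
   side-type signature — which end of each run they attach to. Any single
   rearrangement yields at most two signatures: one junction gives one;
   a block excised from one region and traversed inside the other's
   transcript gives tail-head plus head-tail; an inversion spanning the
   runs gives tail-tail plus head-head. Spliced or mate-gapped
   *pass-through* evidence (reads whose gap skips an intron next to the
   junction) repeats a junction's signature without adding one. Three or
   more signatures mean the two regions are woven together with
   inconsistent orientations — the interleaved-exon pattern characteristic
   of multi-mapping and alignment artifacts — and all discordant edges
   between the two runs are dropped. Two genuinely distinct rearrangements
   between the same two runs would also be dropped; with junction pileups
   separated by at least a fragment length this does not arise in the
   synthetic protocol, and in real data it trades a rare double rearrangement
   against a common artifact class.

## Optimization

The objective — maximize the total weight of compatible edges over all
arrangements — decomposes over connected components. Per component it is
encoded as a 0/1 integer linear program: orientation bits `y_u`, ordering
bits `z_uv` (for `u < v`; `z_vu` substituted as `1 - z_uv`; ordered triples
constrained by `1 <= z_uv + z_vw + z_wu <= 2` to force a total order), and
edge indicators `x_e` tied to `y`/`z` by four inequalities per edge whose
form depends on the endpoint side pair. The model is solved with HiGHS
through `scipy.optimize.milp`; an exhaustive enumerator over all
`|S|! * 2^|S|` arrangements provides an independent oracle for components
of up to 8 segments and an automatic fallback if no solver is available.

Numerical choices: components whose edges are all reference-concordant
short-circuit to the identity arrangement, which is provably optimal there.
Ties between optima are broken lexicographically — most satisfied
reference-concordant edges, then fewest inverted segments — implemented as
epsilon terms in the MILP objective sized well below the weight granularity
(exact whenever weight sums move in steps of at least 1, which holds for
integer `alpha`; for fractional `alpha` the tie-break can in principle
perturb optima by less than 0.5). The solution's satisfied set and
objective are recomputed from the extracted arrangement rather than trusted
from solver variables. Components larger than `max_component` (default 200
segments; the triple constraints grow cubically) are skipped with a warning
and keep the identity arrangement, reporting no TSVs.

## Calling and breakpoint refinement

A TSV candidate is an edge incompatible with the reference but compatible
with its component's optimal arrangement; both conditions are re-verified
post hoc. One physical junction is typically witnessed by several satisfied
discordant edges — the direct edge between the abutting segment ends plus
pass-through edges whose reads skip over adjacent exons — so calls are
consolidated to one per *realized novel adjacency*: candidates are accepted
innermost first (shortest endpoint rank interval in the arrangement, then
higher support), and any candidate whose rank interval contains an accepted
candidate's interval is suppressed. This matches the underlying model of a
single consistent rearranged genome, in which each segment end is adjacent
to exactly one neighbor. Nested rearrangements sharing one junction
neighborhood would be reduced to their innermost junction; the synthetic
protocol plants non-nested SVs, and this is a documented limitation on
real data.

Breakpoints are refined per edge side: if at least three supporting
alignments share the junction-side coordinate (one plus two others), that
coordinate is reported (most frequent first, ties to the smaller
coordinate); otherwise the segment boundary on that side. Output is BEDPE,
0-based half-open, strand `+` meaning the upstream flank of the breakpoint
is retained in the variant and `-` the downstream flank, sorted
deterministically.

## Synthetic data

The generator mirrors the role-swap evaluation design used for RNA-seq SV
callers: SVs transform an *original* genome (which carries the annotation
and is the one transcribed) into a *rearranged* genome, and the rearranged
genome serves as the alignment reference. Defaults: 2 chromosomes of
100 kb, 20 genes of 5 x 150 bp exons with 300 bp introns separated by at
least 500 bp of unexpressed sequence, uniform expression, fragments of
300 bp with 100 bp reads at 30x transcript coverage (per-gene Poisson
counts), and six gene-hitting SVs per replicate covering all five types
(two inversions, one cut-and-paste translocation, one deletion, one tandem
duplication, one novel-sequence insertion), pairwise separated by at least
500 bp so junction pileups never overlap. Read alignments are computed
exactly through the base-level coordinate map — split parts arise at exon
and SV junctions, stretches under 12 bp are clipped as a real aligner
would, ends with no alignable stretch drop the pair — so the method is
tested in isolation from aligner behavior; a SAM exporter covers the file
path end to end. Optional uniform random read pairs (`noise_rate`) exercise
the filters, and per-gene expression multipliers emulate the heterogeneous
mixtures that motivate `alpha`.

Ground truth is derived from transcript adjacencies: every pair of bases
adjacent in a spliced transcript whose images in the rearranged genome do
not form a same-chromosome, same-orientation, correctly ordered adjacency
is a true TSV junction (forward gaps of any size are intron-like and hence
concordant). Junctions with an unmapped side are excluded as undetectable
in principle. A consequence worth stating plainly: under this role swap,
deletions only clip reads, and tandem duplications and novel insertions
produce forward gaps, so none of the three can generate discordant
alignments — only inversion and translocation junctions inside genes are
observable, which is the RNA-seq analogue of treating deletions as introns.
Passing the recovery tests therefore demonstrates correct handling of the
observable junction classes and correct silence on the unobservable ones,
not sensitivity to every genomic SV type. The generator also does not model
sequencing errors, alternative isoforms, or mapping ambiguity; real-data
performance depends on the upstream aligner for all three.

## Evaluation

A prediction matches a truth record when both breakpoints are on the right
chromosomes within a window (default 30 kb — wide because a genomic
breakpoint may sit in unexpressed sequence while the RNA-derived breakpoint
lands at the nearest expressed base) and both retained-flank orientations
agree; truth records consume at most one prediction each, nearest first.
Precision is 1 by convention when nothing is predicted. For cohort-style
analyses, `partner_entropy` bins breakpoints (default 10 kb), and for every
breakpoint bin occurring at least 3 times reports the Shannon entropy
(base 2 by default; the base is configurable because entropy thresholds
quoted in the literature are unit-ambiguous) of its empirical partner
distribution — 0 for a faithful partner, larger for promiscuous joining.
`tag_fusion_genes` labels calls fusion-gene when both breakpoints fall in
annotated genes joined sense-compatibly (one gene donates its 5' side, the
other its 3'); the label is reporting-only.

## Problem sizes of the shipped protocol

The test suite and acceptance script run the solver-versus-enumeration
comparison on 200 random components of up to 6 segments and 10 edges with
integer weights 1-10, the concordance/compatibility equivalence on 1,000
random pairs over a 12-segment two-chromosome universe, a no-SV null
replicate, 20 recovery replicates at the generator defaults above, 100
random graphs for reversal symmetry, and a 6-replicate read-length sweep
(51 bp vs 100 bp). These sizes keep the whole protocol around half a
minute on one CPU while leaving each property with enough instances to be
informative.

## Known limitations

- One consistent genome per component: conflicting TSVs in heterogeneous
  samples resolve to the dominating one.
- Small deletions are intron-like by construction and never called.
- Components over the size cap are left unrearranged (warned).
- The interleaving filter and call consolidation can each suppress one of
  two genuinely co-located rearrangements (see above).
- Breakpoint refinement reports segment boundaries when fewer than three
  reads pin the exact coordinate; junctions whose flank within the segment
  is shorter than a read anchor (~12 bp) may lack sufficient support
  altogether and be missed.
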