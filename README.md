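# rnasv

Detection of **transcriptomic structural variants (TSVs)** — genome
rearrangements visible in transcribed sequence, including but not limited
to fusion genes — directly from paired-end RNA-seq alignments, with no gene
annotation required. The package is aimed at method developers and
analysts who want an annotation-free SV caller for RNA-seq together with a
fully self-contained synthetic benchmark (genome simulator, planted SVs,
analytic alignments, ground truth, and scoring).

## The method

Given coordinate-addressed RNA-seq alignments to a reference genome, the
caller:

1. classifies each read pair as **concordant** or **discordant** (split
   ends must stay on one chromosome and strand with monotone starts; pairs
   must face each other on one chromosome, forward mate leftmost);
2. partitions the genome into **segments** at the boundaries of discordant
   pileups and at the starts of zero-coverage runs;
3. builds a **genome segment graph** `G = (V, E, w)` whose vertices are
   segment ends (head `s_h`, tail `s_t`) and whose edges record the
   adjacencies implied by reads, weighted by supporting-alignment count
   (discordant edges scaled by a coefficient `alpha`);
4. finds, per connected component, the permutation `pi` and orientation
   `f` (with `f(s_h) + f(s_t) = 1`) maximizing

   `max_{pi,f} sum_{e in E} w(e) * 1[e ~ (pi, f)]`,

   where an edge `(u_i, v_j)` is compatible (`e ~ (pi, f)`) iff
   `1 - f(v_j) = 1[pi(v) < pi(u)] = f(u_i)`. The search is solved exactly
   as a 0/1 integer linear program (HiGHS via SciPy), with an exhaustive
   oracle for small components;
5. reports edges that are **incompatible with the reference but compatible
   with the optimum** as TSVs — pairs of oriented breakpoints in BEDPE,
   refined to exact coordinates when three or more reads agree on the
   junction position.

Concordant and discordant evidence compete inside one objective, so a
junction is called only when rearranging the genome explains more reads
than leaving it alone — this is what suppresses the spurious calls that
plague per-junction read-count thresholds.

## Worked example

```sh
python examples/02_predict_tsvs.py
```

builds a 2 x 100-kb synthetic genome with 20 genes and six planted SVs,
samples ~2,200 read pairs from the original transcriptome against the
rearranged reference, and prints:

```
segments: 185
edges: 178 built, 156 after filters
components solved: 95
TSV calls: 3

#chrom1	start1	end1	chrom2	start2	end2	name	score	strand1	strand2
chr1	50670	50671	chr1	51766	51767	tsv_0	36	+	+
chr1	77153	77154	chr2	39435	39436	tsv_1	43	+	-
chr2	7737	7738	chr2	10157	10158	tsv_2	47	+	+
```

`tsv_0` and `tsv_2` are inversion junctions (`+/+`: both upstream flanks
retained), `tsv_1` is a translocation junction joining chr1 to chr2
(`+/-`); the score is the number of supporting read alignments. All three
match the generator's ground truth at exact coordinates — the three planted
junctions that are observable from RNA-seq (deletions, tandem duplications
and novel insertions leave only clipped reads or intron-like gaps; see
`docs/methods.md`). The other examples cover simulation
(`01_simulate_dataset.py`), scoring (`03_evaluate_predictions.py`),
breakpoint-partner entropy (`04_partner_entropy.py`) and the ILP-vs-
enumeration oracle (`05_ilp_vs_enumeration.py`).

The same pipeline runs from the shell on SAM/BAM input:

```sh
rnasv simulate --out-dir sim --seed 3
rnasv predict --bam sim/alignments.sam --out pred.bedpe --theta 3
rnasv evaluate --pred pred.bedpe --truth sim/truth.bedpe
```

Key parameters: `--alpha` (discordant edge weight, the assumed
normal/tumor transcript ratio; default 1), `--theta` (minimum read support
per edge; default 5), `--gamma` (maximum distinct discordant neighbors per
segment; default 5).

## Layout

- `src/rnasv/alignments.py` — SAM parsing, concordance classification
- `src/rnasv/segmentation.py` — breakpoints and genome partitioning
- `src/rnasv/gsg.py` — the genome segment graph, compatibility, filters
- `src/rnasv/ilp.py` — MILP formulation, exhaustive oracle, components
- `src/rnasv/calls.py` — TSV extraction, refinement, BEDPE I/O
- `src/rnasv/simulate.py` — synthetic genomes, SVs, analytic alignments
- `src/rnasv/evaluate.py` — matching, metrics, partner entropy
- `src/rnasv/pipeline.py`, `src/rnasv/cli.py` — end-to-end and CLI

See `docs/methods.md` for the model, parameter semantics, numerical
choices, and known limitations.
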