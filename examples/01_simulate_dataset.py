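"""Build a small synthetic dataset: genome, planted SVs, truth, alignments.

A 2x100-kb genome with 20 genes receives six gene-hitting structural
variants; reads are sampled from the original transcriptome and aligned
(analytically) to the rearranged genome, which plays the role of the
alignment reference.
"""

from rnasv.simulate import simulate_dataset

ds = simulate_dataset(seed=7, noise_rate=0.01)

print(f"chromosomes: { {c: len(s) for c, s in ds.rearranged.items()} }")
print(f"genes: {len(ds.annotation)}, read pairs: {len(ds.pairs)}")
print("planted SVs:")
for sv in ds.svs:
    dest = f" -> {sv.dest_chrom}:{sv.dest_pos}" if sv.dest_chrom else ""
    print(f"  {sv.type:14s} {sv.chrom}:{sv.start}-{sv.end}{dest}")
print(f"ground-truth TSV junctions (observable from RNA-seq): {len(ds.truth)}")
for t in ds.truth:
    print(f"  {t.bp1.chrom}:{t.bp1.pos}({t.bp1.side}) -- {t.bp2.chrom}:{t.bp2.pos}({t.bp2.side})")

# Not every SV junction is observable: deletions clip reads, and tandem
# duplications / novel insertions leave intron-like forward gaps, so only
# inversion and translocation junctions inside genes appear as truth.
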