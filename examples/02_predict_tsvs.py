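"""Predict TSVs end to end and print the BEDPE output.

The pipeline classifies read pairs, partitions the genome into segments,
builds the weighted genome segment graph, solves the rearrangement ILP per
connected component, and reports initially-discordant edges realized by the
optimal arrangement.
"""

import sys

from rnasv.calls import write_predictions
from rnasv.pipeline import predict_from_pairs
from rnasv.simulate import simulate_dataset

ds = simulate_dataset(seed=7, noise_rate=0.01)
res = predict_from_pairs(ds.pairs, ds.chrom_lengths, alpha=1.0, theta=3, gamma=5)

print(f"segments: {len(res.segments)}")
print(f"edges: {len(res.graph.edges)} built, {len(res.filtered.edges)} after filters")
print(f"components solved: {len(res.solutions)}")
print(f"TSV calls: {len(res.calls)}\n")
write_predictions(res.calls, sys.stdout)

# Each line is one junction: strand '+' means the sequence upstream of the
# breakpoint is retained in the variant, '-' the downstream sequence; the
# score is the number of supporting read alignments.
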