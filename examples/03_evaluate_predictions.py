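"""Score predictions against ground truth with the 30-kb matching rule.

A prediction is a true positive when both breakpoints lie within 30 kb of a
truth record's breakpoints on the right chromosomes and the retained-flank
orientations agree; each truth record consumes at most one prediction.
"""

from rnasv.evaluate import match
from rnasv.pipeline import predict_from_pairs
from rnasv.simulate import simulate_dataset

tp = fp = fn = 0
for seed in range(5):
    ds = simulate_dataset(seed=seed, noise_rate=0.0)
    res = predict_from_pairs(ds.pairs, ds.chrom_lengths, theta=3)
    m = match(res.calls, ds.truth, window_bp=30_000)
    print(f"replicate {seed}: truth={len(ds.truth)} calls={len(res.calls)} "
          f"TP={m.true_positives} FP={m.false_positives} FN={m.false_negatives}")
    tp += m.true_positives
    fp += m.false_positives
    fn += m.false_negatives

print(f"\npooled precision   {tp / (tp + fp):.3f}")
print(f"pooled sensitivity {tp / (tp + fn):.3f}")
# Precision counts how many reported junctions are real; sensitivity how
# many observable planted junctions were recovered.
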