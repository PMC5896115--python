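"""Breakpoint-partner entropy over a cohort of samples.

Pooling calls across replicates that share one recurrent rearrangement,
each recurrent breakpoint (>= 3 occurrences, 10-kb bins) gets the Shannon
entropy of its empirical partner distribution: 0 bits means the breakpoint
always rejoins the same partner; higher values mean promiscuous joining.
"""

from rnasv.calls import Breakpoint, TSVCall
from rnasv.evaluate import partner_entropy
from rnasv.segmentation import HEAD, TAIL

# a faithful partner seen in 4 samples plus one promiscuous breakpoint
calls = [
    TSVCall.ordered(Breakpoint("chr1", 50_000, TAIL), Breakpoint("chr2", 80_000, HEAD), 9)
    for _ in range(4)
]
calls += [
    TSVCall.ordered(Breakpoint("chr3", 10_000, TAIL), Breakpoint("chr4", 20_000, HEAD), 5),
    TSVCall.ordered(Breakpoint("chr3", 12_000, TAIL), Breakpoint("chr5", 30_000, HEAD), 5),
    TSVCall.ordered(Breakpoint("chr3", 14_000, TAIL), Breakpoint("chr6", 40_000, HEAD), 5),
]

for (chrom, bin_idx), h in sorted(partner_entropy(calls, min_recurrence=3).items()):
    print(f"breakpoint bin {chrom}:{bin_idx * 10_000}-{(bin_idx + 1) * 10_000}: "
          f"{h:.3f} bits")
# chr1's breakpoint has one fixed partner (0 bits); chr3's rejoins three
# different partners (log2 3 = 1.585 bits).
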