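"""Solve one segment-ordering instance and verify it against enumeration.

Two segments, a weak reference-concordant edge (weight 1) against a strong
tail-tail edge (weight 5): inverting the second segment satisfies the heavy
edge, and the exhaustive search over all 2! x 2^2 arrangements agrees.
"""

from rnasv.gsg import Arrangement, Edge, SegmentGraph, compatible
from rnasv.ilp import brute_force_optimum, optimize_component
from rnasv.segmentation import HEAD, TAIL, Segment, SegmentEnd

segs = [Segment(id=i, chrom="chr1", start=i * 100, end=(i + 1) * 100) for i in range(2)]
ref = Arrangement.reference(segs)
edges = {}
for (su, sv), w in {(TAIL, HEAD): 1, (TAIL, TAIL): 5}.items():
    key = (SegmentEnd(0, su), SegmentEnd(1, sv))
    edges[key] = Edge(end_a=key[0], end_b=key[1], raw_count=w,
                      reference_concordant=compatible(key, ref))
g = SegmentGraph(segments=segs, edges=edges, alpha=1.0)

milp = optimize_component(g)
brute = brute_force_optimum(g)
print(f"MILP objective:        {milp.objective}")
print(f"enumeration objective: {brute.objective}")
print(f"segment 1 orientation: {'inverted' if milp.arrangement.orient[1] == 0 else 'forward'}")
sat = sorted((k[0].segment_id, k[0].side, k[1].segment_id, k[1].side) for k in milp.satisfied)
print(f"satisfied edges:       {sat}")
# The optimum (5) sacrifices the concordant edge; the satisfied tail-tail
# edge is exactly the junction an inversion of segment 1 would create.
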