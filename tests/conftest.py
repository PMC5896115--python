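import numpy as np
import pytest

from rnasv.gsg import Arrangement, Edge, SegmentGraph, compatible
from rnasv.segmentation import HEAD, TAIL, Segment, SegmentEnd
from rnasv.simulate import simulate_dataset


def random_component(rng, max_segs=6, max_edges=10, weight_hi=10):
    """A random small segment graph: the shared test-instance generator."""
    n = int(rng.integers(2, max_segs + 1))
    segs = [Segment(id=i, chrom="c", start=i * 100, end=(i + 1) * 100) for i in range(n)]
    ref = Arrangement.reference(segs)
    m = int(rng.integers(1, max_edges + 1))
    edges = {}
    for _ in range(m):
        u, v = sorted(rng.choice(n, size=2, replace=False))
        su = HEAD if rng.random() < 0.5 else TAIL
        sv = HEAD if rng.random() < 0.5 else TAIL
        key = (SegmentEnd(int(u), su), SegmentEnd(int(v), sv))
        w = int(rng.integers(1, weight_hi + 1))
        if key in edges:
            edges[key].raw_count += w
        else:
            edges[key] = Edge(
                end_a=key[0], end_b=key[1], raw_count=w,
                reference_concordant=compatible(key, ref),
            )
    return SegmentGraph(segments=segs, edges=edges, alpha=1.0)


def random_arrangement(rng, segments):
    ids = [s.id for s in segments]
    perm = rng.permutation(len(ids))
    return Arrangement(
        order={u: int(perm[i]) for i, u in enumerate(ids)},
        orient={u: int(rng.integers(0, 2)) for u in ids},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic replicate shared across tests."""
    return simulate_dataset(seed=7, noise_rate=0.01)


@pytest.fixture(scope="session")
def null_dataset():
    """A replicate with no planted SVs."""
    return simulate_dataset(
        seed=11, n_genes=8, chrom_len=50_000,
        counts_per_type={t: 0 for t in ("deletion", "inversion", "insertion", "duplication", "translocation")},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
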