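"""Ordering and orienting segments to maximize compatible edge weight.

Each connected component of the segment graph is solved independently: the
objective decomposes over components because no edge crosses them.  The
search is over all permutations and orientations of the component's
segments; it is encoded as a 0/1 integer linear program with

*  ``y_u``  = 1 iff segment ``u`` is head-first in the solution,
*  ``z_uv`` = 1 iff ``u`` precedes ``v`` (``z_vu`` is substituted as
   ``1 - z_uv``; ordered triples carry ``1 <= z_uv + z_vw + z_wu <= 2`` so
   the relation is a total order),
*  ``x_e``  = 1 iff edge ``e`` is compatible with the solution, linked to
   ``y``/``z`` by four inequalities per edge whose form depends on the
   endpoint sides (tail-head, tail-tail, head-head, head-tail).

The MILP is solved with HiGHS via :func:`scipy.optimize.milp`.  An
exhaustive enumerator over all ``|S|! * 2^|S|`` arrangements serves as an
independent oracle for small components and as an automatic fallback when
the solver is unavailable.

Ties between optima are broken lexicographically: first maximize total
compatible weight, then the number of satisfied reference-concordant edges,
then the number of forward (head-first) segments.  The secondary terms enter
the MILP objective with coefficients far below the weight granularity
(exact for integer edge weights, the default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .gsg import Arrangement, Edge, EndpointPair, SegmentGraph, compatible
from .segmentation import HEAD, TAIL

log = logging.getLogger(__name__)

BRUTE_FORCE_MAX = 8


@dataclass
class Solution:
    """An arrangement of one component plus its achieved objective."""

    arrangement: Arrangement
    objective: float
    satisfied: set[EndpointPair]
    optimal: bool = True


def components(g: SegmentGraph) -> list[SegmentGraph]:
    """Split a graph into its edge-connected components.

    Segments without edges become singleton components.  The union of the
    components' edges is exactly the input edge set.
    """
    adj: dict[int, set[int]] = {s.id: set() for s in g.segments}
    for e in g.edges.values():
        adj[e.end_a.segment_id].add(e.end_b.segment_id)
        adj[e.end_b.segment_id].add(e.end_a.segment_id)
    seen: set[int] = set()
    out: list[SegmentGraph] = []
    by_id = {s.id: s for s in g.segments}
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        seen.add(start)
        while frontier:
            u = frontier.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    frontier.append(v)
        edges = {
            k: e for k, e in g.edges.items() if e.end_a.segment_id in comp
        }
        out.append(
            SegmentGraph(
                segments=[by_id[i] for i in sorted(comp)],
                edges=edges,
                alpha=g.alpha,
            )
        )
    return out


def _identity_solution(gc: SegmentGraph, *, optimal: bool = True) -> Solution:
    ids = sorted(s.id for s in gc.segments)
    arr = Arrangement(order={u: i for i, u in enumerate(ids)}, orient={u: 1 for u in ids})
    satisfied = {k for k, e in gc.edges.items() if e.reference_concordant}
    objective = sum(gc.edges[k].weight(gc.alpha) for k in satisfied)
    return Solution(arrangement=arr, objective=objective, satisfied=satisfied, optimal=optimal)


def _edge_rows(edge: Edge, yu: int, yv: int, z: int, x: int):
    """The four compatibility inequalities for one edge, as sparse rows.

    Rows are (coeff dict, upper bound) for ``sum coeff*var <= ub``; the
    family is chosen by the endpoint sides with ``u`` the lower-id segment.
    """
    su, sv = edge.end_a.side, edge.end_b.side
    if su == TAIL and sv == HEAD:
        # x=1 -> y_u = y_v = z_uv
        return [
            ({x: 1, yu: -1, yv: 1}, 1),
            ({x: 1, yu: 1, yv: -1}, 1),
            ({x: 1, yu: -1, z: 1}, 1),
            ({x: 1, yu: 1, z: -1}, 1),
        ]
    if su == TAIL and sv == TAIL:
        # x=1 -> y_u = 1 - y_v,  z_uv = y_u
        return [
            ({x: 1, yu: -1, yv: -1}, 0),
            ({x: 1, yu: 1, yv: 1}, 2),
            ({x: 1, yu: -1, z: 1}, 1),
            ({x: 1, yu: 1, z: -1}, 1),
        ]
    if su == HEAD and sv == HEAD:
        # x=1 -> y_v = 1 - y_u,  z_uv = 1 - y_u
        return [
            ({x: 1, yu: 1, yv: 1}, 2),
            ({x: 1, yu: -1, yv: -1}, 0),
            ({x: 1, yu: 1, z: 1}, 2),
            ({x: 1, yu: -1, z: -1}, 0),
        ]
    # head-tail: x=1 -> y_u = y_v,  z_uv = 1 - y_u
    return [
        ({x: 1, yu: -1, yv: 1}, 1),
        ({x: 1, yu: 1, yv: -1}, 1),
        ({x: 1, yu: 1, z: 1}, 2),
        ({x: 1, yu: -1, z: -1}, 0),
    ]


def _solve_milp(gc: SegmentGraph) -> Solution | None:
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import csr_matrix

    ids = sorted(s.id for s in gc.segments)
    n = len(ids)
    local = {u: i for i, u in enumerate(ids)}
    edges = [gc.edges[k] for k in sorted(gc.edges)]
    m = len(edges)

    pair_index = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair_index[(i, j)] = n + len(pair_index)
    nz = len(pair_index)
    x0 = n + nz
    nvar = x0 + m

    rows: list[tuple[dict[int, float], float, float]] = []  # coeffs, lb, ub
    for ei, e in enumerate(edges):
        lu, lv = local[e.end_a.segment_id], local[e.end_b.segment_id]
        z = pair_index[(lu, lv)]
        for coeffs, ub in _edge_rows(e, lu, lv, z, x0 + ei):
            rows.append((coeffs, -np.inf, ub))
    # total order: 0 <= z_ij + z_jk - z_ik <= 1 for i<j<k
    for i, j, k in itertools.combinations(range(n), 3):
        rows.append((
            {pair_index[(i, j)]: 1, pair_index[(j, k)]: 1, pair_index[(i, k)]: -1},
            0, 1,
        ))

    # lexicographic tie-break epsilons: reference-concordant count, then
    # forward-segment count; exact for integer weight sums (gap >= 1)
    eps1 = 0.45 / (m + 1)
    eps2 = eps1 / (n + 1)
    c = np.zeros(nvar)
    for ei, e in enumerate(edges):
        c[x0 + ei] = -(e.weight(gc.alpha) + (eps1 if e.reference_concordant else 0.0))
    for i in range(n):
        c[i] = -eps2

    if rows:
        data, ri, ci, lb, ub = [], [], [], [], []
        for r, (coeffs, lo, hi) in enumerate(rows):
            for var, coef in coeffs.items():
                ri.append(r)
                ci.append(var)
                data.append(coef)
            lb.append(lo)
            ub.append(hi)
        A = csr_matrix((data, (ri, ci)), shape=(len(rows), nvar))
        constraints = [LinearConstraint(A, lb, ub)]
    else:
        constraints = []

    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(nvar),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        return None

    xv = np.round(res.x).astype(int)
    orient = {u: int(xv[local[u]]) for u in ids}
    before = {u: 0 for u in ids}
    for (i, j), zi in pair_index.items():
        if xv[zi] == 1:
            before[ids[j]] += 1  # i before j
        else:
            before[ids[i]] += 1
    # before-counts of a total order are exactly the ranks 0..n-1
    arr = Arrangement(order={u: before[u] for u in ids}, orient=orient)
    satisfied = {k for k in gc.edges if compatible(k, arr)}
    objective = sum(gc.edges[k].weight(gc.alpha) for k in satisfied)
    return Solution(arrangement=arr, objective=objective, satisfied=satisfied)


def optimize_component(gc: SegmentGraph, *, max_segments: int = 200) -> Solution:
    """Best arrangement of one connected component.

    Components whose edges are all reference-concordant short-circuit to the
    identity arrangement (provably optimal there).  Components larger than
    ``max_segments`` are skipped with a warning and keep the identity
    arrangement, flagged non-optimal.
    """
    if not gc.segments:
        raise ValueError("empty component")
    if not gc.edges or all(e.reference_concordant for e in gc.edges.values()):
        return _identity_solution(gc)
    if len(gc.segments) > max_segments:
        log.warning(
            "component with %d segments exceeds cap %d; keeping identity",
            len(gc.segments), max_segments,
        )
        return _identity_solution(gc, optimal=False)
    try:
        sol = _solve_milp(gc)
    except Exception as exc:  # solver unavailable
        log.warning("MILP solver failed (%s); falling back to enumeration", exc)
        sol = None
    if sol is None:
        if len(gc.segments) <= BRUTE_FORCE_MAX:
            return brute_force_optimum(gc)
        log.warning("no solver and component too large to enumerate; keeping identity")
        return _identity_solution(gc, optimal=False)
    return sol


def brute_force_optimum(gc: SegmentGraph) -> Solution:
    """Exhaustive maximum over all arrangements of a small component.

    Deterministic tie-break identical to the MILP: (objective, number of
    satisfied reference-concordant edges, number of forward segments),
    first-found among equals in enumeration order.
    """
    ids = sorted(s.id for s in gc.segments)
    n = len(ids)
    if n > BRUTE_FORCE_MAX:
        raise ValueError(f"component too large to enumerate ({n} > {BRUTE_FORCE_MAX})")
    local = {u: i for i, u in enumerate(ids)}
    edges = [gc.edges[k] for k in sorted(gc.edges)]
    w = np.array([e.weight(gc.alpha) for e in edges])
    ref = np.array([1 if e.reference_concordant else 0 for e in edges])

    # all orientation assignments as a (2^n, n) 0/1 matrix
    O = np.array(list(itertools.product((1, 0), repeat=n)), dtype=np.int8)
    ends = [
        (
            (local[e.end_a.segment_id], e.end_a.side == HEAD),
            (local[e.end_b.segment_id], e.end_b.side == HEAD),
        )
        for e in edges
    ]

    best = None
    for perm in itertools.permutations(range(n)):
        rank = {perm[r]: r for r in range(n)}
        if edges:
            compat = np.ones((O.shape[0], len(edges)), dtype=bool)
            for ei, ((lu, u_head), (lv, v_head)) in enumerate(ends):
                ind = 1 if rank[lv] < rank[lu] else 0
                fu = O[:, lu] if u_head else 1 - O[:, lu]
                fv = O[:, lv] if v_head else 1 - O[:, lv]
                compat[:, ei] = (fu == ind) & (1 - fv == ind)
            obj = compat @ w
            refcnt = compat @ ref
        else:
            obj = np.zeros(O.shape[0])
            refcnt = np.zeros(O.shape[0])
        bits = O.sum(axis=1)
        oi = int(np.lexsort((-bits, -refcnt, -obj))[0])
        key = (obj[oi], refcnt[oi], bits[oi])
        if best is None or key > best[0]:
            best = (key, perm, O[oi].copy())

    (objective, _, _), perm, obits = best
    arr = Arrangement(
        order={ids[i]: perm.index(i) for i in range(n)},
        orient={ids[i]: int(obits[i]) for i in range(n)},
    )
    satisfied = {k for k in gc.edges if compatible(k, arr)}
    return Solution(arrangement=arr, objective=float(objective), satisfied=satisfied)


def solve_graph(g: SegmentGraph, *, max_segments: int = 200) -> list[tuple[SegmentGraph, Solution]]:
    """Solve every connected component of a (filtered) segment graph."""
    return [
        (gc, optimize_component(gc, max_segments=max_segments))
        for gc in components(g)
    ]
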