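"""Strahler ordering and junction classification.

After rooting, each vessel tree gets Strahler orders on its edges
(segments): terminal segments are order 1, and a parent's order increases
by one only where at least two daughters share the maximal daughter
order. Junctions are then classified by their daughter orders —
*branching* where a smaller side vessel leaves the main vessel (daughter
orders differ) and *bifurcation* where a vessel divides into two similar
vessels (daughter orders equal). Degree-4 skeleton nodes are crossings of
two distinct vessels, not anatomical junctions; they are resolved into
two pass-through paths before ordering by pairing incident edges for
maximal tangent continuity.
"""

from __future__ import annotations

import numpy as np

from .graph import SkeletonGraph, _orient_from

__all__ = [
    "JunctionClass",
    "resolve_crossings",
    "assign_strahler",
    "classify_junction",
    "edge_tangent",
]


class JunctionClass:
    BRANCHING = "branching"
    BIFURCATION = "bifurcation"
    CROSSING = "crossing"


def edge_tangent(edge, node_id: int, fit_length: float = 10.0, skip: float = 0.0) -> np.ndarray:
    """Unit tangent of ``edge`` at ``node_id``, pointing away from the node.

    Fitted as the principal axis of the path points whose arc-length
    position (from the node end) lies in ``[skip, skip + fit_length]``,
    oriented outward.
    """
    path = edge.path if edge.nodes[0] == node_id else edge.path[::-1]
    if len(path) < 2:
        return np.array([0.0, 0.0])
    steps = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    sel = (s >= skip) & (s <= skip + fit_length)
    pts = path[sel]
    if len(pts) < 2:  # short edge: use whole path
        pts = path
    centered = pts - pts.mean(axis=0)
    # principal direction via SVD; orient along increasing arc length
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([0.0, 0.0])


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def resolve_crossings(graph: SkeletonGraph) -> SkeletonGraph:
    """Split every degree-4 node into two pass-through vessel paths.

    The four incident edges are paired to maximize tangent continuity
    (each edge paired with the one closest to a straight 180°
    continuation); ties are broken by diameter similarity. The node is
    removed and paired edges merged, so the result is a forest of simple
    vessels. Nodes of degree ≥ 5 are flagged pathological and left
    untouched (they are excluded from measurement downstream).
    """
    g = graph.copy()
    changed = False
    for nid in list(g.nodes):
        inc = g.incident(nid)
        deg = sum((e.nodes[0] == nid) + (e.nodes[1] == nid) for e in inc)
        if deg >= 5:
            if "pathological_degree" not in g.nodes[nid].flags:
                g.nodes[nid].flags.append("pathological_degree")
            continue
        if deg != 4 or len(inc) != 4:  # self-loops at the node: leave alone
            continue
        tangents = [edge_tangent(e, nid) for e in inc]
        diams = [e.mean_diameter for e in inc]
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]

        def score(pairing):
            # continuity error: 0 when each pair is a straight continuation
            err = sum(180.0 - _angle_between(tangents[a], tangents[b]) for a, b in pairing)
            dsim = sum(
                abs((diams[a] or 0.0) - (diams[b] or 0.0))
                if np.isfinite(diams[a]) and np.isfinite(diams[b])
                else 0.0
                for a, b in pairing
            )
            return (round(err, 6), dsim)

        best = min(pairings, key=score)
        node_pos = g.nodes[nid].position
        for a, b in best:
            ea, eb = inc[a], inc[b]
            pa = ea.path if ea.nodes[1] == nid else ea.path[::-1]
            u = ea.nodes[0] if ea.nodes[1] == nid else ea.nodes[1]
            pb = eb.path if eb.nodes[0] == nid else eb.path[::-1]
            v = eb.nodes[1] if eb.nodes[0] == nid else eb.nodes[0]
            path = np.vstack([pa, pb[1:]])
            la, lb = ea.length, eb.length
            if la + lb > 0 and np.isfinite(ea.mean_diameter) and np.isfinite(eb.mean_diameter):
                diam = (ea.mean_diameter * la + eb.mean_diameter * lb) / (la + lb)
            else:
                diam = ea.mean_diameter
            g.remove_edge(ea.id)
            g.remove_edge(eb.id)
            g.add_edge(u, v, path, mean_diameter=diam,
                       flags=sorted(set(ea.flags) | set(eb.flags) | {"through_crossing"}))
        g.remove_node(nid)
        changed = True
    if changed and g.directed:
        # merging may have flipped directions; re-orient from the roots
        g.roots = [r for r in g.roots if r in g.nodes]
        for comp in g.components():
            roots = [r for r in g.roots if r in comp]
            if roots:
                _orient_from(g, roots[0], comp)
    return g


def assign_strahler(graph: SkeletonGraph) -> SkeletonGraph:
    """Assign a Strahler order to every edge of a rooted, directed forest.

    Terminal edges get order 1; a parent's order is ``m + 1`` when two or
    more daughters attain the maximal daughter order ``m``, else ``m``.
    Raises on directed cycles (crossings must be resolved first).
    """
    if not graph.directed:
        raise ValueError("assign_strahler requires a rooted, directed graph")
    g = graph
    out_by_node: dict[int, list] = {nid: [] for nid in g.nodes}
    for e in g.edges.values():
        if e.nodes[0] == e.nodes[1]:
            e.strahler_order = 1
            e.flags.append("self_loop")
            continue
        out_by_node[e.nodes[0]].append(e)

    def order_of(edge, stack: frozenset) -> int:
        if edge.strahler_order is not None:
            return edge.strahler_order
        if edge.id in stack:
            raise ValueError("directed cycle detected; resolve crossings upstream")
        daughters = out_by_node.get(edge.nodes[1], [])
        if not daughters:
            edge.strahler_order = 1
            return 1
        sub = stack | {edge.id}
        orders = [order_of(d, sub) for d in daughters]
        m = max(orders)
        edge.strahler_order = m + 1 if orders.count(m) >= 2 else m
        return edge.strahler_order

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        for e in g.edges.values():
            order_of(e, frozenset())
    finally:
        sys.setrecursionlimit(old)
    return g


def classify_junction(daughter_orders, daughter_diameters=None) -> str:
    """Classify a junction from its daughter Strahler orders.

    Two daughters with equal orders → bifurcation; unequal → branching.
    With more than two daughters the two largest-diameter daughters decide
    (requires ``daughter_diameters``).
    """
    orders = list(daughter_orders)
    if len(orders) < 2:
        raise ValueError("a junction needs at least 2 daughters")
    if len(orders) > 2:
        if daughter_diameters is None:
            raise ValueError("daughter_diameters required for >2 daughters")
        idx = np.argsort(daughter_diameters)[::-1][:2]
        orders = [orders[i] for i in idx]
    return JunctionClass.BIFURCATION if orders[0] == orders[1] else JunctionClass.BRANCHING
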