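"""Centerline graph extraction from binary vessel masks.

A segmented vessel mask (one per vessel class — artery or vein) is reduced
to a one-pixel-wide skeleton, which is then converted into a graph whose
nodes are anatomical landmarks (endpoints, junctions, later crossings and
roots) and whose edges carry the ordered centerline pixel path, its arc
length, and a mean vessel diameter estimated from the Euclidean distance
transform of the mask.

Conventions: 0-based (row, col) coordinates, continuous node positions
(junction-cluster centroids), all lengths in pixels, angles in degrees.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "RasterMask",
    "DiscGeometry",
    "Node",
    "Edge",
    "SkeletonGraph",
    "skeletonize",
    "build_graph",
    "prune_spurs",
    "estimate_diameters",
    "root_components",
    "extract_graph",
    "graph_to_json",
]

# 8-neighbour offsets, 4-connected first so straight steps are preferred
# during path tracing.
_NBRS = [(-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass(frozen=True)
class RasterMask:
    """Binary vessel raster for one vessel class."""

    grid: np.ndarray
    vessel_class: str = "artery"
    pixel_size: float = 1.0

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        object.__setattr__(self, "grid", g.astype(bool))
        if self.vessel_class not in ("artery", "vein"):
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class DiscGeometry:
    """Optic-disc center (row, col) and diameter, in pixels.

    Defines the measurement annulus (0.5–2.0 disc diameters outward from
    the disc edge) and the vertex of the main angle.
    """

    center: tuple[float, float]
    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("disc diameter must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @classmethod
    def from_json(cls, path) -> "DiscGeometry":
        with open(path) as fh:
            d = json.load(fh)
        try:
            return cls(center=tuple(d["center"]), diameter=float(d["diameter"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid disc annotation {path}: {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"center": list(self.center), "diameter": self.diameter}, fh)


@dataclass
class Node:
    id: int
    position: np.ndarray  # (row, col) float
    landmark: str = "endpoint"  # endpoint | junction | crossing | root
    pixels: list = field(default_factory=list)  # cluster pixels (row, col) ints
    flags: list = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class Edge:
    id: int
    nodes: tuple[int, int]  # (u, v); after rooting: directed u -> v
    path: np.ndarray  # (k, 2) float, ordered u -> v, endpoints = node positions
    length: float = 0.0
    mean_diameter: float = float("nan")
    strahler_order: int | None = None
    flags: list = field(default_factory=list)

    @property
    def interior(self) -> np.ndarray:
        """Path points excluding the two node-position endpoints."""
        return self.path[1:-1]


def _path_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.hypot(*np.diff(path, axis=0).T).sum())


class SkeletonGraph:
    """Pixel-path multigraph of a vessel skeleton.

    Supports parallel edges and self-loops (both can arise from thinning
    artifacts); stores nodes and edges in id-keyed dicts.
    """

    def __init__(self, shape: tuple[int, int], vessel_class: str = "artery"):
        self.shape = shape
        self.vessel_class = vessel_class
        self.nodes: dict[int, Node] = {}
        self.edges: dict[int, Edge] = {}
        self._next_node = 0
        self._next_edge = 0
        self.directed = False
        self.roots: list[int] = []

    # -- construction -----------------------------------------------------
    def add_node(self, position, landmark="endpoint", pixels=None) -> int:
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = Node(nid, np.asarray(position, float), landmark, list(pixels or []))
        return nid

    def add_edge(self, u: int, v: int, path: np.ndarray, **kw) -> int:
        eid = self._next_edge
        self._next_edge += 1
        path = np.asarray(path, float)
        e = Edge(eid, (u, v), path, length=_path_length(path), **kw)
        self.edges[eid] = e
        return eid

    def remove_edge(self, eid: int) -> None:
        del self.edges[eid]

    def remove_node(self, nid: int) -> None:
        del self.nodes[nid]

    # -- queries ----------------------------------------------------------
    def incident(self, nid: int) -> list[Edge]:
        return [e for e in self.edges.values() if nid in e.nodes]

    def degree(self, nid: int) -> int:
        d = 0
        for e in self.edges.values():
            d += (e.nodes[0] == nid) + (e.nodes[1] == nid)
        return d

    def out_edges(self, nid: int) -> list[Edge]:
        if not self.directed:
            raise ValueError("graph is not rooted/directed")
        return [e for e in self.edges.values() if e.nodes[0] == nid]

    def in_edges(self, nid: int) -> list[Edge]:
        if not self.directed:
            raise ValueError("graph is not rooted/directed")
        return [e for e in self.edges.values() if e.nodes[1] == nid]

    def components(self) -> list[set[int]]:
        """Connected components as sets of node ids."""
        adj: dict[int, set[int]] = {nid: set() for nid in self.nodes}
        for e in self.edges.values():
            adj[e.nodes[0]].add(e.nodes[1])
            adj[e.nodes[1]].add(e.nodes[0])
        seen: set[int] = set()
        comps = []
        for nid in self.nodes:
            if nid in seen:
                continue
            comp = {nid}
            stack = [nid]
            while stack:
                cur = stack.pop()
                for nxt in adj[cur]:
                    if nxt not in comp:
                        comp.add(nxt)
                        stack.append(nxt)
            seen |= comp
            comps.append(comp)
        return comps

    def copy(self) -> "SkeletonGraph":
        g = SkeletonGraph(self.shape, self.vessel_class)
        g.nodes = {
            nid: Node(n.id, n.position.copy(), n.landmark, list(n.pixels), list(n.flags))
            for nid, n in self.nodes.items()
        }
        g.edges = {
            eid: replace(e, path=e.path.copy(), flags=list(e.flags))
            for eid, e in self.edges.items()
        }
        g._next_node = self._next_node
        g._next_edge = self._next_edge
        g.directed = self.directed
        g.roots = list(self.roots)
        return g

    def total_length(self) -> float:
        return sum(e.length for e in self.edges.values())


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize(mask: RasterMask) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, 8-connected skeleton.

    The skeleton is a subset of the foreground; thinning an already
    1-px-wide structure leaves it unchanged (idempotence).
    """
    grid = mask.grid if isinstance(mask, RasterMask) else np.asarray(mask, bool)
    if not grid.any():
        warnings.warn("empty mask: skeleton is empty", stacklevel=2)
        return np.zeros_like(grid, dtype=bool)
    return _sk_skeletonize(grid)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant") * skel


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(skel: np.ndarray, vessel_class: str = "artery") -> SkeletonGraph:
    """Convert a 1-px skeleton into a :class:`SkeletonGraph`.

    Node pixels are skeleton pixels with ≠2 eight-neighbours. Adjacent
    junction pixels (≥3 neighbours) are merged into a single node at their
    centroid; endpoints and isolated pixels become singleton nodes. Edges
    trace maximal degree-2 pixel paths between node pixels. Every skeleton
    pixel lands in exactly one node cluster or one edge interior.
    """
    skel = np.asarray(skel, bool)
    g = SkeletonGraph(skel.shape, vessel_class)
    if not skel.any():
        return g

    counts = _neighbor_counts(skel)
    junction_px = skel & (counts >= 3)
    end_px = skel & (counts <= 1)

    px2node: dict[tuple[int, int], int] = {}

    lbl, nlbl = ndimage.label(junction_px, structure=np.ones((3, 3)))
    for i in range(1, nlbl + 1):
        pix = np.argwhere(lbl == i)
        nid = g.add_node(pix.mean(axis=0), "junction", [tuple(p) for p in pix])
        for p in pix:
            px2node[tuple(p)] = nid
    for p in np.argwhere(end_px):
        nid = g.add_node(p.astype(float), "endpoint", [tuple(p)])
        px2node[tuple(p)] = nid

    H, W = skel.shape

    def nbrs(p):
        r, c = p
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                yield (rr, cc)

    used = np.zeros_like(skel)  # interior pixels consumed by an edge
    done_pairs: set[tuple] = set()  # direct node-node adjacencies already linked

    def add_edge_path(nid_a, interior, nid_b):
        pts = [g.nodes[nid_a].position]
        pts.extend(np.asarray(p, float) for p in interior)
        pts.append(g.nodes[nid_b].position)
        g.add_edge(nid_a, nid_b, np.asarray(pts))

    # trace from every node pixel into each unvisited degree-2 neighbour
    for start_px, nid in list(px2node.items()):
        for q in nbrs(start_px):
            if q in px2node:
                other = px2node[q]
                if other != nid or q != start_px:
                    key = (min(start_px, q), max(start_px, q))
                    if other is not None and q != start_px and key not in done_pairs:
                        # direct adjacency between two distinct node pixels:
                        # only link if different clusters (same-cluster pairs
                        # are internal adjacencies, not edges)
                        if other != nid:
                            done_pairs.add(key)
                            add_edge_path(nid, [], other)
                continue
            if used[q]:
                continue
            # walk the degree-2 chain
            interior = [q]
            used[q] = True
            prev, cur = start_px, q
            while True:
                nxt = [p for p in nbrs(cur) if p != prev]
                # drop neighbours already in the interior (diagonal shortcuts)
                nxt = [p for p in nxt if p in px2node or not used[p]]
                if not nxt:
                    # dead end without an endpoint pixel: shouldn't happen on
                    # clean skeletons; make the last pixel a node
                    end_id = g.add_node(np.asarray(cur, float), "endpoint", [cur])
                    px2node[cur] = end_id
                    interior.pop()
                    used[cur] = False
                    add_edge_path(nid, interior, end_id)
                    break
                p = nxt[0]
                if p in px2node:
                    add_edge_path(nid, interior, px2node[p])
                    break
                interior.append(p)
                used[p] = True
                prev, cur = cur, p

    # pure cycles (no node pixel): anchor each on an arbitrary pixel
    remaining = skel & ~used
    for p in list(map(tuple, np.argwhere(remaining))):
        if used[p] or p in px2node:
            continue
        nid = g.add_node(np.asarray(p, float), "junction", [p])
        px2node[p] = nid
        ring = []
        neighbours = [q for q in nbrs(p) if q not in px2node]
        if not neighbours:
            continue
        prev, cur = p, neighbours[0]
        while cur != p and cur not in px2node:
            ring.append(cur)
            used[cur] = True
            nxt = [q for q in nbrs(cur) if q != prev and (q == p or not used[q])]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        add_edge_path(nid, ring, nid)

    return g


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

# oblique chord angle (deg) used alongside the perpendicular chord
_CHORD_OBLIQUE = 20.0


def _chord_width(grid: np.ndarray, point: np.ndarray, normal: np.ndarray,
                 reach: float, step: float = 0.25) -> float | None:
    """Vessel width at one centerline point: length of the foreground
    chord along ``normal``, with the two boundary positions located at
    the 0.5-level crossings of the bilinearly interpolated mask
    (sub-pixel boundary)."""
    ts = np.arange(-reach, reach + step, step)
    sam = point[None, :] + ts[:, None] * normal[None, :]
    prof = ndimage.map_coordinates(grid, [sam[:, 0], sam[:, 1]], order=1, mode="constant")
    zi = int(np.argmin(np.abs(ts)))
    if prof[zi] < 0.5:
        return None
    a = zi
    while a > 0 and prof[a - 1] >= 0.5:
        a -= 1
    b = zi
    while b < len(prof) - 1 and prof[b + 1] >= 0.5:
        b += 1
    ta = ts[a]
    if a > 0 and prof[a - 1] < prof[a]:
        ta -= step * (prof[a] - 0.5) / (prof[a] - prof[a - 1])
    tb = ts[b]
    if b < len(prof) - 1 and prof[b + 1] < prof[b]:
        tb += step * (prof[b] - 0.5) / (prof[b] - prof[b + 1])
    return float(tb - ta)


def estimate_diameters(
    mask: RasterMask, graph: SkeletonGraph, *, end_exclusion_radii: float = 2.0
) -> SkeletonGraph:
    """Attach a mean vessel diameter to every edge.

    At each retained centerline point the caliber is measured from
    foreground chords through the point: one perpendicular to the local
    path tangent and two at ±20° around it (each projected back onto the
    perpendicular), with the stroke boundary located to sub-pixel
    precision on the interpolated mask. The oblique chords sample
    different raster phases, which cancels the coherent quantization
    bias a single perpendicular chord suffers on straight strokes; the
    edge diameter is the mean over points and chord angles. The Euclidean distance
    transform of the mask supplies the local radius scale: points within
    ``end_exclusion_radii`` local radii of either end node are excluded,
    because at a junction the parent and daughter strokes overlap into a
    single bulge that stays wider than the vessel until the strokes
    separate — well past one radius for typical branch angles. Edges too
    short to retain any point fall back to the distance-transform mean
    over all points and are flagged.
    """
    grid_f = mask.grid.astype(float)
    dt = ndimage.distance_transform_edt(mask.grid)
    H, W = mask.grid.shape

    def dt_at(pos) -> float:
        r = min(max(float(pos[0]), 0.0), H - 1.0)
        c = min(max(float(pos[1]), 0.0), W - 1.0)
        return float(ndimage.map_coordinates(dt, [[r], [c]], order=1)[0])

    for e in graph.edges.values():
        pts = e.path
        seglen = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.array([0.0])
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        r_a = dt_at(pts[0])
        r_b = dt_at(pts[-1])
        keep = np.flatnonzero(
            (s >= end_exclusion_radii * r_a) & (s <= s[-1] - end_exclusion_radii * r_b)
        )
        vals = []
        for i in keep:
            i0, i1 = max(i - 2, 0), min(i + 2, len(pts) - 1)
            tang = pts[i1] - pts[i0]
            norm = np.linalg.norm(tang)
            if norm == 0:
                continue
            tang = tang / norm
            perp = np.array([-tang[1], tang[0]])
            reach = dt_at(pts[i]) + 2.0
            for theta in (0.0, -_CHORD_OBLIQUE, _CHORD_OBLIQUE):
                t = math.radians(theta)
                direction = math.cos(t) * perp + math.sin(t) * tang
                w = _chord_width(grid_f, pts[i], direction, reach=reach / math.cos(t))
                if w is not None:
                    vals.append(w * math.cos(t))
        if vals:
            # a centerline pixel implies at least one pixel of vessel
            e.mean_diameter = max(float(np.mean(vals)), 1.0)
        else:
            e.mean_diameter = float(np.mean([2.0 * dt_at(p) for p in pts]))
            if "short_edge_diameter" not in e.flags:
                e.flags.append("short_edge_diameter")
        if e.mean_diameter <= 0:
            e.mean_diameter = 1.0  # degenerate: off-mask path point
            e.flags.append("zero_diameter_fallback")
    return graph


# ---------------------------------------------------------------------------
# spur pruning
# ---------------------------------------------------------------------------

def _merge_degree2_nodes(g: SkeletonGraph) -> bool:
    """Merge the two edges of any degree-2 non-root node; True if changed."""
    changed = False
    for nid in list(g.nodes):
        if nid not in g.nodes:
            continue
        inc = g.incident(nid)
        if len(inc) != 2 or inc[0].id == inc[1].id:
            continue
        if any(e.nodes[0] == e.nodes[1] for e in inc):  # self-loop: degree 3+
            continue
        if g.nodes[nid].landmark == "root":
            continue
        e1, e2 = inc
        # orient both paths to run through nid
        p1 = e1.path if e1.nodes[1] == nid else e1.path[::-1]
        u = e1.nodes[0] if e1.nodes[1] == nid else e1.nodes[1]
        p2 = e2.path if e2.nodes[0] == nid else e2.path[::-1]
        v = e2.nodes[1] if e2.nodes[0] == nid else e2.nodes[0]
        path = np.vstack([p1, p2[1:]])
        l1, l2 = e1.length, e2.length
        if l1 + l2 > 0 and np.isfinite(e1.mean_diameter) and np.isfinite(e2.mean_diameter):
            diam = (e1.mean_diameter * l1 + e2.mean_diameter * l2) / (l1 + l2)
        else:
            diam = e1.mean_diameter
        flags = sorted(set(e1.flags) | set(e2.flags))
        g.remove_edge(e1.id)
        g.remove_edge(e2.id)
        g.remove_node(nid)
        g.add_edge(u, v, path, mean_diameter=diam, flags=flags)
        changed = True
    return changed


def prune_spurs(
    graph: SkeletonGraph,
    min_length: float | None = None,
    *,
    length_floor: float = 5.0,
    diameter_factor: float = 1.5,
) -> SkeletonGraph:
    """Remove short terminal spurs and simplify the graph to a fixpoint.

    A terminal edge (leaf at one end, junction at the other) is removed
    when shorter than its threshold: ``min_length`` if given, otherwise
    ``max(length_floor, diameter_factor × parent diameter)`` where the
    parent diameter is the largest sibling-edge diameter at the junction.
    Surviving degree-2 nodes are merged (paths concatenated, diameters
    length-weighted). Isolated segments (leaf at both ends) are kept.
    """
    g = graph.copy()

    def local_thr(nid, exclude_id):
        if min_length is not None:
            return min_length
        sib = [
            s.mean_diameter for s in g.incident(nid)
            if s.id != exclude_id and np.isfinite(s.mean_diameter)
        ]
        return max(length_floor, diameter_factor * (max(sib) if sib else 0.0))

    while True:
        changed = False
        # thinning artifacts at junction bulges: tiny self-loops and short
        # parallel duplicate edges punch holes into what is anatomically a
        # single junction — drop them before spur logic sees the degrees
        for e in list(g.edges.values()):
            u, v = e.nodes
            if u == v and e.length < local_thr(u, e.id):
                g.remove_edge(e.id)
                changed = True
        seen_pairs: dict[tuple[int, int], Edge] = {}
        for e in sorted(g.edges.values(), key=lambda e: e.length):
            u, v = e.nodes
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            other = seen_pairs.get(key)
            if other is not None and other.id in g.edges:
                if e.length < local_thr(u, e.id) and other.length < local_thr(u, other.id):
                    g.remove_edge(e.id)  # keep the shorter of the duplicate pair
                    changed = True
                    continue
            seen_pairs[key] = e
        deg = {nid: g.degree(nid) for nid in g.nodes}
        for e in list(g.edges.values()):
            if e.id not in g.edges:
                continue
            u, v = e.nodes
            if u == v:
                continue
            du, dv = deg.get(u, 0), deg.get(v, 0)
            if not ((du == 1 and dv >= 3) or (dv == 1 and du >= 3)):
                continue
            junction = v if du == 1 else u
            leaf = u if du == 1 else v
            if min_length is not None:
                thr = min_length
            else:
                sib = [
                    s.mean_diameter
                    for s in g.incident(junction)
                    if s.id != e.id and np.isfinite(s.mean_diameter)
                ]
                parent_d = max(sib) if sib else 0.0
                thr = max(length_floor, diameter_factor * parent_d)
            if e.length < thr:
                g.remove_edge(e.id)
                g.remove_node(leaf)
                deg[junction] -= 1
                changed = True
        changed |= _merge_degree2_nodes(g)
        if not changed:
            break
    # re-label landmarks from surviving degrees
    for nid, n in g.nodes.items():
        if n.landmark == "root":
            continue
        d = g.degree(nid)
        n.landmark = "endpoint" if d <= 1 else "junction"
    return g


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_components(
    graph: SkeletonGraph, disc: DiscGeometry, *, max_root_distance_dd: float = 3.0
) -> SkeletonGraph:
    """Root every connected component at its node nearest the optic disc.

    Edges are re-oriented to point away from the root (BFS). Components
    whose nearest node lies farther than ``max_root_distance_dd`` disc
    diameters from the disc center are dropped as unrooted debris.
    """
    g = graph.copy()
    center = np.asarray(disc.center, float)
    kept_roots: list[int] = []
    for comp in g.components():
        dists = {nid: float(np.hypot(*(g.nodes[nid].position - center))) for nid in comp}
        root = min(dists, key=dists.get)
        if dists[root] > max_root_distance_dd * disc.diameter:
            for nid in comp:
                for e in g.incident(nid):
                    if e.id in g.edges:
                        g.remove_edge(e.id)
                g.remove_node(nid)
            continue
        g.nodes[root].landmark = "root"
        kept_roots.append(root)
        _orient_from(g, root, comp)
    if not kept_roots:
        raise ValueError("no rooted vasculature: every component is farther than "
                         f"{max_root_distance_dd} disc diameters from the disc")
    g.directed = True
    g.roots = kept_roots
    return g


def _orient_from(g: SkeletonGraph, root: int, comp: set[int]) -> None:
    """Flip edge directions so each edge in `comp` points away from root."""
    seen_nodes = {root}
    seen_edges: set[int] = set()
    queue = [root]
    while queue:
        nid = queue.pop(0)
        for e in g.incident(nid):
            if e.id in seen_edges:
                continue
            seen_edges.add(e.id)
            if e.nodes[1] == nid and e.nodes[0] != nid:
                e.nodes = (e.nodes[1], e.nodes[0])
                e.path = e.path[::-1]
            other = e.nodes[1]
            if other not in seen_nodes:
                seen_nodes.add(other)
                queue.append(other)


# ---------------------------------------------------------------------------
# pipeline convenience + export
# ---------------------------------------------------------------------------

def extract_graph(mask: RasterMask, disc: DiscGeometry, config=None) -> SkeletonGraph:
    """Full mask → ordered, crossing-resolved, Strahler-labelled graph."""
    from .config import RunConfig
    from .ordering import assign_strahler, resolve_crossings

    cfg = config or RunConfig()
    skel = skeletonize(mask)
    g = build_graph(skel, mask.vessel_class)
    if not g.nodes:
        return g
    g = estimate_diameters(mask, g)
    g = prune_spurs(
        g,
        cfg.spur_min_length,
        length_floor=cfg.spur_length_floor,
        diameter_factor=cfg.spur_diameter_factor,
    )
    g = root_components(g, disc, max_root_distance_dd=cfg.max_root_distance_dd)
    g = resolve_crossings(g)
    g = assign_strahler(g)
    return g


def graph_to_json(g: SkeletonGraph) -> dict:
    return {
        "vessel_class": g.vessel_class,
        "shape": list(g.shape),
        "directed": g.directed,
        "roots": g.roots,
        "nodes": [
            {
                "id": n.id,
                "position": [float(x) for x in n.position],
                "landmark": n.landmark,
                "degree": g.degree(n.id),
                "flags": n.flags,
            }
            for n in g.nodes.values()
        ],
        "edges": [
            {
                "id": e.id,
                "nodes": list(e.nodes),
                "length": e.length,
                "mean_diameter": None if math.isnan(e.mean_diameter) else e.mean_diameter,
                "strahler_order": e.strahler_order,
                "path": [[float(r), float(c)] for r, c in e.path],
                "flags": e.flags,
            }
            for e in g.edges.values()
        ],
    }
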