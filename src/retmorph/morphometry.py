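"""Per-image vascular morphometry: MA, BA, BC, BEA, BEC.

Five metrics are computed per image and vessel class on the ordered
skeleton graph:

* **MA** (main angle) — the angle at the optic-disc center between rays
  to the distal anchor of the highest-Strahler-order chain of the
  superior and the inferior major arcade.
* **BA / BEA** (branching / bifurcation edge angle) — the angle between
  the two daughter vessels at a junction, at junctions whose daughters
  have differing / equal Strahler orders respectively.
* **BC / BEC** (branching / bifurcation edge coefficient) — the
  dimensionless daughter-to-parent caliber relation (d1² + d2²) / d0² at
  the same two junction classes. BC/BEC share one implementation and
  differ only in which junctions they average over.

Branch metrics are restricted to an annulus 0.5–2.0 disc diameters
outward from the disc edge; MA is not annulus-restricted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .graph import DiscGeometry, SkeletonGraph
from .ordering import JunctionClass, classify_junction, edge_tangent

__all__ = [
    "MorphometryRecord",
    "JunctionMeasurement",
    "in_annulus",
    "branch_angle",
    "branch_coefficient",
    "main_angle",
    "measure_junctions",
    "measure_image",
]

METRICS = ("MA", "BA", "BC", "BEA", "BEC")


@dataclass
class MorphometryRecord:
    """One image × one vessel class worth of morphometry.

    Metrics with zero qualifying junctions are NaN (undefined), never 0.
    """

    image_id: str
    vessel_class: str
    MA: float = math.nan
    BA_mean: float = math.nan
    BC_mean: float = math.nan
    BEA_mean: float = math.nan
    BEC_mean: float = math.nan
    n_branching: int = 0
    n_bifurcation: int = 0
    flags: list = field(default_factory=list)

    def as_row(self, group: str = "") -> dict:
        return {
            "image_id": self.image_id,
            "group": group,
            "vessel_class": self.vessel_class,
            "MA": self.MA,
            "BA": self.BA_mean,
            "BC": self.BC_mean,
            "BEA": self.BEA_mean,
            "BEC": self.BEC_mean,
            "n_branching": self.n_branching,
            "n_bifurcation": self.n_bifurcation,
            "flags": ";".join(self.flags),
        }


@dataclass
class JunctionMeasurement:
    node_id: int
    position: tuple[float, float]
    junction_class: str
    daughter_orders: tuple
    angle: float
    coefficient: float
    in_annulus: bool
    flags: list = field(default_factory=list)


def in_annulus(point, disc: DiscGeometry, inner_dd: float = 0.5, outer_dd: float = 2.0) -> bool:
    """True iff the point's distance from the disc EDGE is within
    ``[inner_dd, outer_dd]`` disc diameters, boundaries inclusive."""
    r = math.hypot(point[0] - disc.center[0], point[1] - disc.center[1])
    edge_dist = r - disc.diameter / 2.0
    return inner_dd * disc.diameter <= edge_dist <= outer_dd * disc.diameter


def branch_angle(
    graph: SkeletonGraph,
    node_id: int,
    daughters,
    parent_diameter: float,
    *,
    fit_factor: float = 3.0,
    skip_factor: float = 0.75,
) -> float:
    """Angle in degrees between two daughter vessels at a junction.

    Each daughter's initial direction is a least-squares line fit over
    the first ``fit_factor × parent_diameter`` px of its centerline path,
    after skipping ``skip_factor × parent_diameter`` px nearest the
    junction (the skeleton bends through the junction bulge there).
    Returned in (0°, 180°].
    """
    if len(daughters) != 2:
        raise ValueError("branch_angle needs exactly 2 daughter edges")
    for d in daughters:
        if len(d.path) < 3:
            raise ValueError("daughter path too short to estimate a direction")
    pd = parent_diameter if np.isfinite(parent_diameter) and parent_diameter > 0 else 5.0
    t = [
        edge_tangent(d, node_id, fit_length=fit_factor * pd, skip=skip_factor * pd)
        for d in daughters
    ]
    c = float(np.clip(np.dot(t[0], t[1]), -1.0, 1.0))
    ang = math.degrees(math.acos(c))
    return 180.0 if ang == 0.0 else ang  # degenerate identical directions


def branch_coefficient(d_parent: float, d1: float, d2: float) -> float:
    """(d1² + d2²) / d_parent² — dimensionless caliber relation."""
    if d_parent <= 0 or d1 <= 0 or d2 <= 0:
        raise ValueError("diameters must be positive")
    return (d1 * d1 + d2 * d2) / (d_parent * d_parent)


# ---------------------------------------------------------------------------
# junction iteration
# ---------------------------------------------------------------------------

def measure_junctions(
    graph: SkeletonGraph, disc: DiscGeometry, config: RunConfig | None = None
) -> list[JunctionMeasurement]:
    """Measure angle, coefficient and class at every junction of a rooted,
    ordered graph. Junctions without a parent edge (roots) or flagged
    pathological are skipped."""
    cfg = config or RunConfig()
    out: list[JunctionMeasurement] = []
    if not graph.directed:
        raise ValueError("graph must be rooted and ordered")
    for nid, node in graph.nodes.items():
        if "pathological_degree" in node.flags:
            continue
        daughters = graph.out_edges(nid)
        if len(daughters) < 2:
            continue
        parents = graph.in_edges(nid)
        flags = []
        if not parents:
            continue  # root fan-out: no parent caliber to relate to
        parent = max(parents, key=lambda e: e.length)
        if len(daughters) > 2:
            flags.append("multifurcation_top2")
            daughters = sorted(
                daughters, key=lambda e: (e.mean_diameter if np.isfinite(e.mean_diameter) else 0),
                reverse=True,
            )[:2]
        orders = tuple(e.strahler_order for e in daughters)
        if any(o is None for o in orders):
            continue
        jclass = classify_junction(orders)
        try:
            ang = branch_angle(
                graph, nid, daughters, parent.mean_diameter,
                fit_factor=cfg.daughter_fit_factor, skip_factor=cfg.daughter_skip_factor,
            )
        except ValueError:
            continue  # daughter path too short: junction skipped
        d1, d2 = (e.mean_diameter for e in daughters)
        try:
            coef = branch_coefficient(parent.mean_diameter, d1, d2)
        except ValueError:
            continue
        out.append(
            JunctionMeasurement(
                node_id=nid,
                position=tuple(node.position),
                junction_class=jclass,
                daughter_orders=orders,
                angle=ang,
                coefficient=coef,
                in_annulus=in_annulus(node.position, disc, cfg.annulus_inner_dd, cfg.annulus_outer_dd),
                flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# main angle
# ---------------------------------------------------------------------------

def _arcade_anchor(graph: SkeletonGraph, root: int) -> np.ndarray | None:
    """Distal endpoint of the maximal-Strahler-order chain from ``root``."""
    edges = graph.out_edges(root)
    edges = [e for e in edges if e.strahler_order is not None]
    if not edges:
        return None
    m = max(e.strahler_order for e in edges)
    cur = max(
        (e for e in edges if e.strahler_order == m),
        key=lambda e: e.mean_diameter if np.isfinite(e.mean_diameter) else 0,
    )
    while True:
        nxt = [e for e in graph.out_edges(cur.nodes[1]) if e.strahler_order == m]
        if not nxt:
            return graph.nodes[cur.nodes[1]].position
        cur = max(nxt, key=lambda e: e.mean_diameter if np.isfinite(e.mean_diameter) else 0)


def _root_caliber(graph: SkeletonGraph, root: int) -> float:
    diams = [
        e.mean_diameter for e in graph.out_edges(root) if np.isfinite(e.mean_diameter)
    ]
    return max(diams) if diams else 0.0


def main_angle(
    graph: SkeletonGraph, disc: DiscGeometry, config: RunConfig | None = None
) -> tuple[float, list[str]]:
    """Main angle (degrees) of one vessel class, with flags.

    Among trees rooted at the disc, the largest-caliber tree above the
    disc-center row and the largest below are selected; on each, the
    maximal-order edge chain is followed from the root and the distal end
    of its last maximal-order edge is the anchor. MA is the angle at the
    disc center between the two center→anchor rays, in (0°, 180°].
    Returns (NaN, flags) when either hemifield has no disc-rooted tree.
    """
    cfg = config or RunConfig()
    center = np.asarray(
        cfg.ma_vertex_point if cfg.ma_vertex == "custom" and cfg.ma_vertex_point else disc.center,
        float,
    )
    sup, inf = [], []  # (caliber, root)
    for root in graph.roots:
        if root not in graph.nodes:
            continue
        pos = graph.nodes[root].position
        if np.hypot(*(pos - np.asarray(disc.center))) > cfg.ma_root_distance_dd * disc.diameter:
            continue
        cal = _root_caliber(graph, root)
        (sup if pos[0] < disc.center[0] else inf).append((cal, root))
    if not sup or not inf:
        return math.nan, ["main_angle_undefined"]
    anchors = []
    for side in (sup, inf):
        _, root = max(side)
        a = _arcade_anchor(graph, root)
        if a is None:
            return math.nan, ["main_angle_undefined"]
        anchors.append(a)
    v1, v2 = (np.asarray(a) - center for a in anchors)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return math.nan, ["main_angle_undefined"]
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    ang = math.degrees(math.acos(c))
    return (180.0 if ang == 0.0 else ang), []


# ---------------------------------------------------------------------------
# per-image measurement
# ---------------------------------------------------------------------------

def _measure_class(
    graph: SkeletonGraph, disc: DiscGeometry, image_id: str, cfg: RunConfig
) -> MorphometryRecord:
    rec = MorphometryRecord(image_id=image_id, vessel_class=graph.vessel_class)
    if not graph.nodes:
        rec.flags.append("no_vasculature")
        return rec
    juncs = measure_junctions(graph, disc, cfg)
    use = [j for j in juncs if j.in_annulus] if cfg.annulus_all_branch_metrics else juncs
    branching = [j for j in use if j.junction_class == JunctionClass.BRANCHING]
    bifurcation = [j for j in use if j.junction_class == JunctionClass.BIFURCATION]
    rec.n_branching = len(branching)
    rec.n_bifurcation = len(bifurcation)
    if branching:
        rec.BA_mean = float(np.mean([j.angle for j in branching]))
        rec.BC_mean = float(np.mean([j.coefficient for j in branching]))
    else:
        rec.flags.append("no_branching_in_annulus")
    if bifurcation:
        rec.BEA_mean = float(np.mean([j.angle for j in bifurcation]))
        rec.BEC_mean = float(np.mean([j.coefficient for j in bifurcation]))
    else:
        rec.flags.append("no_bifurcation_in_annulus")
    ma, flags = main_angle(graph, disc, cfg)
    rec.MA = ma
    rec.flags.extend(flags)
    return rec


def measure_image(
    artery_graph: SkeletonGraph,
    vein_graph: SkeletonGraph,
    disc: DiscGeometry,
    image_id: str,
    config: RunConfig | None = None,
) -> tuple[MorphometryRecord, MorphometryRecord]:
    """Measure both vessel classes of one image; graphs must already be
    rooted, crossing-resolved and Strahler-ordered."""
    cfg = config or RunConfig()
    return (
        _measure_class(artery_graph, disc, image_id, cfg),
        _measure_class(vein_graph, disc, image_id, cfg),
    )
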