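"""Synthetic vasculature: parametric trees with exact ground truth.

Fundus photographs and their segmentations are clinical data and cannot
ship with the package, so every downstream stage is exercised on
generated inputs instead:

* parametric vascular trees rooted on the optic-disc edge, grown
  radially outward with known branch angles, daughter/parent diameter
  ratios and Strahler structure, rasterized into binary masks by
  stadium-stamping each segment at its planned caliber;
* cohorts of per-image metric values drawn from per-group normal
  distributions, parameterized by published group summaries (means with
  95% CIs per refractive group) from a pediatric myopia fundus cohort.

The tree generator is a test fixture, not a model of real retinas: real
vessels curve, taper continuously, and cross between classes. What it
guarantees is an analytically known answer for every quantity the
pipeline measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import DiscGeometry, RasterMask
from .morphometry import METRICS, in_annulus

__all__ = [
    "Segment",
    "PlannedJunction",
    "TreeSpec",
    "GroundTruthTable",
    "GroupSpec",
    "CohortSpec",
    "generate_tree_spec",
    "generate_arcade_pair",
    "ground_truth_morphometry",
    "ground_truth_main_angle",
    "render_tree",
    "render_trees",
    "simulate_cohort",
    "reference_cohort_spec",
    "ci_derived_sd",
    "REFERENCE_GROUP_SIZES",
    "REFERENCE_TABLE",
    "GROUP_LABELS",
]

GROUP_LABELS = ("normal", "low", "moderate", "high")

# Published per-group image counts of the reference pediatric cohort.
REFERENCE_GROUP_SIZES = {"normal": 279, "low": 1193, "moderate": 510, "high": 384}

# Published group summaries: (vessel_class, metric) -> {group: (mean, ci_lo, ci_hi)}.
# Means with 95% confidence intervals OF THE MEAN, per refractive group
# (normal, low / moderate / high myopia). Angles in degrees, coefficients
# dimensionless.
REFERENCE_TABLE: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {
    ("artery", "MA"): {
        "normal": (87.55, 84.02, 91.08), "low": (82.12, 80.46, 83.78),
        "moderate": (82.44, 79.01, 83.86), "high": (82.43, 79.83, 85.03),
    },
    ("artery", "BA"): {
        "normal": (36.28, 34.12, 38.44), "low": (34.86, 33.90, 35.83),
        "moderate": (35.88, 34.35, 37.40), "high": (33.34, 31.59, 35.09),
    },
    ("artery", "BC"): {
        "normal": (1.67, 1.37, 1.96), "low": (1.31, 1.28, 1.34),
        "moderate": (1.55, 1.16, 1.94), "high": (1.41, 1.33, 1.50),
    },
    ("artery", "BEA"): {
        "normal": (34.97, 33.34, 36.60), "low": (34.91, 34.21, 35.61),
        "moderate": (34.68, 33.66, 35.71), "high": (33.73, 32.43, 35.02),
    },
    ("artery", "BEC"): {
        "normal": (0.92, 0.79, 1.04), "low": (0.72, 0.70, 0.74),
        "moderate": (0.70, 0.68, 0.73), "high": (0.78, 0.72, 0.84),
    },
    ("vein", "MA"): {
        "normal": (84.94, 81.50, 88.37), "low": (79.05, 77.45, 80.65),
        "moderate": (78.07, 75.70, 80.43), "high": (74.31, 71.75, 76.87),
    },
    ("vein", "BA"): {
        "normal": (36.19, 34.18, 38.20), "low": (36.44, 35.50, 37.38),
        "moderate": (35.24, 33.84, 36.65), "high": (37.71, 36.04, 39.39),
    },
    ("vein", "BC"): {
        "normal": (1.36, 1.20, 1.52), "low": (2.35, 0.50, 4.20),
        "moderate": (1.34, 1.04, 1.65), "high": (1.31, 1.23, 1.39),
    },
    ("vein", "BEA"): {
        "normal": (34.08, 32.74, 35.42), "low": (35.22, 34.64, 35.81),
        "moderate": (34.65, 33.82, 35.48), "high": (34.05, 32.90, 35.20),
    },
    ("vein", "BEC"): {
        "normal": (0.94, 0.67, 1.21), "low": (0.60, 0.58, 0.62),
        "moderate": (0.58, 0.55, 0.61), "high": (0.65, 0.57, 0.73),
    },
}


def ci_derived_sd(ci_lo: float, ci_hi: float, n: int) -> float:
    """Back out a sample SD from a 95% CI of the mean: (half-width/1.96)·√n.

    The reference cohort publishes CIs of group means, not SDs; this
    inversion (normal approximation) is how the simulator parameterizes
    per-group spread. It is an approximation, not a published value.
    """
    return (ci_hi - ci_lo) / 2.0 / 1.96 * math.sqrt(n)


# ---------------------------------------------------------------------------
# tree specification
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    id: int
    parent: int | None
    start: tuple[float, float]
    direction: tuple[float, float]  # unit (row, col)
    length: float
    diameter: float

    @property
    def end(self) -> np.ndarray:
        return np.asarray(self.start) + np.asarray(self.direction) * self.length


@dataclass
class PlannedJunction:
    node: tuple[float, float]
    parent_segment: int
    daughters: tuple[int, int]
    planned_angle: float  # degrees, in (0, 180)
    planned_ratios: tuple[float, float]  # d1/d0 >= d2/d0


@dataclass
class TreeSpec:
    vessel_class: str
    root_point: tuple[float, float]
    root_direction: tuple[float, float]
    segments: list[Segment]
    junctions: list[PlannedJunction]
    disc: DiscGeometry

    def validate(self) -> None:
        by_id = {s.id: s for s in self.segments}
        for s in self.segments:
            if s.diameter <= 0:
                raise ValueError(f"segment {s.id}: nonpositive diameter")
            if s.parent is not None and s.diameter > by_id[s.parent].diameter + 1e-9:
                raise ValueError(f"segment {s.id}: wider than its parent")
        for j in self.junctions:
            if not 0.0 < j.planned_angle < 180.0:
                raise ValueError("planned angle must lie in (0, 180)")
            for d in j.daughters:
                if not np.allclose(by_id[d].start, j.node):
                    raise ValueError("daughter does not emanate from its junction")
        # acyclic, rooted: walk up parents
        for s in self.segments:
            seen, cur = set(), s
            while cur.parent is not None:
                if cur.id in seen:
                    raise ValueError("cycle in tree spec")
                seen.add(cur.id)
                cur = by_id[cur.parent]

    def to_json(self) -> dict:
        return {
            "vessel_class": self.vessel_class,
            "root_point": list(self.root_point),
            "root_direction": list(self.root_direction),
            "disc": {"center": list(self.disc.center), "diameter": self.disc.diameter},
            "segments": [
                {
                    "id": s.id, "parent": s.parent, "start": list(s.start),
                    "direction": list(s.direction), "length": s.length,
                    "diameter": s.diameter,
                }
                for s in self.segments
            ],
            "junctions": [
                {
                    "node": list(j.node), "parent_segment": j.parent_segment,
                    "daughters": list(j.daughters), "planned_angle": j.planned_angle,
                    "planned_ratios": list(j.planned_ratios),
                }
                for j in self.junctions
            ],
        }

    @classmethod
    def from_json(cls, d: dict) -> "TreeSpec":
        return cls(
            vessel_class=d["vessel_class"],
            root_point=tuple(d["root_point"]),
            root_direction=tuple(d["root_direction"]),
            segments=[
                Segment(s["id"], s["parent"], tuple(s["start"]), tuple(s["direction"]),
                        s["length"], s["diameter"])
                for s in d["segments"]
            ],
            junctions=[
                PlannedJunction(tuple(j["node"]), j["parent_segment"], tuple(j["daughters"]),
                                j["planned_angle"], tuple(j["planned_ratios"]))
                for j in d["junctions"]
            ],
            disc=DiscGeometry(tuple(d["disc"]["center"]), d["disc"]["diameter"]),
        )


@dataclass
class GroundTruthTable:
    """Analytic morphometry of a :class:`TreeSpec`.

    ``junctions`` has one row per planned junction (id, class, angle,
    coefficient, in_annulus, daughter orders); ``ma_anchor`` is the
    distal endpoint of the maximal-Strahler chain (None for a single
    segment, in which case MA is undefined and flagged).
    """

    junctions: pd.DataFrame
    ma_anchor: tuple[float, float] | None
    flags: list = field(default_factory=list)


# -- distribution-law plumbing ----------------------------------------------

def _law(spec, rng, *, lo=None, hi=None):
    """Draw from a law spec: ('constant', v), ('uniform', a, b) or callable."""
    if callable(spec):
        v = spec(rng)
    else:
        kind = spec[0]
        if kind == "constant":
            v = spec[1]
        elif kind == "uniform":
            a, b = spec[1], spec[2]
            if b < a:
                raise ValueError(f"invalid uniform bounds ({a}, {b})")
            v = rng.uniform(a, b)
        else:
            raise ValueError(f"unknown distribution law {spec!r}")
    if lo is not None and np.any(np.asarray(v) < lo):
        raise ValueError(f"law draw {v} below bound {lo}")
    if hi is not None and np.any(np.asarray(v) > hi):
        raise ValueError(f"law draw {v} above bound {hi}")
    return v


def _unit(theta_deg: float) -> np.ndarray:
    """Unit (row, col) vector: 0° → +col (temporal), 90° → +row (inferior)."""
    t = math.radians(theta_deg)
    return np.array([math.sin(t), math.cos(t)])


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([c * v[0] + s * v[1], -s * v[0] + c * v[1]])


def _seg_seg_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 2-D segments p1q1 and p2q2."""
    def pt_seg(p, a, b):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0)
        return float(np.linalg.norm(p - (a + t * ab)))

    # cheap and robust for short segments: endpoint-to-segment distances
    # plus an intersection test
    d = min(pt_seg(p1, p2, q2), pt_seg(q1, p2, q2), pt_seg(p2, p1, q1), pt_seg(q2, p1, q1))

    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    if (ccw(p1, q1, p2) * ccw(p1, q1, q2) < 0) and (ccw(p2, q2, p1) * ccw(p2, q2, q1) < 0):
        return 0.0
    return d


def _lattice_margin(d) -> float:
    """Angular distance (deg) of a direction from the nearest raster
    lattice axis (0°, 45°, 90°, 135°)."""
    ang = math.degrees(math.atan2(d[0], d[1])) % 45.0
    return min(ang, 45.0 - ang)


def _delattice(dirs: list[np.ndarray], margin: float = 2.0) -> list[np.ndarray]:
    """Rigidly rotate a direction bundle until every member clears the
    raster lattice axes by ``margin`` degrees.

    A straight stroke aligned with a lattice axis keeps the same sub-pixel
    phase along its whole length, so its rasterized width is off by up to
    one full pixel everywhere and no measurement can recover the planned
    caliber. Real vessels curve and never hold lattice alignment; nudging
    the planned directions (angles between members are preserved) keeps
    the fixture's ground truth recoverable.
    """
    for delta in (0.0, *(s * k for k in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0) for s in (1, -1))):
        cand = [_rot(d, delta) for d in dirs]
        if all(_lattice_margin(c) >= margin for c in cand):
            return cand
    return dirs  # no clean rotation found; accept as drawn


def _tree_is_clear(segments: list[Segment], clearance: float = 3.0) -> bool:
    """True when no two non-adjacent segment strokes touch."""
    by_id = {s.id: s for s in segments}
    for i, a in enumerate(segments):
        for b in segments[i + 1:]:
            if b.parent == a.id or a.parent == b.id:
                continue
            if a.parent is not None and a.parent == b.parent:
                # siblings share the junction point: require divergence only
                continue
            d = _seg_seg_distance(np.asarray(a.start), a.end, np.asarray(b.start), b.end)
            if d < a.diameter / 2 + b.diameter / 2 + clearance:
                return False
    # sibling strokes must separate before their ends
    for a in segments:
        for b in segments:
            if b.id <= a.id or a.parent is None or a.parent != b.parent:
                continue
            if float(np.linalg.norm(a.end - b.end)) < a.diameter / 2 + b.diameter / 2 + clearance:
                return False
    _ = by_id
    return True


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_tree_spec(
    depth: int,
    angle_law=("uniform", 50.0, 95.0),
    diameter_ratio_law=None,
    disc: DiscGeometry | None = None,
    vessel_class: str = "artery",
    seed: int = 0,
    *,
    root_azimuth_deg: float | None = None,
    root_diameter: float = 12.0,
    base_length: float = 70.0,
    length_decay: float = 0.82,
    radial_weight: float = 0.5,
    clearance: float = 3.0,
    asymmetry: float = 0.5,
    max_attempts: int = 60,
) -> TreeSpec:
    """Grow a rooted binary tree from the optic-disc edge, radially outward.

    ``angle_law`` draws the planned angle between the two daughters at
    each junction (constrained to (10°, 170°)); ``diameter_ratio_law``
    draws the (d1/d0, d2/d0) pair with d1 ≥ d2 and ratios in (0, 1].
    The same seed always yields an identical spec. Trees whose strokes
    would touch (non-adjacent segments closer than the sum of radii plus
    ``clearance``) are rejected and regrown deterministically.

    ``asymmetry`` is the probability that the smaller daughter of a
    junction gets a shallower subtree than its sibling; without it the
    tree is a full binary tree whose junctions are all bifurcations
    (equal daughter Strahler orders), so no branching junctions would
    ever be generated.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if diameter_ratio_law is None:
        diameter_ratio_law = ("uniform", 0.70, 0.88)
    disc = disc or DiscGeometry((256.0, 256.0), 110.0)
    rng = np.random.default_rng(seed)
    center = np.asarray(disc.center)

    for _attempt in range(max_attempts):
        az = root_azimuth_deg if root_azimuth_deg is not None else rng.uniform(0.0, 360.0)
        root_dir = _delattice([_unit(az)])[0]
        root_pt = center + disc.radius * root_dir
        segments: list[Segment] = []
        junctions: list[PlannedJunction] = []
        next_id = [0]

        def grow(parent_id, start, direction, level, diameter, budget):
            sid = next_id[0]
            next_id[0] += 1
            length = base_length * (length_decay ** level) * rng.uniform(0.9, 1.1)
            seg = Segment(sid, parent_id, tuple(start), tuple(direction), float(length),
                          float(diameter))
            segments.append(seg)
            if budget <= 1:
                return
            end = seg.end
            alpha = float(_law(angle_law, rng, lo=10.0, hi=170.0))
            if callable(diameter_ratio_law) or diameter_ratio_law[0] != "uniform":
                r = _law(diameter_ratio_law, rng)
                r1, r2 = (max(r), min(r)) if np.ndim(r) else (float(r), float(r))
            else:
                r1, r2 = sorted(
                    (float(_law(diameter_ratio_law, rng, lo=1e-9, hi=1.0)),
                     float(_law(diameter_ratio_law, rng, lo=1e-9, hi=1.0))),
                    reverse=True,
                )
            if not (0 < r2 <= r1 <= 1.0):
                raise ValueError(f"diameter ratios ({r1}, {r2}) outside (0, 1]")
            radial = end - center
            radial = radial / max(np.linalg.norm(radial), 1e-9)
            bias = (1 - radial_weight) * np.asarray(direction) + radial_weight * radial
            bias = bias / max(np.linalg.norm(bias), 1e-9)
            f = rng.uniform(0.30, 0.48)  # larger daughter deviates less
            s = rng.choice([-1.0, 1.0])
            d1_dir, d2_dir = _delattice([_rot(bias, s * alpha * f),
                                         _rot(bias, -s * alpha * (1 - f))])
            junctions.append(
                PlannedJunction(tuple(end), sid, (next_id[0], next_id[0] + 1), alpha, (r1, r2))
            )
            b2 = budget - 1
            if b2 >= 2 and rng.uniform() < asymmetry:
                b2 = int(rng.integers(1, b2))  # smaller daughter loses depth
            grow(sid, end, d1_dir, level + 1, diameter * r1, budget - 1)
            grow(sid, end, d2_dir, level + 1, diameter * r2, b2)

        grow(None, root_pt, root_dir, 0, root_diameter, depth)
        # fix daughter ids: grow() interleaves subtrees, so the planned ids
        # recorded before recursion are only right for the first daughter
        for j in junctions:
            kids = tuple(s.id for s in segments if s.parent == j.parent_segment)
            j.daughters = kids
        spec = TreeSpec(vessel_class, tuple(root_pt), tuple(root_dir), segments, junctions, disc)
        if _tree_is_clear(segments, clearance):
            spec.validate()
            return spec
    raise RuntimeError(f"could not grow a collision-free tree in {max_attempts} attempts")


def generate_arcade_pair(
    disc: DiscGeometry,
    vessel_class: str = "artery",
    seed: int = 0,
    depth: int = 4,
    sup_azimuth: tuple[float, float] = (-75.0, -35.0),
    inf_azimuth: tuple[float, float] = (35.0, 75.0),
    **kw,
):
    """Superior + inferior arcade trees for one vessel class, jointly
    collision-free, emulating the two major temporal arcades.

    Azimuths are degrees around the disc: 0° points temporally (+col),
    negative values superiorly (−row); defaults place both arcades on
    the temporal side like the real vascular arcades.
    """
    rng = np.random.default_rng(seed)
    for _ in range(40):
        s_sup = int(rng.integers(0, 2**31 - 1))
        s_inf = int(rng.integers(0, 2**31 - 1))
        az_sup = float(rng.uniform(*sup_azimuth))
        az_inf = float(rng.uniform(*inf_azimuth))
        sup = generate_tree_spec(depth, disc=disc, vessel_class=vessel_class, seed=s_sup,
                                 root_azimuth_deg=az_sup, **kw)
        inf = generate_tree_spec(depth, disc=disc, vessel_class=vessel_class, seed=s_inf,
                                 root_azimuth_deg=az_inf, **kw)
        clearance = kw.get("clearance", 3.0)
        ok = all(
            _seg_seg_distance(np.asarray(a.start), a.end, np.asarray(b.start), b.end)
            >= a.diameter / 2 + b.diameter / 2 + clearance
            for a in sup.segments
            for b in inf.segments
        )
        if ok:
            return sup, inf
    raise RuntimeError("could not place a collision-free arcade pair")


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _spec_strahler(spec: TreeSpec) -> dict[int, int]:
    """Strahler order per segment of the planned tree (recursive)."""
    kids: dict[int, list[int]] = {}
    for s in spec.segments:
        if s.parent is not None:
            kids.setdefault(s.parent, []).append(s.id)
    order: dict[int, int] = {}

    def rec(sid: int) -> int:
        ds = kids.get(sid, [])
        if not ds:
            order[sid] = 1
            return 1
        sub = [rec(d) for d in ds]
        m = max(sub)
        order[sid] = m + 1 if sub.count(m) >= 2 else m
        return order[sid]

    for s in spec.segments:
        if s.parent is None:
            rec(s.id)
    return order


def _spec_ma_anchor(spec: TreeSpec):
    """Distal end of the last maximal-order segment along the chain from
    the root (None for a junction-free spec)."""
    order = _spec_strahler(spec)
    kids: dict[int, list[int]] = {}
    for s in spec.segments:
        if s.parent is not None:
            kids.setdefault(s.parent, []).append(s.id)
    by_id = {s.id: s for s in spec.segments}
    roots = [s.id for s in spec.segments if s.parent is None]
    if not roots:
        return None
    cur = roots[0]
    m = order[cur]
    while True:
        nxt = [k for k in kids.get(cur, []) if order[k] == m]
        if not nxt:
            return tuple(by_id[cur].end)
        cur = nxt[0]


def ground_truth_morphometry(
    spec: TreeSpec, annulus=(0.5, 2.0)
) -> GroundTruthTable:
    """Analytic junction table and arcade anchor of a planned tree.

    Angles come from the planned direction vectors, coefficients from
    the planned diameters, junction classes from Strahler orders of the
    planned tree itself.
    """
    order = _spec_strahler(spec)
    by_id = {s.id: s for s in spec.segments}
    rows = []
    for jid, j in enumerate(spec.junctions):
        d1, d2 = (by_id[d] for d in j.daughters[:2])
        u1 = np.asarray(d1.direction)
        u2 = np.asarray(d2.direction)
        ang = math.degrees(math.acos(float(np.clip(np.dot(u1, u2), -1, 1))))
        parent = by_id[j.parent_segment]
        coef = (d1.diameter**2 + d2.diameter**2) / parent.diameter**2
        o1, o2 = order[d1.id], order[d2.id]
        rows.append(
            {
                "junction_id": jid,
                "class": "bifurcation" if o1 == o2 else "branching",
                "angle": ang,
                "coefficient": coef,
                "in_annulus": in_annulus(j.node, spec.disc, annulus[0], annulus[1]),
                "daughter_orders": (o1, o2),
                "node_row": j.node[0],
                "node_col": j.node[1],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["junction_id", "class", "angle", "coefficient", "in_annulus",
                 "daughter_orders", "node_row", "node_col"],
    )
    anchor = _spec_ma_anchor(spec)
    flags = [] if spec.junctions else ["main_angle_undefined"]
    return GroundTruthTable(junctions=df, ma_anchor=anchor, flags=flags)


def ground_truth_main_angle(
    superior: TreeSpec, inferior: TreeSpec, vertex=None
) -> float:
    """Analytic MA of an arcade pair: angle at the disc center between the
    rays to the two maximal-order chain endpoints."""
    center = np.asarray(vertex if vertex is not None else superior.disc.center, float)
    a_sup = _spec_ma_anchor(superior)
    a_inf = _spec_ma_anchor(inferior)
    if a_sup is None or a_inf is None:
        return math.nan
    v1 = np.asarray(a_sup) - center
    v2 = np.asarray(a_inf) - center
    c = float(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _stamp_segment(canvas: np.ndarray, seg: Segment) -> None:
    """Draw one segment as an exact stadium (capsule) of its diameter."""
    H, W = canvas.shape
    a = np.asarray(seg.start, float)
    b = seg.end
    r = seg.diameter / 2.0
    r0 = max(int(math.floor(min(a[0], b[0]) - r - 1)), 0)
    r1 = min(int(math.ceil(max(a[0], b[0]) + r + 1)), H - 1)
    c0 = max(int(math.floor(min(a[1], b[1]) - r - 1)), 0)
    c1 = min(int(math.ceil(max(a[1], b[1]) + r + 1)), W - 1)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    p = np.stack([rr, cc], axis=-1).astype(float)
    ab = b - a
    denom = max(float(np.dot(ab, ab)), 1e-12)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    dist = np.hypot(*(p - proj).transpose(2, 0, 1))
    canvas[r0:r1 + 1, c0:c1 + 1] |= dist <= r


def render_tree(spec: TreeSpec, height: int, width: int) -> RasterMask:
    """Rasterize a tree spec into a strictly binary mask."""
    return render_trees([spec], height, width, vessel_class=spec.vessel_class)


def render_trees(specs, height: int, width: int, vessel_class: str | None = None) -> RasterMask:
    """Rasterize several tree specs (e.g. an arcade pair) into one mask."""
    canvas = np.zeros((height, width), dtype=bool)
    offenders = []
    for spec in specs:
        for seg in spec.segments:
            a, b, r = np.asarray(seg.start), seg.end, seg.diameter / 2
            lo = np.minimum(a, b) - r
            hi = np.maximum(a, b) + r
            if lo[0] < 0 or lo[1] < 0 or hi[0] > height - 1 or hi[1] > width - 1:
                offenders.append(seg.id)
    if offenders:
        raise ValueError(f"segments out of canvas: {offenders}")
    for spec in specs:
        for seg in spec.segments:
            _stamp_segment(canvas, seg)
    vc = vessel_class or (specs[0].vessel_class if specs else "artery")
    return RasterMask(canvas, vc)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    label: str
    n: int
    means: dict[str, float]  # metric -> mean
    sds: dict[str, float]    # metric -> SD

    def __post_init__(self):
        if self.label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.label!r}")
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("SD must be >= 0")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0
    vessel_class: str = "vein"

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-image metric table: each metric of each image is an
    independent Normal(mean, SD) draw for its group. Deterministic in
    ``spec.seed``; with SD = 0 every value equals the group mean."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        data = {"image_id": [f"{g.label}_{i:05d}" for i in range(g.n)],
                "group": [g.label] * g.n, "vessel_class": [spec.vessel_class] * g.n}
        for metric in METRICS:
            mu = g.means.get(metric, math.nan)
            sd = g.sds.get(metric, 0.0)
            data[metric] = mu + sd * rng.standard_normal(g.n) if sd > 0 else np.full(g.n, mu)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def reference_cohort_spec(
    vessel_class: str = "vein", sd_mode: str = "derived", seed: int = 0
) -> CohortSpec:
    """Cohort spec at the published reference summaries.

    ``sd_mode='derived'`` backs SDs out of the printed 95% CIs
    (:func:`ci_derived_sd`); ``'zero'`` makes every group degenerate at
    its printed mean (useful to reproduce printed mean differences
    exactly).
    """
    if sd_mode not in ("derived", "zero"):
        raise ValueError("sd_mode must be 'derived' or 'zero'")
    groups = []
    for label in GROUP_LABELS:
        n = REFERENCE_GROUP_SIZES[label]
        means, sds = {}, {}
        for metric in METRICS:
            mean, lo, hi = REFERENCE_TABLE[(vessel_class, metric)][label]
            means[metric] = mean
            sds[metric] = ci_derived_sd(lo, hi, n) if sd_mode == "derived" else 0.0
        groups.append(GroupSpec(label, n, means, sds))
    return CohortSpec(groups=groups, seed=seed, vessel_class=vessel_class)
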