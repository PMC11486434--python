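"""Chorionic vessel growth over the chorionic-plate mesh.

Two umbilical-artery segments are laid onto the plate at the cord insertion
and chorionic arteries grow from them generation by generation.  Candidate
daughter endpoints are plate mesh vertices at the desired branch length
(within tolerance) and branching angle (within tolerance); candidates are
ranked by a global distribution penalty that rewards distance to the
existing tree (D1, weight cf1) and closeness to the plate centroid (D2,
weight cf2), and the first ranked candidate passing the branch-intersection
pipeline is accepted.  Growth stops at ``bg_c`` generations or ``bn_c``
segments; a branch terminates when its tip comes closer than its diameter
to other tree nodes or closer than twice its diameter to the plate margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import collision
from .config import Distribution, constant, normal, positive_sample, uniform
from .geometry import TriangulatedSurface
from .trees import ROOT, TreeBuilder, VascularTree, vector_angles_deg

logger = logging.getLogger("fetovasc.chorionic")

#: Cubic fit of the chorionic length-to-diameter ratio over generation.
LTD_C_COEFFS = (0.02629, -0.655, 5.176, -0.7898)

UMBILICAL_LENGTH_MM = 20.0
STEM_LENGTH_MM = 2.0


class GrowthFailure(RuntimeError):
    """No viable daughter candidate could be placed at the tree root."""


@dataclass
class ChorionicGrowthParams:
    """User-tunable inputs for umbilical/chorionic growth (defaults: healthy)."""

    ud: Distribution = field(default_factory=lambda: normal(4.6, 0.9))
    k_c: float = 3.2
    theta_pd: Distribution = field(default_factory=lambda: uniform(35.0, 50.0))
    theta_dd_min: float = 70.0
    theta_dd_max: float = 100.0
    ltd_c_sd: float = 1.0
    a: Distribution = field(default_factory=lambda: normal(1.0, 0.05))
    bg_c: int = 8
    bn_c: int = 100
    cf1: float = 0.8
    cf2: float = 0.2
    tol_l: float = 0.10
    tol_theta: float = 0.30
    collision_multiplier: float = collision.VENOUS_MULTIPLIER
    max_candidate_batch: int = 128
    retries: int = 3

    def __post_init__(self) -> None:
        if self.bg_c < 1 or self.bn_c < 2:
            raise ValueError("bg_c >= 1 and bn_c >= 2 required")
        if self.cf1 < 0 or self.cf2 < 0:
            raise ValueError("penalty weights must be non-negative")
        if not (0 <= self.tol_l < 1 and 0 <= self.tol_theta < 1):
            raise ValueError("tolerance fractions must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "ChorionicGrowthParams":
        kwargs = dict(d)
        for key in ("ud", "theta_pd", "a"):
            if key in kwargs:
                kwargs[key] = Distribution.from_spec(kwargs[key])
        return cls(**kwargs)


@dataclass
class CandidateSet:
    """Scored candidate daughter nodes δ_i with their penalty terms."""

    points: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    score: np.ndarray
    order: np.ndarray  # candidate indices sorted by descending score

    def __len__(self) -> int:
        return self.points.shape[0]


def ltd_c_of_generation(g) -> float:
    """Mean chorionic length-to-diameter ratio at branching generation g."""
    a, b, c, d = LTD_C_COEFFS
    g = np.asarray(g, dtype=float)
    out = ((a * g + b) * g + c) * g + d
    return float(out) if out.ndim == 0 else out


def apply_tolerances(l: float, theta_pd: float, tol_l: float, tol_theta: float):
    """Tolerance windows l_f = l·(1±tol_l), θ_f = θ_pd·(1±tol_θ)."""
    return ((l * (1.0 - tol_l), l * (1.0 + tol_l)),
            (theta_pd * (1.0 - tol_theta), theta_pd * (1.0 + tol_theta)))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-300:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def score_candidates_chorionic(tree, candidates: np.ndarray,
                               plate_centroid: np.ndarray,
                               cf1: float, cf2: float) -> CandidateSet:
    """Rank candidates by L = cf1·norm(D1) + cf2·norm(1/D2).

    D1 is each candidate's minimum distance to the existing tree nodes
    (spreads vessels apart); D2 its distance to the plate centroid (pulls
    growth over the plate interior).
    """
    coords = tree.node_coords if isinstance(tree, VascularTree) else np.asarray(tree)
    candidates = np.atleast_2d(candidates)
    if candidates.shape[0] == 0:
        return CandidateSet(candidates, np.empty(0), np.empty(0),
                            np.empty(0), np.empty(0, dtype=int))
    d1, _ = cKDTree(coords).query(candidates)
    d2 = np.linalg.norm(candidates - np.asarray(plate_centroid)[None], axis=1)
    with np.errstate(divide="ignore"):
        inv_d2 = np.where(d2 > 1e-12, 1.0 / d2, np.inf)
    inv_d2 = np.where(np.isinf(inv_d2), np.nanmax(inv_d2[~np.isinf(inv_d2)],
                                                  initial=1.0), inv_d2)
    score = cf1 * _minmax(d1) + cf2 * _minmax(inv_d2)
    order = np.argsort(-score, kind="stable")
    return CandidateSet(candidates, d1, d2, score, order)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _outward_normal(point: np.ndarray, semi_axes) -> np.ndarray:
    if semi_axes is None:
        return np.array([0.0, 0.0, 1.0])
    a, b, c = semi_axes
    n = np.array([point[0] / a ** 2, point[1] / b ** 2, point[2] / c ** 2])
    nn = np.linalg.norm(n)
    return n / nn if nn > 0 else np.array([0.0, 0.0, 1.0])


def _tangent_frame(point: np.ndarray, semi_axes, rng: np.random.Generator):
    """(x_t, r_t, n): local plate tangent frame at ``point``.

    ``r_t`` is the outward normal projected onto the tangent plane (the
    down-slope direction away from the pole); at the pole the azimuth is a
    seeded random choice.
    """
    n = _outward_normal(point, semi_axes)
    radial = np.array([point[0], point[1], 0.0])
    r_t = radial - (radial @ n) * n
    nrm = np.linalg.norm(r_t)
    if nrm < 1e-9:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        helper = np.array([np.cos(phi), np.sin(phi), 0.0])
        r_t = helper - (helper @ n) * n
        nrm = np.linalg.norm(r_t)
    r_t = r_t / nrm
    x_t = np.cross(r_t, n)
    x_t /= np.linalg.norm(x_t)
    return x_t, r_t, n


class _ChorionicGrower:
    def __init__(self, plate: TriangulatedSurface, insertion: int,
                 params: ChorionicGrowthParams, rng: np.random.Generator):
        self.plate = plate
        self.params = params
        self.rng = rng
        self.kdtree = plate.meta.get("_kdtree")
        if self.kdtree is None:
            self.kdtree = cKDTree(plate.vertices)
            plate.meta["_kdtree"] = self.kdtree
        self.boundary_tree = cKDTree(plate.vertices[plate.boundary_loop]) \
            if plate.boundary_loop.size else None
        self.centroid = plate.centroid
        self.semi_axes = plate.meta.get("semi_axes")
        self.builder = TreeBuilder()
        self.seg_start: list[np.ndarray] = []
        self.seg_end: list[np.ndarray] = []
        self.seg_diam: list[float] = []
        self.node_seg: dict[int, int] = {}   # node id -> index of its segment
        self.used_vertices: set[int] = set()
        self.insertion = insertion
        self.stats = {"accepted": 0, "rejected_collision": 0, "dead_tips": 0}

    # -- plumbing -----------------------------------------------------------
    def _add_segment(self, parent_node: int, point: np.ndarray, diameter: float,
                     generation: int, label: str) -> int:
        node = self.builder.add_node(point, parent=parent_node,
                                     diameter=diameter, generation=generation,
                                     label=label)
        self.seg_start.append(np.asarray(self.builder.coords[parent_node]))
        self.seg_end.append(np.asarray(point, dtype=float))
        self.seg_diam.append(diameter)
        self.node_seg[node] = len(self.seg_diam) - 1
        return node

    def _segments(self):
        return (np.array(self.seg_start), np.array(self.seg_end),
                np.array(self.seg_diam))

    def n_segments(self) -> int:
        return len(self.seg_diam)

    # -- roots --------------------------------------------------------------
    def place_umbilical_roots(self) -> list[tuple[int, int]]:
        ins_pt = self.plate.vertices[self.insertion]
        x_t, r_t, _ = _tangent_frame(ins_pt, self.semi_axes, self.rng)
        # the cord's orientation about its own axis is arbitrary: rotate the
        # in-plate frame by a seeded random azimuth
        phi = self.rng.uniform(0.0, 2.0 * np.pi)
        axis = np.cos(phi) * x_t + np.sin(phi) * r_t
        perp = -np.sin(phi) * x_t + np.cos(phi) * r_t
        tips = []
        for sign in (+1.0, -1.0):
            ud = positive_sample(self.params.ud, self.rng)
            # the two arteries leave the cord in opposite directions along
            # the local x axis, each displaced by ud in the perpendicular so
            # the antiparallel cylinders clear each other (at ±ud/2 they
            # would sit in exact contact, which the collision rule forbids)
            start = ins_pt + sign * ud * perp
            end_target = start + sign * UMBILICAL_LENGTH_MM * axis
            _, end_idx = self.kdtree.query(end_target)
            end = self.plate.vertices[end_idx]
            root = self.builder.add_node(start)
            tip = self._add_segment(root, end, ud, 0, "umbilical")
            self.used_vertices.add(int(end_idx))
            tips.append((tip, 0))
        return tips

    # -- termination --------------------------------------------------------
    def tip_terminated(self, tip: int) -> bool:
        point = np.asarray(self.builder.coords[tip])
        diam = self.builder.diameter[tip]
        coords = np.array(self.builder.coords)
        parent = self.builder.parent[tip]
        d = np.linalg.norm(coords - point[None], axis=1)
        d[tip] = np.inf
        if parent != ROOT:
            d[parent] = np.inf
        if np.min(d) < diam:
            return True
        if self.boundary_tree is not None:
            b, _ = self.boundary_tree.query(point)
            if b < 2.0 * diam:
                return True
        return False

    # -- daughters ----------------------------------------------------------
    def find_daughter(self, tip: int, diameter: float, generation: int,
                      sibling_dir: np.ndarray | None):
        """Place one daughter segment from ``tip``; returns node id or None."""
        p = self.params
        tip_pt = np.asarray(self.builder.coords[tip])
        parent_pt = np.asarray(self.builder.coords[self.builder.parent[tip]])
        u = tip_pt - parent_pt
        u /= np.linalg.norm(u)
        ltd = float(self.rng.normal(ltd_c_of_generation(generation), p.ltd_c_sd))
        length = max(ltd, 0.5) * diameter
        theta = float(p.theta_pd.sample(self.rng))
        (l_lo, l_hi), (t_lo, t_hi) = apply_tolerances(length, theta,
                                                      p.tol_l, p.tol_theta)
        idx = np.array(self.kdtree.query_ball_point(tip_pt, l_hi), dtype=int)
        if idx.size == 0:
            return None
        pts = self.plate.vertices[idx]
        vec = pts - tip_pt[None]
        dist = np.linalg.norm(vec, axis=1)
        keep = dist >= max(l_lo, 1e-9)
        idx, pts, vec, dist = idx[keep], pts[keep], vec[keep], dist[keep]
        if idx.size == 0:
            return None
        ang = vector_angles_deg(u[None], vec)
        keep = (ang >= t_lo) & (ang <= t_hi)
        if sibling_dir is not None:
            dd = vector_angles_deg(sibling_dir[None], vec)
            keep &= (dd >= p.theta_dd_min) & (dd <= p.theta_dd_max)
        if self.used_vertices:
            keep &= ~np.isin(idx, np.fromiter(self.used_vertices, dtype=int))
        idx, pts = idx[keep], pts[keep]
        if idx.size == 0:
            return None

        cs = score_candidates_chorionic(np.array(self.builder.coords), pts,
                                        self.centroid, p.cf1, p.cf2)
        starts, ends, diams = self._segments()
        exempt_cols = {self.node_seg[tip]} if tip in self.node_seg else set()
        if sibling_dir is not None:
            exempt_cols.add(len(self.seg_diam) - 1)  # daughter-1 just placed
        exempt_row = np.zeros(len(self.seg_diam), dtype=bool)
        exempt_row[list(exempt_cols)] = True
        for lo in range(0, len(cs.order), p.max_candidate_batch):
            batch = cs.order[lo: lo + p.max_candidate_batch]
            bpts = pts[batch]
            ok = collision.candidates_collision_free(
                np.broadcast_to(tip_pt, bpts.shape), bpts,
                np.full(batch.size, diameter), starts, ends, diams,
                exempt=np.broadcast_to(exempt_row, (batch.size, exempt_row.size)),
                multiplier=p.collision_multiplier)
            if ok.any():
                pick = batch[int(np.argmax(ok))]
                self.stats["rejected_collision"] += lo + int(np.argmax(ok))
                node = self._add_segment(tip, pts[pick], diameter,
                                         generation, "chorionic")
                self.used_vertices.add(int(idx[pick]))
                self.stats["accepted"] += 1
                return node
        self.stats["rejected_collision"] += len(cs.order)
        return None

    def grow(self) -> VascularTree:
        p = self.params
        tips = self.place_umbilical_roots()
        for generation in range(1, p.bg_c + 1):
            new_tips = []
            for tip, _ in tips:
                if self.n_segments() >= p.bn_c:
                    break
                if self.tip_terminated(tip):
                    self.stats["dead_tips"] += 1
                    continue
                d_tip = self.builder.diameter[tip]
                placed = []
                for _ in range(p.retries):
                    a = max(float(p.a.sample(self.rng)), 0.05)
                    from .trees import murray_daughter_diameters
                    d1, d2 = murray_daughter_diameters(d_tip, p.k_c, a)
                    n1 = self.find_daughter(tip, d1, generation, None)
                    sib_dir = None
                    if n1 is not None:
                        sib_dir = (np.asarray(self.builder.coords[n1])
                                   - np.asarray(self.builder.coords[tip]))
                        sib_dir /= np.linalg.norm(sib_dir)
                        placed.append(n1)
                    if n1 is not None and self.n_segments() < p.bn_c:
                        n2 = self.find_daughter(tip, d2, generation, sib_dir)
                        if n2 is not None:
                            placed.append(n2)
                    if placed:
                        break
                if not placed:
                    self.stats["dead_tips"] += 1
                new_tips.extend((n, generation) for n in placed)
            logger.info("chorionic generation %d: %d segments, %d active tips",
                        generation, self.n_segments(), len(new_tips))
            tips = new_tips
            if not tips or self.n_segments() >= p.bn_c:
                break
        if self.n_segments() <= 2:
            raise GrowthFailure("no viable daughter candidates at the cord insertion")
        return self.builder.build(meta={"stage": "chorionic",
                                        "stats": dict(self.stats)})


def grow_chorionic_tree(plate: TriangulatedSurface, insertion: int,
                        params: ChorionicGrowthParams | None = None,
                        rng_seed=None) -> VascularTree:
    """Grow umbilical + chorionic arteries on a chorionic-plate patch.

    ``insertion`` is a plate vertex index (see ``locate_cord_insertion``);
    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    params = params or ChorionicGrowthParams()
    rng = np.random.default_rng(rng_seed)
    return _ChorionicGrower(plate, insertion, params, rng).grow()


# ---------------------------------------------------------------------------
# stem vessels
# ---------------------------------------------------------------------------

def attach_stem_vessels(tree: VascularTree, plate: TriangulatedSurface,
                        rng_seed=None,
                        stem_diameter: Distribution | None = None,
                        inside_test=None, retries: int = 8) -> VascularTree:
    """Append one 2 mm intraplacental stem per chorionic artery segment.

    Each chorionic segment is split at its midpoint and a stem segment of
    length 2 mm leaves the midpoint into the placental volume (−z side) at
    an angle sampled uniformly in [60°, 90°] to the chorionic segment axis.
    ``inside_test`` may be a predicate on points; stems whose far end fails
    it are re-sampled and finally skipped (logged).
    """
    rng = np.random.default_rng(rng_seed)
    stem_diameter = stem_diameter or normal(0.7, 0.03)
    semi_axes = plate.meta.get("semi_axes")
    builder = TreeBuilder()
    for i in range(tree.n_nodes):
        builder.add_node(tree.node_coords[i], parent=int(tree.parent_index[i]),
                         diameter=float(tree.segment_diameters[i]),
                         generation=int(tree.segment_generation[i]),
                         label=str(tree.segment_label[i]))
    chorionic_segs = [i for i in tree.segments
                      if tree.segment_label[i] == "chorionic"]
    n_placed = 0
    for seg in chorionic_segs:
        parent_node = int(tree.parent_index[seg])
        a = tree.node_coords[parent_node]
        b = tree.node_coords[seg]
        mid = 0.5 * (a + b)
        u = (b - a) / np.linalg.norm(b - a)
        n_out = _outward_normal(mid, semi_axes)
        w = -n_out + (n_out @ u) * u
        nrm = np.linalg.norm(w)
        if nrm < 1e-9:
            w = np.array([0.0, 0.0, -1.0])
            nrm = 1.0
        w = w / nrm
        # a stem cannot be thicker than the chorionic vessel carrying it
        d_s = min(positive_sample(stem_diameter, rng),
                  float(tree.segment_diameters[seg]))
        end = None
        for _ in range(retries):
            alpha = np.radians(rng.uniform(60.0, 90.0))
            sign = rng.choice([-1.0, 1.0])
            direction = sign * np.cos(alpha) * u + np.sin(alpha) * w
            trial = mid + STEM_LENGTH_MM * direction
            if inside_test is None or bool(np.atleast_1d(inside_test(trial))[0]):
                end = trial
                break
        if end is None:
            logger.info("stem at segment %d left the placental surface; skipped", seg)
            continue
        # split the chorionic segment at its midpoint
        mid_node = builder.add_node(mid, parent=parent_node,
                                    diameter=float(tree.segment_diameters[seg]),
                                    generation=int(tree.segment_generation[seg]),
                                    label="chorionic")
        builder.parent[seg] = mid_node
        builder.add_node(end, parent=mid_node, diameter=d_s,
                         generation=0, label="stem")
        n_placed += 1
    out = builder.build(meta={**tree.meta, "n_stems": n_placed})
    return out
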