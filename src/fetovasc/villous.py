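"""Villous-tree growth in 3D domains and whole-organ assembly.

Villous trees grow from a 2 mm stem vessel into the intervillous space,
bifurcating generation by generation.  Candidate daughter endpoints are
sampled uniformly on a sphere of the desired branch length around the tip;
the plane through tip, parent and grandparent (unit normal ``n_V``) splits
candidates so the two daughters leave on opposite sides, which drives the
out-of-plane alternation typical of villous branching.  Candidates are
filtered by the parent-daughter angle window, ranked by a penalty rewarding
distance to the ``n_V`` plane (cf1) and closeness to the basal plate (cf2),
and accepted on the first collision-free candidate inside the growth domain
and outside the central cavity.  Branches stop at ``bg_v`` generations,
when diameters fall below the terminal band, or when a tip crowds other
vessels (closer than its diameter) or the basal plate (closer than twice
its diameter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import collision
from .config import Distribution, normal, positive_sample
from .chorionic import ChorionicGrowthParams, attach_stem_vessels, grow_chorionic_tree
from .geometry import (CM, PlacentalShapeParams, PlacentoneDomain,
                       TriangulatedSurface, _latlong_spheroid, chorionic_area,
                       extract_chorionic_plate, locate_cord_insertion,
                       build_placental_surface)
from .trees import (ROOT, VascularTree, murray_daughter_diameters,
                    vector_angles_deg)

logger = logging.getLogger("fetovasc.villous")

STEM_LENGTH_MM = 2.0


@dataclass
class VillousGrowthParams:
    """User-tunable inputs for villous growth (defaults: healthy placentone)."""

    d_s: Distribution = field(default_factory=lambda: normal(0.7, 0.03))
    ltd_v: Distribution = field(default_factory=lambda: normal(10.5, 0.8))
    k_v: float = 3.2
    a: Distribution = field(default_factory=lambda: normal(1.0, 0.05))
    theta_pd: Distribution = field(default_factory=lambda: normal(45.0, 15.0))
    theta_dd_min: float = 25.0
    cf1: float = 0.7
    cf2: float = 0.3
    bg_v: int = 15
    #: expected terminal caliber range (mm) that bg_v is chosen to reach for
    #: healthy inputs; reported/validated, not a termination rule — growth
    #: stops at bg_v or by the distance criteria only
    terminal_diameter_band: tuple = (0.03, 0.04)
    tol_theta: float = 0.15
    n_sphere_candidates: int = 500
    collision_multiplier: float = collision.VENOUS_MULTIPLIER
    max_candidate_batch: int = 32
    retries: int = 3

    def __post_init__(self) -> None:
        if self.bg_v < 1:
            raise ValueError("bg_v >= 1 required")
        lo, hi = self.terminal_diameter_band
        if not 0 < lo < hi:
            raise ValueError("terminal diameter band must satisfy 0 < lo < hi")

    @classmethod
    def from_dict(cls, d: dict) -> "VillousGrowthParams":
        kwargs = dict(d)
        for key in ("d_s", "ltd_v", "a", "theta_pd"):
            if key in kwargs:
                kwargs[key] = Distribution.from_spec(kwargs[key])
        if "terminal_diameter_band" in kwargs:
            kwargs["terminal_diameter_band"] = tuple(kwargs["terminal_diameter_band"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def branch_plane_normal(c_g, c_gm1, c_gm2, rng=None) -> np.ndarray:
    """Unit normal of the plane through the tip, its parent and grandparent.

    For (numerically) collinear points the fallback is a seeded random unit
    vector orthogonal to the parent direction.
    """
    c_g = np.asarray(c_g, dtype=float)
    n = np.cross(np.asarray(c_gm1, dtype=float) - c_g,
                 np.asarray(c_gm2, dtype=float) - c_g)
    nn = np.linalg.norm(n)
    if nn > 1e-9:
        return n / nn
    logger.debug("collinear branch points; using random orthogonal normal")
    rng = np.random.default_rng(rng)
    u = np.asarray(c_gm1, dtype=float) - c_g
    u = u / np.linalg.norm(u)
    while True:
        v = rng.normal(size=3)
        v -= (v @ u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            return v / nv


def sample_sphere_candidates(center, radius: float, n_points: int,
                             rng=None) -> np.ndarray:
    """Approximately uniform points on the sphere of ``radius`` about ``center``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(rng)
    v = rng.normal(size=(n_points, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return np.asarray(center, dtype=float)[None] + radius * v


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-300:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass
class CandidateSet:
    points: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    score: np.ndarray
    order: np.ndarray


def score_candidates_villous(candidates: np.ndarray, plane_normal, plane_point,
                             basal_vertices, cf1: float, cf2: float) -> CandidateSet:
    """Rank candidates by L = cf1·norm(D1) + cf2·norm(1/D2).

    D1 is the unsigned distance to the branching plane (maximised — daughters
    escape the plane of their ancestors); D2 the minimum distance to the
    basal-plate vertices (minimised — growth is drawn towards the basal
    plate).  ``basal_vertices`` may be an ``(N, 3)`` array or a cKDTree.
    """
    candidates = np.atleast_2d(candidates)
    if candidates.shape[0] == 0:
        e = np.empty(0)
        return CandidateSet(candidates, e, e, e, np.empty(0, dtype=int))
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    d1 = np.abs((candidates - np.asarray(plane_point, dtype=float)[None]) @ n)
    tree = basal_vertices if isinstance(basal_vertices, cKDTree) \
        else cKDTree(np.atleast_2d(basal_vertices))
    d2, _ = tree.query(candidates)
    with np.errstate(divide="ignore"):
        inv_d2 = np.where(d2 > 1e-12, 1.0 / d2, np.inf)
    finite_max = np.nanmax(np.where(np.isinf(inv_d2), np.nan, inv_d2), initial=1.0)
    inv_d2 = np.where(np.isinf(inv_d2), finite_max, inv_d2)
    score = cf1 * _minmax(d1) + cf2 * _minmax(inv_d2)
    order = np.argsort(-score, kind="stable")
    return CandidateSet(candidates, d1, d2, score, order)


# ---------------------------------------------------------------------------
# growth domains
# ---------------------------------------------------------------------------

class _PlacentoneAdapter:
    def __init__(self, dom: PlacentoneDomain):
        self.dom = dom
        self.basal_tree = cKDTree(dom.basal_vertices())
        self.convex = True

    def admissible(self, points: np.ndarray, margin: float) -> np.ndarray:
        return self.dom.contains(points, margin=margin)

    def in_cavity(self, points: np.ndarray) -> np.ndarray:
        return self.dom.cavity_test(points)

    @property
    def volume(self) -> float:
        return self.dom.volume


class _MeshAdapter:
    """Closed triangulated surface as a growth domain (no cavity)."""

    def __init__(self, surface: TriangulatedSurface, pitch: float | None = None):
        self.surface = surface
        self.pitch = pitch
        basal = surface.vertices[surface.vertices[:, 2] < 0.0]
        self.basal_tree = cKDTree(basal)
        self.convex = True  # spheroids are convex; general meshes may not be

    def admissible(self, points: np.ndarray, margin: float) -> np.ndarray:
        return collision.point_in_mesh(self.surface, np.atleast_2d(points),
                                       pitch=self.pitch)

    def in_cavity(self, points: np.ndarray) -> np.ndarray:
        return np.zeros(np.atleast_2d(points).shape[0], dtype=bool)

    @property
    def volume(self) -> float:
        return self.surface.volume()


def make_domain_adapter(domain):
    if isinstance(domain, PlacentoneDomain):
        return _PlacentoneAdapter(domain)
    if isinstance(domain, TriangulatedSurface):
        return _MeshAdapter(domain)
    return domain


# ---------------------------------------------------------------------------
# the grower (flat numpy buffers; hot path)
# ---------------------------------------------------------------------------

class _VillousGrower:
    REBUILD_EVERY = 512

    def __init__(self, domain_adapter, params: VillousGrowthParams,
                 rng: np.random.Generator, capacity: int = 1 << 12):
        self.dom = domain_adapter
        self.p = params
        self.rng = rng
        # node buffers
        self.coords = np.empty((capacity, 3))
        self.parent = np.full(capacity, ROOT, dtype=np.int64)
        self.n_nodes = 0
        self.node_label: list[str] = []
        self.node_gen: list[int] = []
        self.node_diam: list[float] = []
        # segment buffers (segment i ends at child node seg_child[i])
        self.seg_start = np.empty((capacity, 3))
        self.seg_end = np.empty((capacity, 3))
        self.seg_diam = np.empty(capacity)
        self.n_segs = 0
        self.node_seg = np.full(capacity, -1, dtype=np.int64)
        self.children_segs: dict[int, list[int]] = {}
        #: segments longer than this are screened by exact point-to-segment
        #: distance: a long segment can pass near a short candidate without
        #: either of its endpoints entering the local neighbourhood query
        self.long_threshold = 1.0
        self.long_segs: list[int] = []
        self._node_tree: cKDTree | None = None
        self._tree_size = 0
        self.stats = {"accepted": 0, "dead_tips": 0}

    # -- buffers ------------------------------------------------------------
    def _ensure(self, extra: int) -> None:
        need = max(self.n_nodes, self.n_segs) + extra
        cap = self.coords.shape[0]
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("coords", "seg_start", "seg_end"):
            buf = np.empty((cap, 3))
            buf[: getattr(self, name).shape[0]] = getattr(self, name)
            setattr(self, name, buf)
        for name, fill in (("parent", ROOT), ("node_seg", -1)):
            buf = np.full(cap, fill, dtype=np.int64)
            buf[: getattr(self, name).shape[0]] = getattr(self, name)
            setattr(self, name, buf)
        buf = np.empty(cap)
        buf[: self.seg_diam.shape[0]] = self.seg_diam
        self.seg_diam = buf

    def add_node(self, coord, parent: int = ROOT, diameter: float = np.nan,
                 generation: int = -1, label: str = "") -> int:
        self._ensure(1)
        i = self.n_nodes
        self.coords[i] = coord
        self.parent[i] = parent
        self.node_label.append(label)
        self.node_gen.append(generation)
        self.node_diam.append(diameter)
        self.n_nodes += 1
        if parent != ROOT:
            s = self.n_segs
            self.seg_start[s] = self.coords[parent]
            self.seg_end[s] = coord
            self.seg_diam[s] = diameter
            self.node_seg[i] = s
            self.children_segs.setdefault(parent, []).append(s)
            if np.linalg.norm(self.seg_end[s] - self.seg_start[s]) > self.long_threshold:
                self.long_segs.append(s)
            self.n_segs += 1
        if self.n_nodes - self._tree_size >= self.REBUILD_EVERY:
            self._rebuild_tree()
        return i

    def absorb_tree(self, tree: VascularTree) -> None:
        """Seed the grower with an existing tree (parent refs may be forward)."""
        self._ensure(tree.n_nodes)
        for i in range(tree.n_nodes):
            j = self.n_nodes
            self.coords[j] = tree.node_coords[i]
            self.parent[j] = tree.parent_index[i]
            self.node_label.append(str(tree.segment_label[i]))
            self.node_gen.append(int(tree.segment_generation[i]))
            self.node_diam.append(float(tree.segment_diameters[i]))
            self.n_nodes += 1
        for i in tree.segments:
            s = self.n_segs
            self.seg_start[s] = tree.node_coords[tree.parent_index[i]]
            self.seg_end[s] = tree.node_coords[i]
            self.seg_diam[s] = tree.segment_diameters[i]
            self.node_seg[i] = s
            self.children_segs.setdefault(int(tree.parent_index[i]), []).append(s)
            if np.linalg.norm(self.seg_end[s] - self.seg_start[s]) > self.long_threshold:
                self.long_segs.append(s)
            self.n_segs += 1
        self._rebuild_tree()

    def _rebuild_tree(self) -> None:
        self._node_tree = cKDTree(self.coords[: self.n_nodes])
        self._tree_size = self.n_nodes

    def _nodes_near(self, point: np.ndarray, radius: float) -> list[int]:
        hits = (self._node_tree.query_ball_point(point, radius)
                if self._node_tree is not None else [])
        tail = self.coords[self._tree_size: self.n_nodes]
        if tail.shape[0]:
            close = np.flatnonzero(
                np.einsum("ij,ij->i", tail - point, tail - point) <= radius * radius)
            hits = list(hits) + (close + self._tree_size).tolist()
        return hits

    def _segments_near(self, point: np.ndarray, radius: float,
                       exempt: set[int]) -> np.ndarray:
        # endpoint query covers segments up to long_threshold in length;
        # longer ones are screened by exact point-to-segment distance (their
        # endpoints can both lie outside while the segment passes through)
        segs: set[int] = set()
        for j in self._nodes_near(point, radius + 0.5 * self.long_threshold):
            s = self.node_seg[j]
            if s >= 0:
                segs.add(int(s))
            for c in self.children_segs.get(j, ()):
                segs.add(c)
        if self.long_segs:
            idx = np.asarray(self.long_segs, dtype=np.int64)
            sv = self.seg_start[idx]
            ev = self.seg_end[idx]
            v = ev - sv
            len2 = np.einsum("ij,ij->i", v, v)
            t = np.clip(np.einsum("ij,ij->i", point[None] - sv, v) / len2, 0, 1)
            d = np.linalg.norm(point[None] - (sv + t[:, None] * v), axis=1)
            segs.update(idx[d <= radius].tolist())
        segs -= exempt
        return np.fromiter(segs, dtype=np.int64, count=len(segs))

    # -- termination --------------------------------------------------------
    def tip_terminated(self, tip: int) -> bool:
        p = self.coords[tip]
        d = self.node_diam[tip]
        parent = self.parent[tip]
        for j in self._nodes_near(p, d):
            if j != tip and j != parent:
                return True
        b_dist, _ = self.dom.basal_tree.query(p)
        return bool(b_dist < 2.0 * d)

    # -- daughter placement -------------------------------------------------
    def place_daughter(self, tip: int, diameter: float, generation: int,
                       n_v: np.ndarray, side: float,
                       sibling_dir: np.ndarray | None):
        p = self.p
        tip_pt = self.coords[tip]
        parent_pt = self.coords[self.parent[tip]]
        u = tip_pt - parent_pt
        u = u / np.linalg.norm(u)
        length = positive_sample(p.ltd_v, self.rng, floor=1.0) * diameter
        theta = float(np.clip(p.theta_pd.sample(self.rng), 1.0, 179.0))
        t_lo, t_hi = theta * (1.0 - p.tol_theta), theta * (1.0 + p.tol_theta)
        cands = sample_sphere_candidates(tip_pt, length,
                                         p.n_sphere_candidates, self.rng)
        vec = cands - tip_pt[None]
        keep = np.sign(vec @ n_v) == side
        cands, vec = cands[keep], vec[keep]
        # candidates sit on the sphere: |vec| == length, so angles reduce to
        # a single arccos over the dot products
        cosang = np.clip((vec @ u) / length, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        keep = (ang >= t_lo) & (ang <= t_hi)
        if sibling_dir is not None:
            cos_dd = np.clip((vec @ sibling_dir) / length, -1.0, 1.0)
            keep &= np.degrees(np.arccos(cos_dd)) >= p.theta_dd_min
        cands = cands[keep]
        if cands.shape[0] == 0:
            return None
        admissible = self.dom.admissible(cands, margin=diameter / 2.0)
        admissible &= ~self.dom.in_cavity(cands)
        cands = cands[admissible]
        if cands.shape[0] == 0:
            return None
        mids = 0.5 * (cands + tip_pt[None])
        keep = ~self.dom.in_cavity(mids)
        if not self.dom.convex:
            keep &= self.dom.admissible(mids, margin=0.0)
        cands = cands[keep]
        if cands.shape[0] == 0:
            return None
        cs = score_candidates_villous(cands, n_v, tip_pt, self.dom.basal_tree,
                                      p.cf1, p.cf2)
        exempt = {int(self.node_seg[tip])} if self.node_seg[tip] >= 0 else set()
        if sibling_dir is not None:
            exempt.add(self.n_segs - 1)  # daughter-1 just placed
        seg_idx = self._segments_near(tip_pt, 1.1 * length + diameter, exempt)
        if seg_idx.size:
            s_geom = (self.seg_start[seg_idx], self.seg_end[seg_idx],
                      self.seg_diam[seg_idx])
        else:
            s_geom = None
        for lo in range(0, len(cs.order), p.max_candidate_batch):
            batch = cs.order[lo: lo + p.max_candidate_batch]
            bpts = cands[batch]
            if s_geom is None:
                ok = np.ones(batch.size, dtype=bool)
            else:
                ok = collision.candidates_collision_free(
                    np.broadcast_to(tip_pt, bpts.shape), bpts,
                    np.full(batch.size, diameter), *s_geom,
                    multiplier=p.collision_multiplier)
            if ok.any():
                pick = int(batch[int(np.argmax(ok))])
                node = self.add_node(cands[pick], parent=tip,
                                     diameter=diameter, generation=generation,
                                     label="villous")
                self.stats["accepted"] += 1
                return node
        return None

    # -- generation loop ----------------------------------------------------
    def grow(self, stem_tip: int, start_generation: int = 1) -> list[int]:
        p = self.p
        tips = [stem_tip]
        for generation in range(start_generation, p.bg_v + 1):
            self._rebuild_tree()
            new_tips = []
            for tip in tips:
                if self.tip_terminated(tip):
                    self.stats["dead_tips"] += 1
                    continue
                parent = int(self.parent[tip])
                grandparent = int(self.parent[parent]) if parent != ROOT else ROOT
                gp_pt = self.coords[grandparent] if grandparent != ROOT \
                    else self.coords[parent]
                n_v = branch_plane_normal(self.coords[tip], self.coords[parent],
                                          gp_pt, self.rng)
                d_tip = self.node_diam[tip]
                side1 = float(self.rng.choice([-1.0, 1.0]))
                placed: list[int] = []
                for _ in range(p.retries):
                    a = max(float(p.a.sample(self.rng)), 0.05)
                    d1, d2 = murray_daughter_diameters(d_tip, p.k_v, a)
                    n1 = self.place_daughter(tip, d1, generation, n_v, side1, None)
                    if n1 is not None:
                        placed.append(n1)
                        sib = self.coords[n1] - self.coords[tip]
                        sib = sib / np.linalg.norm(sib)
                        n2 = self.place_daughter(tip, d2, generation, n_v,
                                                 -side1, sib)
                        if n2 is not None:
                            placed.append(n2)
                    if placed:
                        break
                if not placed:
                    self.stats["dead_tips"] += 1
                new_tips.extend(placed)
            logger.info("villous generation %d: %d segments, %d active tips",
                        generation, self.n_segs, len(new_tips))
            if not new_tips:
                break
            tips = new_tips
        return tips

    def build(self, meta: dict | None = None) -> VascularTree:
        n = self.n_nodes
        return VascularTree(
            node_coords=self.coords[:n].copy(),
            parent_index=self.parent[:n].copy(),
            segment_diameters=np.array(self.node_diam),
            segment_generation=np.array(self.node_gen, dtype=int),
            segment_label=np.array(self.node_label, dtype=object),
            meta=dict(meta or {}),
        )


def default_stem(domain: PlacentoneDomain, params: VillousGrowthParams,
                 rng=None):
    """Stem segment entering the placentone through the chorionic (+z) face."""
    rng = np.random.default_rng(rng)
    d_s = positive_sample(params.d_s, rng)
    t = domain.t_half
    start = np.array([0.0, 0.0, t])
    end = np.array([0.0, 0.0, t - STEM_LENGTH_MM])
    return start, end, d_s


def grow_villous_tree(domain, stem_root, params: VillousGrowthParams | None = None,
                      rng_seed=None) -> VascularTree:
    """Grow one villous tree from ``stem_root`` inside ``domain``.

    ``domain`` is a :class:`PlacentoneDomain` or a closed
    :class:`TriangulatedSurface`; ``stem_root`` is ``(start, end, diameter)``
    of the stem segment, whose end must lie inside the domain.
    """
    params = params or VillousGrowthParams()
    rng = np.random.default_rng(rng_seed)
    adapter = make_domain_adapter(domain)
    start, end, d_s = stem_root
    if not bool(np.atleast_1d(adapter.admissible(np.atleast_2d(end), 0.0))[0]):
        raise ValueError("stem root must lie inside the growth domain")
    grower = _VillousGrower(adapter, params, rng)
    root = grower.add_node(start)
    stem_tip = grower.add_node(end, parent=root, diameter=d_s,
                               generation=0, label="stem")
    grower.grow(stem_tip)
    return grower.build(meta={"stage": "villous",
                              "stats": dict(grower.stats),
                              "domain_volume_mm3": adapter.volume})


# ---------------------------------------------------------------------------
# whole-organ assembly
# ---------------------------------------------------------------------------

def grow_full_vasculature(shape: PlacentalShapeParams,
                          chorionic_params: ChorionicGrowthParams | None = None,
                          villous_params: VillousGrowthParams | None = None,
                          rng_seed=None, *, surface: TriangulatedSurface | None = None,
                          seed_density: float = 13.0,
                          include_villous: bool = True,
                          domain_n_lat: int = 40) -> VascularTree:
    """Assemble a full feto-placental vasculature.

    Pipeline: spheroid surface → chorionic plate → cord insertion →
    chorionic tree → intraplacental stems → one villous tree per stem grown
    inside the closed placental surface (basal plate = −z cap).  Returns the
    merged forest; with ``include_villous=False`` the output stops at the
    stems.
    """
    chorionic_params = chorionic_params or ChorionicGrowthParams()
    villous_params = villous_params or VillousGrowthParams()
    rng = np.random.default_rng(rng_seed)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    if surface is None:
        surface = _stage("surface", lambda: build_placental_surface(
            shape, target_seed_density=seed_density, refine=False))
    a_chor = chorionic_area(shape.r_maj, shape.r_min, shape.t_half)
    plate = _stage("plate", lambda: extract_chorionic_plate(surface, a_chor))
    insertion = _stage("insertion", lambda: locate_cord_insertion(
        plate, shape.CCI, shape.r_maj, shape.m_t, rng))
    chorionic_tree = _stage("chorionic", lambda: grow_chorionic_tree(
        plate, insertion, chorionic_params, rng))

    # coarse closed spheroid for inside tests (voxel parity on ~10^3 faces)
    a, b, c = shape.r_maj * CM, shape.r_min * CM, shape.t_half * CM
    verts, faces, _ = _latlong_spheroid(a, b, c, domain_n_lat)
    domain = TriangulatedSurface(verts, faces)
    inside = lambda pt: collision.point_in_mesh(domain, np.atleast_2d(pt))[0]

    stems_tree = _stage("stems", lambda: attach_stem_vessels(
        chorionic_tree, plate, rng, stem_diameter=villous_params.d_s,
        inside_test=inside))
    if not include_villous:
        stems_tree.meta.update(stage="chorionic+stems")
        return stems_tree

    adapter = _MeshAdapter(domain)
    grower = _VillousGrower(adapter, villous_params, rng)
    grower.absorb_tree(stems_tree)
    stem_tips = [int(s) for s in stems_tree.segments
                 if stems_tree.segment_label[s] == "stem"]
    for tip in stem_tips:
        grower.grow(tip)
    return grower.build(meta={"stage": "full",
                              "stats": dict(grower.stats),
                              "domain_volume_mm3": adapter.volume,
                              "n_stems": len(stem_tips)})
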