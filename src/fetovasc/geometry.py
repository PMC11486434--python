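"""Growth-domain geometry: placental spheroid, chorionic plate, placentone.

The idealized placenta is an oblate spheroid with semi-axes ``r_maj``,
``r_min`` (in-plane) and ``t_half`` (thickness axis, +z up).  The chorionic
plate is the +z cap of the spheroid, the basal plate the −z cap.  All
geometry is in mm internally; volumes cross the interface in cm³ and radii
in cm, matching how placental biometry is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

CM = 10.0  # mm per cm

#: Knud Thomsen exponent for the approximate ellipsoid surface area.
_THOMSEN_P = 1.6


class GeometryError(ValueError):
    pass


class InfeasibleInsertionError(GeometryError):
    """No plate vertex satisfies the cord-insertion constraints."""


@dataclass
class PlacentalShapeParams:
    """Placental size/shape and cord-insertion inputs.

    V in cm³, r_maj in cm, eccentricity E in [0, 1), cord centrality index
    CCI in [0, 1], minimum insertion-to-margin distance m_t in mm.
    """

    V: float
    r_maj: float
    E: float
    CCI: float
    m_t: float = 20.0

    def __post_init__(self) -> None:
        if self.V <= 0 or self.r_maj <= 0:
            raise GeometryError("V and r_maj must be positive")
        if not 0.0 <= self.E < 1.0:
            raise GeometryError("eccentricity must lie in [0, 1)")
        if not 0.0 <= self.CCI <= 1.0:
            raise GeometryError("CCI must lie in [0, 1]")
        if self.m_t < 0:
            raise GeometryError("m_t must be non-negative")

    @property
    def t_half(self) -> float:
        return placental_thickness(self.V, self.r_maj)

    @property
    def r_min(self) -> float:
        return minor_radius(self.r_maj, self.E)


@dataclass
class TriangulatedSurface:
    """Triangle mesh used as growth domain or seed source (mm units)."""

    vertices: np.ndarray
    faces: np.ndarray
    boundary_loop: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.boundary_loop = np.asarray(self.boundary_loop, dtype=int)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edge_counts(self):
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n = self.vertices.shape[0]
        code = edges[:, 0] * n + edges[:, 1]
        uniq_code, counts = np.unique(code, return_counts=True)
        uniq = np.stack([uniq_code // n, uniq_code % n], axis=1)
        return uniq, counts

    @property
    def is_closed(self) -> bool:
        _, counts = self.edge_counts()
        return bool(np.all(counts == 2))

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Enclosed volume (mm³) of a closed surface via the divergence theorem."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export(self, path) -> None:
        """Write OBJ/STL/PLY (format from the file extension)."""
        self.to_trimesh().export(path)

    @classmethod
    def load(cls, path) -> "TriangulatedSurface":
        mesh = trimesh.load_mesh(path, process=True)
        surf = cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))
        if not surf.is_closed:
            surf.boundary_loop = _ordered_boundary_loop(surf)
        return surf


def _ordered_boundary_loop(surface: TriangulatedSurface) -> np.ndarray:
    """Ordered vertex indices of the (single) boundary loop of an open patch."""
    uniq, counts = surface.edge_counts()
    boundary = uniq[counts == 1]
    if boundary.size == 0:
        return np.empty(0, dtype=int)
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    start = int(boundary[0, 0])
    loop = [start]
    prev = None
    while True:
        nbrs = nxt[loop[-1]]
        step = nbrs[0] if nbrs[0] != prev else nbrs[1]
        if step == start:
            break
        prev = loop[-1]
        loop.append(step)
        if len(loop) > len(nxt) + 1:
            raise GeometryError("patch has more than one boundary loop")
    if len(loop) != len(nxt):
        raise GeometryError("patch has more than one boundary loop")
    return np.array(loop, dtype=int)


# ---------------------------------------------------------------------------
# scalar shape relations
# ---------------------------------------------------------------------------

def placental_thickness(V: float, r_maj: float) -> float:
    """Half-thickness t_half = 3V / (4π r_maj²); cm in, cm out."""
    if V <= 0 or r_maj <= 0:
        raise GeometryError("V and r_maj must be positive")
    return 3.0 * V / (4.0 * math.pi * r_maj ** 2)

def minor_radius(r_maj: float, E: float) -> float:
    """Short in-plane radius r_min = sqrt(r_maj² (1 − E²))."""
    if not 0.0 <= E < 1.0:
        raise GeometryError("eccentricity must lie in [0, 1)")
    if r_maj <= 0:
        raise GeometryError("r_maj must be positive")
    return math.sqrt(r_maj ** 2 * (1.0 - E ** 2))

def chorionic_area(r_maj: float, r_min: float, t_half: float) -> float:
    """Half-ellipsoid surface area (Knud Thomsen approximation), cm² for cm in."""
    if min(r_maj, r_min, t_half) <= 0:
        raise GeometryError("all radii must be positive")
    p = _THOMSEN_P
    return 2.0 * math.pi * (((r_maj * r_min) ** p + (r_maj * t_half) ** p
                             + (r_min * t_half) ** p) / 3.0) ** (1.0 / p)


# ---------------------------------------------------------------------------
# spheroid mesh
# ---------------------------------------------------------------------------

def _latlong_spheroid(a: float, b: float, c: float, n_lat: int):
    """Closed lat-long quadrangulation split into triangles.

    Returns (vertices, faces, face_row) where face_row labels each face with
    its latitude band, 0 at the +z pole increasing towards −z.
    """
    n_lon = 2 * n_lat
    thetas = np.pi * np.arange(1, n_lat) / n_lat
    phis = 2.0 * np.pi * np.arange(n_lon) / n_lon
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    ring = np.stack([a * np.sin(tt) * np.cos(pp),
                     b * np.sin(tt) * np.sin(pp),
                     c * np.cos(tt)], axis=-1).reshape(-1, 3)
    verts = np.vstack([[0.0, 0.0, c], ring, [0.0, 0.0, -c]])
    top, bottom = 0, verts.shape[0] - 1

    j = np.arange(n_lon)
    jn = (j + 1) % n_lon

    def vid(i, jj):  # ring row i (0-based), longitude jj (array)
        return 1 + i * n_lon + jj

    face_blocks, row_blocks = [], []
    cap_top = np.stack([np.full(n_lon, top), vid(0, j), vid(0, jn)], axis=1)
    face_blocks.append(cap_top)
    row_blocks.append(np.zeros(n_lon, dtype=np.int64))
    for i in range(n_lat - 2):
        v00, v01 = vid(i, j), vid(i, jn)
        v10, v11 = vid(i + 1, j), vid(i + 1, jn)
        face_blocks.append(np.stack([v00, v10, v11], axis=1))
        face_blocks.append(np.stack([v00, v11, v01], axis=1))
        row_blocks.append(np.full(2 * n_lon, i + 1, dtype=np.int64))
    cap_bot = np.stack([np.full(n_lon, bottom), vid(n_lat - 2, jn), vid(n_lat - 2, j)], axis=1)
    face_blocks.append(cap_bot)
    row_blocks.append(np.full(n_lon, n_lat - 1, dtype=np.int64))
    return verts, np.vstack(face_blocks).astype(np.int64), np.concatenate(row_blocks)


def _subdivide(vertices, faces, face_attr=None, project=None):
    """One midpoint (1→4) subdivision; optionally project new vertices."""
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    nv = vertices.shape[0]
    code = edges[:, 0] * nv + edges[:, 1]
    uniq_code, inverse = np.unique(code, return_inverse=True)
    uniq = np.stack([uniq_code // nv, uniq_code % nv], axis=1)
    mids = 0.5 * (vertices[uniq[:, 0]] + vertices[uniq[:, 1]])
    if project is not None:
        mids = project(mids)
    mid_idx = vertices.shape[0] + np.arange(uniq.shape[0])
    m01, m12, m20 = mid_idx[inverse.reshape(-1, 3)].T
    f0, f1, f2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.concatenate([
        np.stack([f0, m01, m20], axis=1),
        np.stack([f1, m12, m01], axis=1),
        np.stack([f2, m20, m12], axis=1),
        np.stack([m01, m12, m20], axis=1),
    ])
    new_attr = None if face_attr is None else np.tile(face_attr, 4)
    return np.vstack([vertices, mids]), new_faces, new_attr


def _spheroid_projector(a: float, b: float, c: float):
    def project(points):
        q = ((points[:, 0] / a) ** 2 + (points[:, 1] / b) ** 2
             + (points[:, 2] / c) ** 2)
        return points / np.sqrt(q)[:, None]
    return project


def build_placental_surface(params: PlacentalShapeParams,
                            target_seed_density: float = 13.0,
                            max_vertices: int = 4_000_000,
                            refine: bool = True) -> TriangulatedSurface:
    """Watertight oblate-spheroid mesh with the requested seed density.

    ``target_seed_density`` is in seed vertices per mm² of surface; the
    lat-long base mesh is chosen so a single midpoint subdivision lands at or
    just above the target, and subdivision repeats until the density is met.
    Latitude-band labels are carried through subdivision so whole "rows" of
    elements can later be peeled off to isolate the chorionic plate.
    """
    a, b, c = params.r_maj * CM, params.r_min * CM, params.t_half * CM
    p = _THOMSEN_P
    area = 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1 / p)
    if target_seed_density * area > max_vertices:
        raise MemoryError("requested seed density exceeds the vertex budget")
    # base density ~ target/3 so one 1→4 subdivision overshoots only mildly
    n_lat = max(8, int(math.ceil(math.sqrt(target_seed_density * area / 6.0))))
    verts, faces, rows = _latlong_spheroid(a, b, c, n_lat)
    project = _spheroid_projector(a, b, c)
    if refine:
        while verts.shape[0] / area < target_seed_density:
            if 4 * verts.shape[0] > max_vertices:
                raise MemoryError("seed-density refinement exceeds the vertex budget")
            verts, faces, rows = _subdivide(verts, faces, rows, project)
    surf = TriangulatedSurface(verts, faces)
    surf.meta.update(face_row=rows, n_rows=n_lat, semi_axes=(a, b, c),
                     seed_density=verts.shape[0] / area,
                     shape_params=params,
                     # with refine=False the plate is refined after row
                     # extraction instead of the whole closed surface
                     deferred_density=None if refine else target_seed_density,
                     max_vertices=max_vertices)
    return surf


def extract_chorionic_plate(surface: TriangulatedSurface, A_chor: float) -> TriangulatedSurface:
    """Isolate the +z cap whose area best matches ``A_chor`` (cm²).

    Whole latitude rows of elements are removed from the −z pole upward until
    the remaining cap area is the closest achievable to the requested
    chorionic area; the result is an open patch with one boundary loop.
    """
    if "face_row" not in surface.meta:
        raise GeometryError("surface lacks latitude-row labels")
    target = A_chor * CM ** 2  # mm²
    areas = surface.face_areas()
    rows = surface.meta["face_row"]
    n_rows = int(surface.meta["n_rows"])
    row_areas = np.bincount(rows, weights=areas, minlength=n_rows)
    if target >= row_areas.sum():
        raise GeometryError("A_chor must be smaller than the closed-surface area")
    # cumulative area of caps keeping rows 0..r
    cumulative = np.cumsum(row_areas)
    best_r = int(np.argmin(np.abs(cumulative - target)))
    keep = rows <= best_r
    faces = surface.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(surface.vertices.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    patch = TriangulatedSurface(surface.vertices[used], remap[faces])
    patch.meta.update(face_row=rows[keep], target_area_mm2=target,
                      achieved_area_mm2=float(cumulative[best_r]),
                      semi_axes=surface.meta.get("semi_axes"),
                      shape_params=surface.meta.get("shape_params"))
    deferred = surface.meta.get("deferred_density")
    if deferred is not None and surface.meta.get("semi_axes") is not None:
        project = _spheroid_projector(*surface.meta["semi_axes"])
        v, f, fr = patch.vertices, patch.faces, patch.meta["face_row"]
        area = patch.area()
        max_vertices = surface.meta.get("max_vertices", 4_000_000)
        while v.shape[0] / area < deferred:
            if 4 * v.shape[0] > max_vertices:
                raise MemoryError("seed-density refinement exceeds the vertex budget")
            v, f, fr = _subdivide(v, f, fr, project)
        patch = TriangulatedSurface(v, f)
        patch.meta.update(face_row=fr, target_area_mm2=target,
                          achieved_area_mm2=float(cumulative[best_r]),
                          semi_axes=surface.meta.get("semi_axes"),
                          shape_params=surface.meta.get("shape_params"),
                          seed_density=v.shape[0] / area)
    patch.boundary_loop = _ordered_boundary_loop(patch)
    return patch


def locate_cord_insertion(plate: TriangulatedSurface, CCI: float, r_maj: float,
                          m_t: float, rng: np.random.Generator | None = None) -> int:
    """Vertex index for the umbilical cord insertion.

    The target in-plane distance from the plate centroid is d_c = CCI·r_maj
    (r_maj in cm, result in mm); candidate vertices must lie at least ``m_t``
    mm from the plate boundary, and the azimuth among near-equidistant
    candidates is a seeded random choice.
    """
    rng = np.random.default_rng(rng)
    d_c = CCI * r_maj * CM
    centroid = plate.centroid
    inplane = np.linalg.norm(plate.vertices[:, :2] - centroid[None, :2], axis=1)
    edge = _median_edge_length(plate)
    btree = cKDTree(plate.vertices[plate.boundary_loop]) \
        if plate.boundary_loop.size else None

    def eligible_pool(window: float):
        near = np.flatnonzero(np.abs(inplane - d_c) <= window)
        if near.size == 0 or btree is None:
            return near
        b_dist, _ = btree.query(plate.vertices[near])
        return near[b_dist >= m_t]

    # widen the distance window until margin-feasible vertices appear
    window = max(2.0 * edge, 0.5)
    pool = eligible_pool(window)
    while pool.size == 0 and window < 2.0 * inplane.max() + d_c:
        window *= 2.0
        pool = eligible_pool(window)
    if pool.size == 0:
        raise InfeasibleInsertionError(
            f"no plate vertex lies ≥ {m_t} mm from the boundary")
    err = np.abs(inplane[pool] - d_c)
    # tolerance of one local edge length keeps all azimuths in play
    tol = err.min() + edge
    return int(rng.choice(pool[err <= tol]))


def _median_edge_length(surface: TriangulatedSurface) -> float:
    f = surface.faces[:: max(1, surface.faces.shape[0] // 2048)]
    v = surface.vertices
    e = np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1)
    return float(np.median(e))


# ---------------------------------------------------------------------------
# placentone
# ---------------------------------------------------------------------------

@dataclass
class PlacentoneDomain:
    """Cuboid functional-lobule domain with a villous-free central cavity.

    The cuboid spans x, y ∈ [−X_p/2, X_p/2] and z ∈ [−t_half, t_half].  The
    cavity is a semi-ellipsoid of radius ``CC_r`` and height ``CC_h`` rising
    from the centre of the basal (−z) face, where the spiral artery opens;
    the stem vessel enters through the chorionic (+z) face.
    """

    X_p: float
    Y_p: float
    thickness: float
    CC_r: float
    CC_h: float
    surface: TriangulatedSurface

    @property
    def t_half(self) -> float:
        return self.thickness / 2.0

    @property
    def volume(self) -> float:
        return self.X_p * self.Y_p * self.thickness

    def cavity_test(self, points: np.ndarray) -> np.ndarray:
        """True for points inside the central cavity semi-ellipsoid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        zc = p[:, 2] + self.t_half
        q = ((p[:, 0] / self.CC_r) ** 2 + (p[:, 1] / self.CC_r) ** 2
             + (zc / self.CC_h) ** 2)
        inside = (q <= 1.0) & (zc >= 0.0)
        return inside if np.asarray(points).ndim > 1 else bool(inside[0])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True for points inside the cuboid (and outside any margin shell)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ok = ((np.abs(p[:, 0]) <= self.X_p / 2 - margin)
              & (np.abs(p[:, 1]) <= self.Y_p / 2 - margin)
              & (np.abs(p[:, 2]) <= self.t_half - margin))
        return ok if np.asarray(points).ndim > 1 else bool(ok[0])

    def basal_vertices(self) -> np.ndarray:
        v = self.surface.vertices
        return v[np.isclose(v[:, 2], -self.t_half)]


def _box_mesh(X: float, Y: float, Z: float, pitch: float) -> TriangulatedSurface:
    """Closed triangulated box centred at the origin with ~``pitch`` mm facets."""
    nx = max(2, int(round(X / pitch)) + 1)
    ny = max(2, int(round(Y / pitch)) + 1)
    nz = max(2, int(round(Z / pitch)) + 1)
    xs = np.linspace(-X / 2, X / 2, nx)
    ys = np.linspace(-Y / 2, Y / 2, ny)
    zs = np.linspace(-Z / 2, Z / 2, nz)
    verts: list = []
    faces: list = []
    index: dict = {}

    def vid(p):
        key = (round(p[0], 9), round(p[1], 9), round(p[2], 9))
        if key not in index:
            index[key] = len(verts)
            verts.append(p)
        return index[key]

    def grid_face(us, vs, fixed, axis, flip):
        for i in range(len(us) - 1):
            for j in range(len(vs) - 1):
                quad = []
                for du, dv in ((0, 0), (1, 0), (1, 1), (0, 1)):
                    uv = [0.0, 0.0, 0.0]
                    uv[axis] = fixed
                    uv[(axis + 1) % 3] = us[i + du]
                    uv[(axis + 2) % 3] = vs[j + dv]
                    quad.append(vid(tuple(uv)))
                t1, t2 = [quad[0], quad[1], quad[2]], [quad[0], quad[2], quad[3]]
                if flip:
                    t1, t2 = t1[::-1], t2[::-1]
                faces.extend([t1, t2])

    grid_face(ys, zs, -X / 2, 0, True)
    grid_face(ys, zs, X / 2, 0, False)
    grid_face(zs, xs, -Y / 2, 1, True)
    grid_face(zs, xs, Y / 2, 1, False)
    grid_face(xs, ys, -Z / 2, 2, True)
    grid_face(xs, ys, Z / 2, 2, False)
    return TriangulatedSurface(np.array(verts), np.array(faces, dtype=np.int64))


def build_placentone(V: float, thickness: float, n_p: int,
                     CC_r: float, CC_h: float,
                     mesh_pitch: float = 1.5) -> PlacentoneDomain:
    """Cuboid placentone domain for one villous tree.

    ``V`` is the whole-placenta volume in cm³, ``thickness`` the full
    placental thickness 2·t_half in mm and ``n_p`` the number of placentones;
    the square cross-section side is X_p = sqrt(V / (thickness · n_p)).
    """
    if min(V, thickness, n_p, CC_r, CC_h) <= 0:
        raise GeometryError("all placentone inputs must be positive")
    X_p = math.sqrt(V * CM ** 3 / (thickness * n_p))
    if CC_r >= X_p / 2:
        raise GeometryError("cavity radius exceeds half the cross-section")
    if CC_h >= thickness:
        raise GeometryError("cavity height exceeds the placentone thickness")
    surface = _box_mesh(X_p, X_p, thickness, mesh_pitch)
    return PlacentoneDomain(X_p=X_p, Y_p=X_p, thickness=thickness,
                            CC_r=CC_r, CC_h=CC_h, surface=surface)
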