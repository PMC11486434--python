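"""Intersection machinery for vessel growth.

Candidate branches are screened in four stages, mirroring how the generative
algorithm keeps vessels apart while reserving space for the (un-modelled)
venous counterparts:

1. point-vs-mesh containment (voxelized ray-crossing parity);
2. a spherical region of interest (ROI) of radius (3/5)·l around the
   candidate midpoint pre-filters which existing segments are checked;
3. an infinite-cylinder clearance test: line-to-line distance above
   ``multiplier·(d_i + d_j)`` fast-accepts the pair, the multiplier (default
   7/4) bundling the arterial contact radius (d_i+d_j)/2 with two venous
   radii of (3/4)·(d_i+d_j) and a safety margin;
4. a finite-cylinder convex collision test (GJK on polygonal cylinder
   hulls) decides pairs that fail the clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriangulatedSurface
from .trees import VascularTree

#: Default infinite-cylinder clearance multiplier: (1/2 + 3/4)·(d_i+d_j)
#: is the venous-augmented contact floor; 7/4 strictifies it.
VENOUS_MULTIPLIER = 7.0 / 4.0
ROI_RADIUS_FACTOR = 3.0 / 5.0
_EPS = 1e-12


class CollisionError(ValueError):
    pass


@dataclass
class SegmentCylinder:
    """A finite vessel segment as a circular cylinder (mm)."""

    start: np.ndarray
    end: np.ndarray
    diameter: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.diameter <= 0:
            raise CollisionError("cylinder diameter must be positive")
        if np.allclose(self.start, self.end):
            raise CollisionError("degenerate (zero-length) cylinder")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


# ---------------------------------------------------------------------------
# point-in-mesh via voxelized ray parity
# ---------------------------------------------------------------------------

class VoxelizedMesh:
    """Column voxelization of a watertight mesh for fast inside tests.

    Triangles are rasterized onto a regular (x, y) pixel grid; for every
    pixel column the z-values where the surface crosses the column ray are
    stored sorted.  A point is inside when the number of crossings above it
    is odd — the ray-crossing parity rule on the voxelized surface.
    """

    def __init__(self, surface: TriangulatedSurface, pitch: float | None = None,
                 pitch_fraction: float = 1.0 / 50.0, max_columns: int = 4_000_000):
        if not surface.is_closed:
            raise CollisionError("point_in_mesh requires a watertight mesh")
        v, f = surface.vertices, surface.faces
        lo, hi = v.min(axis=0), v.max(axis=0)
        if pitch is None:
            pitch = max(float((hi - lo).min()) * pitch_fraction, 1e-6)
        nx = int(np.ceil((hi[0] - lo[0]) / pitch)) + 2
        ny = int(np.ceil((hi[1] - lo[1]) / pitch)) + 2
        while nx * ny > max_columns:
            pitch *= 2.0
            nx = int(np.ceil((hi[0] - lo[0]) / pitch)) + 2
            ny = int(np.ceil((hi[1] - lo[1]) / pitch)) + 2
        # half-pixel offset keeps column rays off mesh vertices/edges
        self.origin = lo[:2] - 0.5 * pitch * np.array([0.61803398875, 0.5411961])
        self.pitch = float(pitch)
        self.shape = (nx, ny)
        cols: dict[int, list[float]] = {}
        tri = v[f]  # (F, 3, 3)
        for a, b, c in tri:
            det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            if abs(det) < _EPS:
                continue  # edge-on in projection
            xmin = min(a[0], b[0], c[0]); xmax = max(a[0], b[0], c[0])
            ymin = min(a[1], b[1], c[1]); ymax = max(a[1], b[1], c[1])
            i0 = int(np.floor((xmin - self.origin[0]) / pitch))
            i1 = int(np.floor((xmax - self.origin[0]) / pitch)) + 1
            j0 = int(np.floor((ymin - self.origin[1]) / pitch))
            j1 = int(np.floor((ymax - self.origin[1]) / pitch)) + 1
            xs = self.origin[0] + pitch * (np.arange(i0, i1) + 0.5)
            ys = self.origin[1] + pitch * (np.arange(j0, j1) + 0.5)
            if xs.size == 0 or ys.size == 0:
                continue
            px, py = np.meshgrid(xs, ys, indexing="ij")
            lam2 = ((px - a[0]) * (c[1] - a[1]) - (py - a[1]) * (c[0] - a[0])) / det
            lam3 = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) / det
            lam1 = 1.0 - lam2 - lam3
            inside = (lam1 >= 0) & (lam2 >= 0) & (lam3 >= 0)
            if not inside.any():
                continue
            zval = lam1 * a[2] + lam2 * b[2] + lam3 * c[2]
            ii, jj = np.nonzero(inside)
            keys = (ii + i0) * ny + (jj + j0)
            for key, z in zip(keys, zval[inside]):
                cols.setdefault(int(key), []).append(float(z))
        # CSR layout of sorted crossings per column
        self._ptr = np.zeros(nx * ny + 1, dtype=np.int64)
        zs: list[float] = []
        for key in sorted(cols):
            self._ptr[key + 1] = len(cols[key])
        np.cumsum(self._ptr, out=self._ptr)
        flat = np.zeros(self._ptr[-1])
        for key, zlist in cols.items():
            zlist = sorted(zlist)
            if len(zlist) % 2 == 1:
                zlist = zlist[:-1]  # numerical sliver; drop unmatched crossing
            flat[self._ptr[key]: self._ptr[key] + len(zlist)] = zlist
        self._z = flat
        del zs

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ij = np.floor((p[:, :2] - self.origin[None, :]) / self.pitch).astype(np.int64)
        nx, ny = self.shape
        valid = (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
        out = np.zeros(p.shape[0], dtype=bool)
        keys = ij[valid, 0] * ny + ij[valid, 1]
        res = np.zeros(keys.size, dtype=bool)
        for n, (key, z) in enumerate(zip(keys, p[valid, 2])):
            lo, hi = self._ptr[key], self._ptr[key + 1]
            crossings_above = hi - lo - np.searchsorted(self._z[lo:hi], z)
            res[n] = (crossings_above % 2) == 1
        out[valid] = res
        return out if np.asarray(points).ndim > 1 else out


def point_in_mesh(mesh: TriangulatedSurface, points: np.ndarray,
                  pitch: float | None = None):
    """True iff each point lies inside the watertight ``mesh``.

    The voxelization is cached on the mesh, keyed by pitch.
    """
    key = f"_voxelization_{pitch}"
    vox = mesh.meta.get(key)
    if vox is None:
        vox = VoxelizedMesh(mesh, pitch=pitch)
        mesh.meta[key] = vox
    result = vox.contains(points)
    if np.asarray(points).ndim == 1:
        return bool(np.atleast_1d(result)[0])
    return result


# ---------------------------------------------------------------------------
# ROI pre-filter
# ---------------------------------------------------------------------------

def roi_filter(tree: VascularTree, candidate: SegmentCylinder) -> np.ndarray:
    """Tree segments with an endpoint within (3/5)·l of the candidate midpoint."""
    radius = ROI_RADIUS_FACTOR * candidate.length
    segs = tree.segments
    if segs.size == 0:
        return segs
    mid = candidate.midpoint
    child_pts = tree.node_coords[segs]
    parent_pts = tree.node_coords[tree.parent_index[segs]]
    inside = ((np.linalg.norm(child_pts - mid, axis=1) <= radius)
              | (np.linalg.norm(parent_pts - mid, axis=1) <= radius))
    return segs[inside]


# ---------------------------------------------------------------------------
# infinite-cylinder clearance
# ---------------------------------------------------------------------------

def line_line_distance(a: SegmentCylinder, b: SegmentCylinder) -> float:
    """Minimum distance between the two segments' supporting lines."""
    return float(lines_distance_matrix(a.start[None], a.direction[None],
                                       b.start[None], b.direction[None])[0, 0])


def lines_distance_matrix(starts_a, dirs_a, starts_b, dirs_b) -> np.ndarray:
    """Pairwise infinite-line distances, shape ``(A, B)``."""
    sa = np.asarray(starts_a)[:, None, :]
    ua = np.asarray(dirs_a)[:, None, :]
    sb = np.asarray(starts_b)[None, :, :]
    ub = np.asarray(dirs_b)[None, :, :]
    cross = np.cross(ua, ub)
    ncross = np.linalg.norm(cross, axis=-1)
    w = sb - sa
    skew = np.abs(np.einsum("abi,abi->ab", cross, w)) / np.where(ncross > _EPS,
                                                                 ncross, 1.0)
    # parallel fallback: distance from line a to the point S_b
    para = (np.linalg.norm(np.cross(np.broadcast_to(ua, w.shape), w), axis=-1)
            / np.linalg.norm(np.broadcast_to(ua, w.shape), axis=-1))
    return np.where(ncross > _EPS, skew, para)


def venous_clearance_ok(a: SegmentCylinder, b: SegmentCylinder,
                        multiplier: float = VENOUS_MULTIPLIER) -> bool:
    """True iff the line-line distance exceeds ``multiplier·(d_a + d_b)``."""
    return line_line_distance(a, b) > multiplier * (a.diameter + b.diameter)


# ---------------------------------------------------------------------------
# finite-segment distance (screen for the convex test)
# ---------------------------------------------------------------------------

def segment_distance_matrix(p0, p1, q0, q1):
    """Pairwise segment-segment minimum distances and interior flags.

    Returns (dist, interior) of shape (A, B): ``interior`` marks pairs whose
    closest approach lies strictly inside both segments (for those the
    segment distance equals the axis distance of the common perpendicular).
    """
    p0 = np.asarray(p0)[:, None, :]; p1 = np.asarray(p1)[:, None, :]
    q0 = np.asarray(q0)[None, :, :]; q1 = np.asarray(q1)[None, :, :]
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = np.einsum("abi,abi->ab", *np.broadcast_arrays(d1, d1))
    e = np.einsum("abi,abi->ab", *np.broadcast_arrays(d2, d2))
    f = np.einsum("abi,abi->ab", *np.broadcast_arrays(d2, r))
    c = np.einsum("abi,abi->ab", *np.broadcast_arrays(d1, r))
    b = np.einsum("abi,abi->ab", *np.broadcast_arrays(d1, d2))
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > _EPS, (b * f - c * e) / denom, 0.0)
    s_unclamped = s.copy()
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(e > _EPS, (b * s + f) / e, 0.0)
    t_unclamped = t.copy()
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for clamped t
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where((t_unclamped != t) & (a > _EPS),
                     np.clip((t * b - c) / np.where(a > _EPS, a, 1.0), 0.0, 1.0), s)
    cp = p0 + s[..., None] * d1
    cq = q0 + t[..., None] * d2
    dist = np.linalg.norm(cp - cq, axis=-1)
    margin = 1e-9
    interior = ((s_unclamped > margin) & (s_unclamped < 1 - margin)
                & (t_unclamped > margin) & (t_unclamped < 1 - margin)
                & (denom > _EPS))
    return dist, interior


# ---------------------------------------------------------------------------
# GJK convex collision for finite cylinders
# ---------------------------------------------------------------------------

def _cylinder_vertices(cyl: SegmentCylinder, n_facets: int = 16) -> np.ndarray:
    u = cyl.direction
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    r = cyl.diameter / 2.0
    ang = 2.0 * np.pi * np.arange(n_facets) / n_facets
    rim = r * (np.cos(ang)[:, None] * e1[None] + np.sin(ang)[:, None] * e2[None])
    return np.vstack([cyl.start[None] + rim, cyl.end[None] + rim])


def _cross3(a, b):
    # manual 3-vector cross: much cheaper than np.cross for scalars
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _gjk_intersects(va: np.ndarray, vb: np.ndarray, tol: float = 1e-9,
                    max_iter: int = 64) -> bool:
    """GJK boolean intersection of two convex vertex clouds.

    Contact (zero distance) counts as intersection; on failure to converge
    the answer is the conservative ``True``.
    """

    def support(d):
        return va[int(np.argmax(va @ d))] - vb[int(np.argmax(-(vb @ d)))]

    d = va.mean(axis=0) - vb.mean(axis=0)
    if np.linalg.norm(d) < tol:
        d = np.array([1.0, 0.0, 0.0])
    simplex = [support(d)]
    d = -simplex[0]
    for _ in range(max_iter):
        if np.linalg.norm(d) < tol:
            return True  # origin on simplex boundary: contact
        a = support(d)
        if a @ d < tol:
            # cannot pass the origin: separated unless touching
            return bool(a @ d > -1e-8 and abs(a @ d) <= tol)
        simplex.append(a)
        contains, simplex, d = _nearest_simplex(simplex)
        if contains:
            return True
    return True


def _nearest_simplex(simplex):
    """Standard GJK simplex reduction towards the origin."""
    if len(simplex) == 2:
        b, a = simplex
        ab = b - a
        if ab @ (-a) > 0:
            d = _cross3(_cross3(ab, -a), ab)
            if np.linalg.norm(d) < 1e-14:  # origin on the segment line
                return True, simplex, d
            return False, [b, a], d
        return False, [a], -a
    if len(simplex) == 3:
        c, b, a = simplex
        ab, ac = b - a, c - a
        abc = _cross3(ab, ac)
        if _cross3(abc, ac) @ (-a) > 0:
            if ac @ (-a) > 0:
                return False, [c, a], _cross3(_cross3(ac, -a), ac)
            simplex = [b, a]
            return _nearest_simplex(simplex)
        if _cross3(ab, abc) @ (-a) > 0:
            simplex = [b, a]
            return _nearest_simplex(simplex)
        if abc @ (-a) > 0:
            return False, [c, b, a], abc
        return False, [b, c, a], -abc
    # tetrahedron
    d_, c, b, a = simplex
    ab, ac, ad = b - a, c - a, d_ - a
    abc = _cross3(ab, ac)
    acd = _cross3(ac, ad)
    adb = _cross3(ad, ab)
    ao = -a
    if abc @ ad > 0:
        abc = -abc
    if acd @ ab > 0:
        acd = -acd
    if adb @ ac > 0:
        adb = -adb
    if abc @ ao > 0:
        return _nearest_simplex([c, b, a])
    if acd @ ao > 0:
        return _nearest_simplex([d_, c, a])
    if adb @ ao > 0:
        return _nearest_simplex([d_, b, a])
    return True, simplex, np.zeros(3)


def finite_cylinder_collision(a: SegmentCylinder, b: SegmentCylinder,
                              n_facets: int = 16) -> bool:
    """True iff the convex polygonal hulls of the two cylinders intersect.

    Contact counts as collision; callers exempt parent/child and sibling
    pairs that necessarily share a node.
    """
    if n_facets < 3:
        raise CollisionError("need at least 3 circumferential facets")
    return _gjk_intersects(_cylinder_vertices(a, n_facets),
                           _cylinder_vertices(b, n_facets))


# ---------------------------------------------------------------------------
# vectorized acceptance pipeline used by the growth loops
# ---------------------------------------------------------------------------

def candidates_collision_free(cand_starts, cand_ends, cand_diams,
                              seg_starts, seg_ends, seg_diams,
                              exempt=None,
                              multiplier: float = VENOUS_MULTIPLIER) -> np.ndarray:
    """Per-candidate boolean: passes the branch-intersection pipeline.

    Each candidate cylinder is tested against the supplied segments: segments
    outside the candidate's spherical ROI are skipped; the remaining pairs
    are fast-accepted by the venous clearance, else screened by an exact
    segment-distance test and finally (ambiguous end-cap geometry only)
    decided by GJK on the finite cylinders.  ``exempt`` is an optional
    ``(C, S)`` mask of pairs excluded from testing (shared-node neighbours).
    """
    cand_starts = np.atleast_2d(cand_starts)
    cand_ends = np.atleast_2d(cand_ends)
    cand_diams = np.atleast_1d(cand_diams)
    seg_starts = np.atleast_2d(seg_starts)
    seg_ends = np.atleast_2d(seg_ends)
    seg_diams = np.atleast_1d(seg_diams)
    n_c = cand_starts.shape[0]
    if seg_starts.shape[0] == 0:
        return np.ones(n_c, dtype=bool)

    lens = np.linalg.norm(cand_ends - cand_starts, axis=1)
    mids = 0.5 * (cand_starts + cand_ends)
    dsum = cand_diams[:, None] + seg_diams[None, :]
    # ROI membership by exact segment-to-midpoint distance, padded by the
    # contact radius: an endpoint-only test lets a long segment slice
    # through a short candidate's ROI undetected
    roi_r = ROI_RADIUS_FACTOR * lens[:, None] + dsum / 2.0
    seg_vec = seg_ends - seg_starts
    seg_len2 = np.einsum("ij,ij->i", seg_vec, seg_vec)
    rel = mids[:, None, :] - seg_starts[None, :, :]
    t = np.einsum("abi,bi->ab", rel, seg_vec) / np.where(seg_len2 > _EPS,
                                                         seg_len2, 1.0)
    closest = seg_starts[None, :, :] + np.clip(t, 0.0, 1.0)[..., None] * seg_vec[None]
    in_roi = np.linalg.norm(mids[:, None, :] - closest, axis=-1) <= roi_r
    if exempt is not None:
        in_roi &= ~exempt
    ok = np.ones(n_c, dtype=bool)
    if not in_roi.any():
        return ok

    dirs_c = (cand_ends - cand_starts) / lens[:, None]
    seg_lens = np.sqrt(seg_len2)
    dirs_s = seg_vec / np.where(seg_lens > _EPS, seg_lens, 1.0)[:, None]
    dl = lines_distance_matrix(cand_starts, dirs_c, seg_starts, dirs_s)
    needs_finite = in_roi & (dl <= multiplier * dsum)
    if not needs_finite.any():
        return ok
    dist, interior = segment_distance_matrix(cand_starts, cand_ends,
                                             seg_starts, seg_ends)
    contact = dsum / 2.0
    colliding = needs_finite & (dist < contact) & interior
    ok &= ~colliding.any(axis=1)
    ambiguous = needs_finite & (dist < contact) & ~interior
    for ci, si in zip(*np.nonzero(ambiguous)):
        if not ok[ci]:
            continue
        a = SegmentCylinder(cand_starts[ci], cand_ends[ci], cand_diams[ci])
        b = SegmentCylinder(seg_starts[si], seg_ends[si], seg_diams[si])
        if finite_cylinder_collision(a, b):
            ok[ci] = False
    return ok


def audit_tree_clearances(tree: VascularTree,
                          multiplier: float = VENOUS_MULTIPLIER) -> int:
    """Post-hoc audit: number of non-adjacent segment pairs in actual collision.

    A pair violates the contract when the finite cylinders overlap (beyond
    contact at a shared node); pairs respecting the venous clearance are
    never violations.  Returns the violation count (0 for a valid tree).
    """
    segs = tree.segments
    if segs.size < 2:
        return 0
    starts = tree.node_coords[tree.parent_index[segs]]
    ends = tree.node_coords[segs]
    diams = tree.segment_diameters[segs]
    par = tree.parent_index
    violations = 0
    # adjacency: shared node between two segments
    nodes = np.stack([par[segs], segs], axis=1)
    for i in range(segs.size):
        shared = (np.isin(nodes[i + 1:], nodes[i]).any(axis=1))
        mask = ~shared
        if not mask.any():
            continue
        free = candidates_collision_free(
            starts[i][None], ends[i][None], diams[i][None],
            starts[i + 1:][mask], ends[i + 1:][mask], diams[i + 1:][mask],
            multiplier=multiplier)
        if not free[0]:
            violations += 1
    return violations
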