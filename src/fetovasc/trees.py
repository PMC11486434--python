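"""Vascular tree data model and per-tree morphometric computations.

A vascular tree is stored in the classic morphology-array form: node
coordinates ``C_1..N`` (mm), a per-node parent index encoding the adjacency
matrix, and one diameter per segment, a segment being the connection between
a non-root node and its parent.  Trees are forests of rooted, at most
bifurcating trees: every non-root node has exactly one parent and every node
has at most two children (a single child is a monopodial continuation).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

ROOT = -1

#: SWC structure-type codes for the vessel classes handled here.
SWC_TYPE_CODES = {"umbilical": 2, "chorionic": 3, "stem": 4, "villous": 5}
SWC_TYPE_NAMES = {v: k for k, v in SWC_TYPE_CODES.items()}


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid arguments."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class VascularTree:
    """A forest of rooted bifurcating vessel trees.

    Parameters
    ----------
    node_coords:
        ``(N, 3)`` float array of node positions in mm.
    parent_index:
        ``(N,)`` int array; ``parent_index[i]`` is the parent node of node
        ``i`` or ``ROOT`` (−1) for root nodes.  Node ``i`` together with its
        parent defines segment ``i``; per-segment arrays below are indexed by
        child node and carry NaN / placeholder values at root positions.
    segment_diameters:
        ``(N,)`` float array, mm; NaN at roots.
    segment_generation:
        ``(N,)`` int array of branching-generation indices; −1 at roots.
    segment_label:
        ``(N,)`` array of vessel-class labels (``umbilical``, ``chorionic``,
        ``stem``, ``villous``); empty string at roots.
    """

    node_coords: np.ndarray
    parent_index: np.ndarray
    segment_diameters: np.ndarray
    segment_generation: np.ndarray
    segment_label: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.segment_diameters = np.asarray(self.segment_diameters, dtype=float)
        self.segment_generation = np.asarray(self.segment_generation, dtype=int)
        self.segment_label = np.asarray(self.segment_label, dtype=object)

    # -- basic structure ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent_index == ROOT)

    @property
    def segments(self) -> np.ndarray:
        """Indices of non-root nodes; segment ``i`` joins node ``i`` to its parent."""
        return np.flatnonzero(self.parent_index != ROOT)

    @property
    def n_segments(self) -> int:
        return self.n_nodes - self.roots.size

    def child_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent_index[self.segments], 1)
        return counts

    def terminal_segments(self) -> np.ndarray:
        """Segments whose child node has no children of its own."""
        counts = self.child_counts()
        segs = self.segments
        return segs[counts[segs] == 0]

    def segment_lengths(self) -> np.ndarray:
        """Per-node segment lengths in mm (NaN at roots)."""
        lengths = np.full(self.n_nodes, np.nan)
        segs = self.segments
        vec = self.node_coords[segs] - self.node_coords[self.parent_index[segs]]
        lengths[segs] = np.linalg.norm(vec, axis=1)
        return lengths

    def validate(self) -> None:
        """Check the forest invariants; raise :class:`TreeError` on violation."""
        if self.n_nodes == 0:
            raise TreeError("empty tree")
        n = self.n_nodes
        par = self.parent_index
        if par.shape != (n,):
            raise TreeError("parent_index shape mismatch")
        segs = self.segments
        if np.any((par[segs] < 0) | (par[segs] >= n)):
            raise TreeError("parent index out of range")
        # acyclic: walking up from every node must reach a root
        depth = node_depths(par)
        if np.any(depth < 0):
            raise TreeError("cycle detected")
        if np.any(self.child_counts() > 2):
            raise TreeError("node with more than two children")
        d = self.segment_diameters[segs]
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise TreeError("non-positive segment diameter")
        # daughters strictly thinner than their parent segment
        par_seg = par[segs]
        has_parent_seg = par[par_seg] != ROOT
        child_d = d[has_parent_seg]
        parent_d = self.segment_diameters[par_seg[has_parent_seg]]
        if np.any(child_d >= parent_d + 1e-12):
            raise TreeError("daughter diameter not smaller than parent diameter")


def node_depths(parent_index: np.ndarray) -> np.ndarray:
    """Depth of each node (roots at 0); −1 marks nodes not reaching a root."""
    n = parent_index.size
    depth = np.full(n, -1, dtype=int)
    depth[parent_index == ROOT] = 0
    # nodes are not guaranteed topologically sorted: iterate to fixpoint
    for _ in range(n):
        pending = np.flatnonzero(depth < 0)
        if pending.size == 0:
            break
        par = parent_index[pending]
        ready = depth[par] >= 0
        if not np.any(ready):
            break
        depth[pending[ready]] = depth[par[ready]] + 1
    return depth


def bifurcation_generations(tree: VascularTree) -> np.ndarray:
    """Per-node count of bifurcation levels on the path from the root.

    Monopodial continuations do not increment the counter: a node's level is
    its parent's level, plus one iff the parent node is a bifurcation.
    """
    order = np.argsort(node_depths(tree.parent_index), kind="stable")
    counts = tree.child_counts()
    gen = np.zeros(tree.n_nodes, dtype=int)
    par = tree.parent_index
    for i in order:
        p = par[i]
        if p != ROOT:
            gen[i] = gen[p] + (1 if counts[p] >= 2 else 0)
    return gen


# ---------------------------------------------------------------------------
# incremental construction (used by the growth algorithms)
# ---------------------------------------------------------------------------

class TreeBuilder:
    """Append-only tree assembly with O(1) node insertion."""

    def __init__(self) -> None:
        self.coords: list[np.ndarray] = []
        self.parent: list[int] = []
        self.diameter: list[float] = []
        self.generation: list[int] = []
        self.label: list[str] = []

    def add_node(self, coord, parent: int = ROOT, diameter: float = math.nan,
                 generation: int = -1, label: str = "") -> int:
        self.coords.append(np.asarray(coord, dtype=float))
        self.parent.append(parent)
        self.diameter.append(diameter)
        self.generation.append(generation)
        self.label.append(label)
        return len(self.coords) - 1

    def __len__(self) -> int:
        return len(self.coords)

    def n_segments(self) -> int:
        return sum(1 for p in self.parent if p != ROOT)

    def build(self, meta: dict | None = None) -> VascularTree:
        return VascularTree(
            node_coords=np.array(self.coords) if self.coords else np.empty((0, 3)),
            parent_index=np.array(self.parent, dtype=int),
            segment_diameters=np.array(self.diameter, dtype=float),
            segment_generation=np.array(self.generation, dtype=int),
            segment_label=np.array(self.label, dtype=object),
            meta=dict(meta or {}),
        )


# ---------------------------------------------------------------------------
# elementary morphometric operations
# ---------------------------------------------------------------------------

def length_to_diameter(length: float, diameter: float):
    """Length-to-diameter ratio l/d of a segment."""
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter <= 0):
        raise TreeError("diameter must be positive")
    return np.asarray(length, dtype=float) / diameter


def branching_angle_3d(c_j, c_i, c_g) -> float:
    """3D branching angle (degrees) at vertex ``c_i`` between ``c_j`` and ``c_g``.

    The angle is the arccos of the normalised dot product of the two arms
    ``c_j − c_i`` and ``c_g − c_i``; it lies in [0°, 180°].
    """
    u = np.asarray(c_j, dtype=float) - np.asarray(c_i, dtype=float)
    v = np.asarray(c_g, dtype=float) - np.asarray(c_i, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise TreeError("zero-length arm in branching angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def vector_angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angles (degrees) between rows of ``u`` and ``v`` (broadcasting allowed)."""
    u = np.atleast_2d(u)
    v = np.atleast_2d(v)
    dot = np.sum(u * v, axis=-1)
    norms = np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def murray_daughter_diameters(d0: float, k: float, a: float) -> tuple[float, float]:
    """Daughter diameters of a bifurcation under Murray's law.

    Solves ``d0**k = d1**k + d2**k`` jointly with the asymmetry constraint
    ``d1 = a * d2``, giving ``d2 = d0 / (1 + a**k)**(1/k)``.  Both daughters
    are strictly smaller than the parent for any ``a > 0``.
    """
    if d0 <= 0 or k <= 0 or a <= 0:
        raise TreeError("murray_daughter_diameters requires positive d0, k, a")
    d2 = d0 / (1.0 + a ** k) ** (1.0 / k)
    d1 = a * d2
    return d1, d2


def strahler_orders(tree: VascularTree) -> np.ndarray:
    """Per-node Strahler order of the segment ending at each node (0 at roots).

    Terminal segments have order 1.  At a bifurcation the parent order is the
    larger child order, incremented by one when the children tie; a monopodial
    continuation passes its child's order through unchanged.
    """
    if tree.n_nodes == 0:
        raise TreeError("empty tree")
    order_by_depth = np.argsort(node_depths(tree.parent_index), kind="stable")[::-1]
    par = tree.parent_index
    counts = tree.child_counts()
    orders = np.zeros(tree.n_nodes, dtype=int)
    # per-node running (max child order, multiplicity of the max)
    best = np.zeros(tree.n_nodes, dtype=int)
    mult = np.zeros(tree.n_nodes, dtype=int)
    for i in order_by_depth:
        if par[i] == ROOT:
            continue
        if counts[i] == 0:
            o = 1
        elif counts[i] == 1 or mult[i] == 1:
            o = best[i]
        else:  # all (two) children share the maximum order
            o = best[i] + 1
        orders[i] = o
        p = par[i]
        if o > best[p]:
            best[p], mult[p] = o, 1
        elif o == best[p]:
            mult[p] += 1
    return orders


def strahler_ratios(tree: VascularTree) -> tuple[float, float, float]:
    """Strahler (branching, diameter, length) ratios.

    Segments are grouped by Strahler order; per order the segment count and
    the mean diameter and length are computed, log10-transformed and fitted
    against the order by linear least squares.  Each ratio is the antilog of
    the absolute fitted gradient.  Orders without segments are excluded from
    the fits.
    """
    orders = strahler_orders(tree)
    segs = tree.segments
    seg_orders = orders[segs]
    lengths = tree.segment_lengths()[segs]
    diams = tree.segment_diameters[segs]
    uniq = np.unique(seg_orders)
    if uniq.size < 2:
        raise TreeError("Strahler ratios undefined for a single-order tree")
    counts = np.array([np.sum(seg_orders == o) for o in uniq], dtype=float)
    mean_d = np.array([diams[seg_orders == o].mean() for o in uniq])
    mean_l = np.array([lengths[seg_orders == o].mean() for o in uniq])

    def antilog_slope(values: np.ndarray) -> float:
        slope = np.polyfit(uniq.astype(float), np.log10(values), 1)[0]
        return float(10.0 ** abs(slope))

    return antilog_slope(counts), antilog_slope(mean_d), antilog_slope(mean_l)


# ---------------------------------------------------------------------------
# aggregate morphometry
# ---------------------------------------------------------------------------

@dataclass
class MorphometrySummary:
    """Topological metrics of a single vascular tree."""

    mean_branching_angle_deg: float
    min_branching_angle_deg: float
    max_branching_angle_deg: float
    mean_branching_generations: float
    sd_branching_generations: float
    max_strahler_order: int
    strahler_branching_ratio: float
    strahler_diameter_ratio: float
    strahler_length_ratio: float
    mean_diameter_ratio: float
    sd_diameter_ratio: float
    mean_path_length_mm: float
    sd_path_length_mm: float
    mean_terminal_diameter_mm: float
    sd_terminal_diameter_mm: float
    mean_terminal_length_mm: float
    sd_terminal_length_mm: float
    mean_ltd: float
    sd_ltd: float
    segment_count: int
    mean_vascular_density_pct: float
    spread_mm: float

    def as_dict(self) -> dict:
        return asdict(self)


def _branching_angles(tree: VascularTree) -> np.ndarray:
    """Parent-daughter angles (deg) for daughters born at bifurcation nodes."""
    par = tree.parent_index
    counts = tree.child_counts()
    segs = tree.segments
    sel = segs[(counts[par[segs]] >= 2) & (par[par[segs]] != ROOT)]
    if sel.size == 0:
        return np.empty(0)
    p = par[sel]
    gp = par[p]
    parent_dir = tree.node_coords[p] - tree.node_coords[gp]
    child_dir = tree.node_coords[sel] - tree.node_coords[p]
    return vector_angles_deg(parent_dir, child_dir)


def path_lengths(tree: VascularTree) -> np.ndarray:
    """Summed segment length (mm) from root to every terminal node."""
    lengths = tree.segment_lengths()
    par = tree.parent_index
    cum = np.zeros(tree.n_nodes)
    for i in np.argsort(node_depths(par), kind="stable"):
        if par[i] != ROOT:
            cum[i] = cum[par[i]] + lengths[i]
    return cum[tree.terminal_segments()]


def morphometry_summary(tree: VascularTree, domain_volume: float) -> MorphometrySummary:
    """Populate the full per-tree metrics record.

    ``domain_volume`` is the growth-domain volume in mm³ used for the mean
    vascular density; path lengths are summed segment lengths root→terminal
    and branching generations count bifurcation levels per terminal path.
    """
    if domain_volume <= 0:
        raise TreeError("domain_volume must be positive")
    tree.validate()
    from . import density  # local import: density depends on this module

    segs = tree.segments
    lengths = tree.segment_lengths()
    diams = tree.segment_diameters
    angles = _branching_angles(tree)
    term = tree.terminal_segments()
    # bifurcation level per segment, averaged over all segments (the
    # terminal-only mean overweights the deepest paths)
    gens = bifurcation_generations(tree)[segs]
    plens = path_lengths(tree)
    # daughter-to-mother diameter ratios over segment pairs
    with_parent_seg = segs[tree.parent_index[tree.parent_index[segs]] != ROOT]
    ratios = (diams[with_parent_seg]
              / diams[tree.parent_index[with_parent_seg]]) if with_parent_seg.size else np.empty(0)
    ltd = lengths[segs] / diams[segs]
    try:
        s_b, s_d, s_l = strahler_ratios(tree)
    except TreeError:
        s_b = s_d = s_l = math.nan
    orders = strahler_orders(tree)

    def _ms(x):
        x = np.asarray(x, dtype=float)
        if x.size == 0:
            return math.nan, math.nan
        return float(np.mean(x)), float(np.std(x))

    mean_gen, sd_gen = _ms(gens)
    mean_ratio, sd_ratio = _ms(ratios)
    mean_pl, sd_pl = _ms(plens)
    mean_td, sd_td = _ms(diams[term])
    mean_tl, sd_tl = _ms(lengths[term])
    mean_ltd, sd_ltd = _ms(ltd)
    return MorphometrySummary(
        mean_branching_angle_deg=float(np.mean(angles)) if angles.size else math.nan,
        min_branching_angle_deg=float(np.min(angles)) if angles.size else math.nan,
        max_branching_angle_deg=float(np.max(angles)) if angles.size else math.nan,
        mean_branching_generations=mean_gen,
        sd_branching_generations=sd_gen,
        max_strahler_order=int(orders.max()),
        strahler_branching_ratio=s_b,
        strahler_diameter_ratio=s_d,
        strahler_length_ratio=s_l,
        mean_diameter_ratio=mean_ratio,
        sd_diameter_ratio=sd_ratio,
        mean_path_length_mm=mean_pl,
        sd_path_length_mm=sd_pl,
        mean_terminal_diameter_mm=mean_td,
        sd_terminal_diameter_mm=sd_td,
        mean_terminal_length_mm=mean_tl,
        sd_terminal_length_mm=sd_tl,
        mean_ltd=mean_ltd,
        sd_ltd=sd_ltd,
        segment_count=int(tree.n_segments),
        mean_vascular_density_pct=density.mean_vascular_density(tree, domain_volume),
        spread_mm=density.spread(tree.node_coords, tree.node_coords.mean(axis=0)),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_swc(tree: VascularTree, path) -> None:
    """Write one node per line: id, type code, x, y, z, radius, parent (1-based)."""
    lengths = tree.segment_lengths()
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(tree.n_nodes):
            p = tree.parent_index[i]
            if p == ROOT:
                tcode, radius = 1, 0.0
            else:
                tcode = SWC_TYPE_CODES.get(str(tree.segment_label[i]), 0)
                radius = tree.segment_diameters[i] / 2.0
            x, y, z = tree.node_coords[i]
            fh.write(f"{i + 1} {tcode} {x:.6f} {y:.6f} {z:.6f} {radius:.6f} "
                     f"{p + 1 if p != ROOT else -1}\n")
    del lengths


def read_swc(path) -> VascularTree:
    builder = TreeBuilder()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, tcode, x, y, z, radius, parent = line.split()
            parent = int(parent)
            builder.add_node(
                (float(x), float(y), float(z)),
                parent=parent - 1 if parent != -1 else ROOT,
                diameter=2.0 * float(radius) if parent != -1 else math.nan,
                label=SWC_TYPE_NAMES.get(int(tcode), ""),
            )
    return builder.build()


def write_csv(tree: VascularTree, path, metadata_path=None) -> None:
    """CSV edge list (child_id, parent_id, x, y, z, diameter, generation, label)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["child_id", "parent_id", "x", "y", "z",
                         "diameter", "generation", "label"])
        for i in range(tree.n_nodes):
            writer.writerow([
                i, int(tree.parent_index[i]),
                *(f"{v:.6f}" for v in tree.node_coords[i]),
                "" if tree.parent_index[i] == ROOT else f"{tree.segment_diameters[i]:.6f}",
                int(tree.segment_generation[i]), str(tree.segment_label[i]),
            ])
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(tree.meta, indent=2, default=str))
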