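"""Conforming triangulation of convex-polygon-minus-disks domains.

The domains of this model are convex polygons with circular vessel
cut-outs whose centres lie on polygon vertices, on polygon edges, or in the
interior.  That structure permits a simple, fully deterministic meshing
strategy:

1. polygon edges are clipped against the vessel circles and sampled at the
   target spacing; circle arcs lying inside the polygon are found
   semi-analytically and sampled;
2. interior nodes come from a triangular lattice, keeping a clearance of
   0.72 local spacings from every boundary node (which guarantees the
   boundary chords are Gabriel edges and therefore appear in the Delaunay
   triangulation);
3. ``scipy.spatial.Delaunay`` triangulates the node set and triangles whose
   centroid leaves the domain are dropped;
4. boundary edges are recovered, tagged through node provenance, and the
   triangulation is verified to conform to the geometry.

Shared septum segments between neighbouring cells are sampled in a
canonical orientation, so the two cells produce bitwise-identical node
coordinates there; the solver merges them into a single continuous
interstitial unknown while keeping the sinusoidal unknowns distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import (
    BoundaryTag,
    Cell,
    Circle,
    GeometryError,
    LobuleGeometry,
    SlabGeometry,
    VesselKind,
)

#: merge radius for coincident nodes [m]; far below any mesh spacing in use
_MERGE_TOL = 1e-9

#: interior-node clearance, in units of the local boundary spacing
_CLEARANCE = 0.72


class MeshingError(RuntimeError):
    """Triangulation failed to conform to the geometry."""


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------

def _canonical(p0, p1):
    a = (float(p0[0]), float(p0[1]))
    b = (float(p1[0]), float(p1[1]))
    return (a, b, False) if a <= b else (b, a, True)


def _sample_segment(p0, p1, h: float) -> np.ndarray:
    """Uniform samples on a segment, computed in canonical orientation."""
    a, b, swapped = _canonical(p0, p1)
    a = np.array(a)
    b = np.array(b)
    n = max(1, int(math.ceil(float(np.hypot(*(b - a))) / h)))
    t = np.linspace(0.0, 1.0, n + 1)
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    return pts[::-1] if swapped else pts


def _segment_circle_t(a: np.ndarray, d: np.ndarray, circle: Circle):
    """Parameter interval of segment a + t*d, t in [0,1], inside the circle."""
    f = a - np.asarray(circle.center)
    A = float(d @ d)
    B = 2.0 * float(f @ d)
    C = float(f @ f) - circle.radius**2
    disc = B * B - 4.0 * A * C
    if disc <= 0.0:
        return None
    sq = math.sqrt(disc)
    t1 = (-B - sq) / (2.0 * A)
    t2 = (-B + sq) / (2.0 * A)
    lo, hi = max(t1, 0.0), min(t2, 1.0)
    if hi <= lo + 1e-14:
        return None
    return lo, hi


def _edge_free_segments(p0, p1, circles: Sequence[Circle]):
    """Sub-segments of the edge outside all circles (canonical orientation)."""
    a, b, _ = _canonical(p0, p1)
    a = np.array(a)
    b = np.array(b)
    d = b - a
    blocked = []
    for c in circles:
        iv = _segment_circle_t(a, d, c)
        if iv is not None:
            blocked.append(iv)
    blocked.sort()
    free = []
    t = 0.0
    for lo, hi in blocked:
        if lo > t + 1e-12:
            free.append((t, lo))
        t = max(t, hi)
    if t < 1.0 - 1e-12:
        free.append((t, 1.0))
    return [(a + t0 * d, a + t1 * d) for t0, t1 in free]


def _edge_blocked_segments(p0, p1, circle: Circle):
    """Sub-segment of the edge inside one circle (canonical orientation)."""
    a, b, _ = _canonical(p0, p1)
    a = np.array(a)
    b = np.array(b)
    d = b - a
    iv = _segment_circle_t(a, d, circle)
    if iv is None:
        return None
    lo, hi = iv
    return a + lo * d, a + hi * d


def _triangle_areas(pts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    d1 = pts[tris[:, 1]] - pts[tris[:, 0]]
    d2 = pts[tris[:, 2]] - pts[tris[:, 0]]
    return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


def _inside_convex(points: np.ndarray, verts: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Vectorized strict point-in-convex-CCW-polygon test with margin ``tol``."""
    d = np.roll(verts, -1, axis=0) - verts
    lens = np.hypot(d[:, 0], d[:, 1])
    inside = np.ones(len(points), dtype=bool)
    for (vx, vy), (dx, dy), ln in zip(verts, d, lens):
        s = (dx * (points[:, 1] - vy) - dy * (points[:, 0] - vx)) / ln
        inside &= s > tol
    return inside


def _circle_arcs(circle: Circle, cell: Cell):
    """Angular intervals of the circle lying inside the cell polygon."""
    angs = []
    for p0, p1, _tag in cell.edges:
        a, b, _ = _canonical(p0, p1)
        a = np.array(a)
        d = np.array(b) - a
        iv = _segment_circle_t(a, d, circle)
        if iv is None:
            continue
        for t in iv:
            if -1e-12 <= t <= 1.0 + 1e-12:
                p = a + min(max(t, 0.0), 1.0) * d
                r_p = p - np.asarray(circle.center)
                if abs(float(np.hypot(*r_p)) - circle.radius) < 1e-9:
                    angs.append(math.atan2(r_p[1], r_p[0]))
    cx, cy = circle.center
    if not angs:
        if cell.contains((cx, cy)):
            return [(0.0, 2.0 * math.pi)]
        return []
    angs = sorted(angs)
    arcs = []
    verts = np.asarray(cell.vertices, dtype=float)
    for i, a0 in enumerate(angs):
        a1 = angs[(i + 1) % len(angs)]
        if a1 <= a0:
            a1 += 2.0 * math.pi
        if a1 - a0 < 1e-10:
            continue
        mid = 0.5 * (a0 + a1)
        pm = np.array([[cx + circle.radius * math.cos(mid),
                        cy + circle.radius * math.sin(mid)]])
        if _inside_convex(pm, verts)[0]:
            arcs.append((a0, a1))
    return arcs


def _sample_arc(circle: Circle, a0: float, a1: float, h: float) -> np.ndarray:
    span = a1 - a0
    arc_len = circle.radius * span
    n = max(1, int(math.ceil(arc_len / h)), int(math.ceil(span / (math.pi / 8.0))))
    ang = np.linspace(a0, a1, n + 1)
    cx, cy = circle.center
    return np.column_stack([cx + circle.radius * np.cos(ang),
                            cy + circle.radius * np.sin(ang)])


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------

@dataclass
class CellMesh:
    """Triangulation of one cell (tissue region or vessel-interior patch)."""

    name: str
    points: np.ndarray                  # (n, 2) [m]
    triangles: np.ndarray               # (m, 3) CCW
    boundary_edges: np.ndarray          # (k, 2) node indices
    boundary_tags: list[BoundaryTag]    # one per boundary edge
    region: str = "tissue"              # "tissue" | "vessel"

    def triangle_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def nodal_areas(self) -> np.ndarray:
        """Lumped (one third per vertex) nodal areas."""
        areas = self.triangle_areas()
        m = np.zeros(len(self.points))
        np.add.at(m, self.triangles.ravel(),
                  np.repeat(areas / 3.0, 3))
        return m

    def nodes_with_tag(self, tag: BoundaryTag) -> np.ndarray:
        sel = [e for e, t in zip(self.boundary_edges, self.boundary_tags) if t is tag]
        if not sel:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(sel))

    def boundary_edges_with_tag(self, tag: BoundaryTag) -> np.ndarray:
        sel = [e for e, t in zip(self.boundary_edges, self.boundary_tags) if t is tag]
        if not sel:
            return np.empty((0, 2), dtype=int)
        return np.array(sel, dtype=int)

    def present_tags(self) -> set[BoundaryTag]:
        return set(self.boundary_tags)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())


@dataclass
class Mesh:
    """Multi-cell mesh with a merged (continuous) interstitial node numbering.

    The sinusoidal pressure is discretized on the per-cell tissue nodes (so
    it may jump across septa), the interstitial pressure on the merged
    global nodes (continuous everywhere, including into vessel-interior
    patches when present).
    """

    cells: list[CellMesh]
    target_edge_length: float
    pI_maps: list[np.ndarray] = field(default_factory=list)
    n_pI: int = 0

    def __post_init__(self) -> None:
        if not self.pI_maps:
            self._build_global_numbering()

    def _build_global_numbering(self) -> None:
        offsets = np.cumsum([0] + [len(c.points) for c in self.cells])
        all_pts = np.vstack([c.points for c in self.cells])
        n = len(all_pts)
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(all_pts)
        for i, j in tree.query_pairs(_MERGE_TOL):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        roots = np.array([find(i) for i in range(n)])
        uniq, glob = np.unique(roots, return_inverse=True)
        self.n_pI = len(uniq)
        self.pI_maps = [glob[offsets[k]:offsets[k + 1]]
                        for k in range(len(self.cells))]

    @property
    def tissue_cells(self) -> list[tuple[int, CellMesh]]:
        return [(k, c) for k, c in enumerate(self.cells) if c.region == "tissue"]

    @property
    def vessel_cells(self) -> list[tuple[int, CellMesh]]:
        return [(k, c) for k, c in enumerate(self.cells) if c.region == "vessel"]

    @property
    def n_nodes(self) -> int:
        return sum(len(c.points) for c in self.cells)

    def pI_coordinates(self) -> np.ndarray:
        coords = np.zeros((self.n_pI, 2))
        for c, gmap in zip(self.cells, self.pI_maps):
            coords[gmap] = c.points
        return coords


# ---------------------------------------------------------------------------
# cell meshing
# ---------------------------------------------------------------------------

def _mesh_cell(cell: Cell, h: float) -> CellMesh:
    """Triangulate one tissue cell (polygon minus vessel disks)."""
    verts = np.asarray(cell.vertices, dtype=float)

    bnd_pts: list[np.ndarray] = []
    bnd_src: list[tuple[str, int]] = []
    bnd_spacing: list[float] = []

    for i, (p0, p1, _tag) in enumerate(cell.edges):
        for a, b in _edge_free_segments(p0, p1, cell.circles):
            samples = _sample_segment(a, b, h)
            spacing = float(np.hypot(*(np.asarray(b) - np.asarray(a)))) / (len(samples) - 1)
            for p in samples:
                bnd_pts.append(p)
                bnd_src.append(("edge", i))
                bnd_spacing.append(spacing)

    arc_info = []
    for j, circ in enumerate(cell.circles):
        arcs = _circle_arcs(circ, cell)
        arc_info.append(arcs)
        for a0, a1 in arcs:
            samples = _sample_arc(circ, a0, a1, h)
            spacing = circ.radius * (a1 - a0) / (len(samples) - 1)
            for p in samples:
                bnd_pts.append(p)
                bnd_src.append(("circle", j))
                bnd_spacing.append(spacing)

    bnd = np.array(bnd_pts)
    # merge coincident boundary samples (junctions are generated twice)
    tree = cKDTree(bnd)
    parent = np.arange(len(bnd))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(_MERGE_TOL):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(bnd))])
    uniq_roots, inv = np.unique(roots, return_inverse=True)
    bpts = bnd[uniq_roots]
    sources: list[set] = [set() for _ in uniq_roots]
    spacing_arr = np.full(len(uniq_roots), np.inf)
    for i in range(len(bnd)):
        sources[inv[i]].add(bnd_src[i])
        spacing_arr[inv[i]] = min(spacing_arr[inv[i]], bnd_spacing[i])

    ipts = _interior_lattice(cell, h, bpts, spacing_arr)
    pts = np.vstack([bpts, ipts]) if len(ipts) else bpts

    tri = Delaunay(pts)
    cents = pts[tri.simplices].mean(axis=1)
    keep = _inside_convex(cents, verts)
    for circ in cell.circles:
        keep &= np.hypot(cents[:, 0] - circ.center[0],
                         cents[:, 1] - circ.center[1]) > circ.radius
    keep &= _triangle_areas(pts, tri.simplices) > 1e-6 * h * h
    tris = tri.simplices[keep]

    # drop unreferenced nodes, re-index
    used = np.unique(tris)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tris = remap[tris]

    # enforce CCW orientation
    d1 = pts[tris[:, 1]] - pts[tris[:, 0]]
    d2 = pts[tris[:, 2]] - pts[tris[:, 0]]
    flip = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0] < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    node_sources: dict[int, set] = {}
    for old_idx in range(len(bpts)):
        new_idx = remap[old_idx]
        if new_idx >= 0:
            node_sources[new_idx] = sources[old_idx]

    bedges, btags = _recover_boundary(cell, tris, node_sources)
    return CellMesh(cell.name, pts, tris, bedges, btags)


def _interior_lattice(cell: Cell, h: float, bpts: np.ndarray,
                      bspacing: np.ndarray) -> np.ndarray:
    verts = np.asarray(cell.vertices, dtype=float)
    xmin, ymin = verts.min(axis=0)
    xmax, ymax = verts.max(axis=0)
    dy = h * math.sqrt(3.0) / 2.0
    rows = []
    y = ymin + 0.5 * dy
    row_idx = 0
    while y < ymax:
        x0 = xmin + (0.25 if row_idx % 2 else 0.75) * h
        xs = np.arange(x0, xmax, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row_idx += 1
    if not rows:
        return np.empty((0, 2))
    cand = np.vstack(rows)
    inside = _inside_convex(cand, verts)
    for circ in cell.circles:
        inside &= np.hypot(cand[:, 0] - circ.center[0],
                           cand[:, 1] - circ.center[1]) > circ.radius
    cand = cand[inside]
    if len(cand) == 0:
        return cand
    tree = cKDTree(bpts)
    dist, idx = tree.query(cand)
    keep = dist >= _CLEARANCE * bspacing[idx]
    return cand[keep]


def _recover_boundary(cell: Cell, tris: np.ndarray,
                      node_sources: dict[int, set]):
    """Extract boundary edges and tag them via node provenance."""
    edge_count: dict[tuple[int, int], int] = {}
    for t in tris:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    bedges = []
    btags = []
    for (a, b), cnt in edge_count.items():
        if cnt != 1:
            continue
        sa = node_sources.get(a)
        sb = node_sources.get(b)
        if sa is None or sb is None:
            raise MeshingError(
                f"cell {cell.name!r}: boundary edge touches an interior node; "
                "the triangulation does not conform (reduce the edge length)")
        common = sa & sb
        if not common:
            raise MeshingError(
                f"cell {cell.name!r}: boundary edge between unrelated "
                "boundary features; the triangulation does not conform")
        circles = [s for s in common if s[0] == "circle"]
        if circles:
            tag = cell.circles[circles[0][1]].wall_tag
        else:
            tag = cell.edge_tags[next(iter(common))[1]]
        bedges.append((a, b))
        btags.append(tag)
    return np.array(bedges, dtype=int), btags


def _mesh_vessel_patch(cell: Cell, circ_idx: int, tissue: CellMesh,
                       h: float) -> CellMesh | None:
    """Triangulate the part of one vessel disk inside the cell polygon.

    Reuses the tissue mesh's arc nodes bitwise so the interstitial field is
    continuous across the vessel wall.
    """
    circ = cell.circles[circ_idx]
    verts = np.asarray(cell.vertices, dtype=float)
    wall_tag = circ.wall_tag

    # arc nodes from the tissue mesh, identified through boundary edges
    arc_nodes = tissue.nodes_with_tag(wall_tag)
    cx, cy = circ.center
    on_this = np.hypot(tissue.points[arc_nodes, 0] - cx,
                       tissue.points[arc_nodes, 1] - cy) < circ.radius + _MERGE_TOL
    keep = np.abs(np.hypot(tissue.points[arc_nodes, 0] - cx,
                           tissue.points[arc_nodes, 1] - cy) - circ.radius) < _MERGE_TOL
    arc_pts = tissue.points[arc_nodes[on_this & keep]]
    if len(arc_pts) == 0:
        return None

    bnd_pts = [arc_pts]
    bnd_src = [[("arc", 0)] * len(arc_pts)]
    h_local = min(h, circ.radius / 3.0)
    for i, (p0, p1, _tag) in enumerate(cell.edges):
        seg = _edge_blocked_segments(p0, p1, circ)
        if seg is None:
            continue
        samples = _sample_segment(seg[0], seg[1], h_local)
        bnd_pts.append(samples)
        bnd_src.append([("edge", i)] * len(samples))
    pts0 = np.vstack(bnd_pts)
    src0 = [s for chunk in bnd_src for s in chunk]

    tree = cKDTree(pts0)
    parent = np.arange(len(pts0))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(_MERGE_TOL):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(pts0))])
    uniq, inv = np.unique(roots, return_inverse=True)
    bpts = pts0[uniq]
    sources: list[set] = [set() for _ in uniq]
    for i in range(len(pts0)):
        sources[inv[i]].add(src0[i])

    # interior lattice clipped to disk-and-polygon
    xs = np.arange(cx - circ.radius, cx + circ.radius, h_local)
    ys = np.arange(cy - circ.radius, cy + circ.radius, h_local * math.sqrt(3) / 2)
    cand = np.array([[x + (0.5 * h_local if k % 2 else 0.0), y]
                     for k, y in enumerate(ys) for x in xs])
    if len(cand):
        inside = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy) < circ.radius
        inside &= _inside_convex(cand, verts)
        cand = cand[inside]
    if len(cand):
        tree_b = cKDTree(bpts)
        dist, _ = tree_b.query(cand)
        cand = cand[dist >= _CLEARANCE * h_local]
    pts = np.vstack([bpts, cand]) if len(cand) else bpts

    if len(pts) < 3:
        return None
    tri = Delaunay(pts)
    cents = pts[tri.simplices].mean(axis=1)
    keep_t = np.hypot(cents[:, 0] - cx, cents[:, 1] - cy) < circ.radius
    keep_t &= _inside_convex(cents, verts)
    keep_t &= _triangle_areas(pts, tri.simplices) > 1e-6 * h_local * h_local
    tris = tri.simplices[keep_t]
    if len(tris) == 0:
        return None

    used = np.unique(tris)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tris = remap[tris]
    d1 = pts[tris[:, 1]] - pts[tris[:, 0]]
    d2 = pts[tris[:, 2]] - pts[tris[:, 0]]
    flip = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0] < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    node_sources = {}
    for old in range(len(bpts)):
        if remap[old] >= 0:
            node_sources[remap[old]] = sources[old]

    edge_count: dict[tuple[int, int], int] = {}
    for t in tris:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    bedges, btags = [], []
    for (a, b), cnt in edge_count.items():
        if cnt != 1:
            continue
        sa, sb = node_sources.get(a), node_sources.get(b)
        if sa is None or sb is None or not (sa & sb):
            raise MeshingError(
                f"vessel patch of cell {cell.name!r}: non-conforming boundary")
        common = sa & sb
        if any(s[0] == "arc" for s in common):
            tag = wall_tag
        else:
            tag = cell.edge_tags[next(iter(common))[1]]
        bedges.append((a, b))
        btags.append(tag)

    return CellMesh(f"{cell.name}:{circ.kind.value}{circ_idx}",
                    pts, np.asarray(tris), np.array(bedges, dtype=int),
                    btags, region="vessel")


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def generate_mesh(geometry, target_edge_length: float,
                  include_vessel_interiors: bool = False) -> Mesh:
    """Triangulate a geometry at the given target edge length [m].

    ``geometry`` may be a :class:`LobuleGeometry`, a :class:`SlabGeometry`,
    a bare :class:`Cell`, or a list of cells.  With
    ``include_vessel_interiors`` the vessel disks are meshed as separate
    patches sharing their wall nodes with the tissue (used by the
    vessel-interstitium model variant).
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    if isinstance(geometry, LobuleGeometry):
        cells = [geometry.cell]
    elif isinstance(geometry, SlabGeometry):
        cells = geometry.cells
    elif isinstance(geometry, Cell):
        cells = [geometry]
    else:
        cells = list(geometry)

    h = float(target_edge_length)
    meshes: list[CellMesh] = []
    for cell in cells:
        meshes.append(_mesh_cell(cell, h))
    if include_vessel_interiors:
        for cell, tissue in zip(cells, list(meshes)):
            for j in range(len(cell.circles)):
                patch = _mesh_vessel_patch(cell, j, tissue, h)
                if patch is not None:
                    meshes.append(patch)
    return Mesh(meshes, h)
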