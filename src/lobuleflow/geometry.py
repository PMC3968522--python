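"""Cross-sectional domains of the lobule model.

Domains are convex polygons with circular vessel cut-outs:

* a single interior lobule: regular hexagon of side ``L_lob`` with the
  central vein (CV) at the centroid and portal tracts (PT) at the six
  vertices;
* a square-lattice variant preserving cross-sectional area and the vessel
  area fractions;
* a near-surface slab: one mirror-symmetric half-column of lobules cut by
  the flat liver surface.  The surface passes at ``L_lob/4`` from the
  nearest PT row and ``3 L_lob/4`` from the nearest CV row, and the cut
  (pentagonal) outermost lobule has the same cross-sectional area as an
  interior lobule.

Every boundary segment carries exactly one tag, which the solver maps to a
boundary condition: ``PT_WALL``/``CV_WALL`` are Dirichlet for the blood
pressure, ``SEPTUM`` is blood-impermeable (interstitial fluid crosses
freely), ``SURFACE`` carries the membrane condition, and ``SYMMETRY`` is
no-flux for both fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .parameters import PhysiologicalParameters


class GeometryError(ValueError):
    """Raised when a parameter set yields an infeasible domain."""


class BoundaryTag(Enum):
    SEPTUM = "septum"
    SYMMETRY = "symmetry"
    SURFACE = "surface"
    PT_WALL = "pt_wall"
    CV_WALL = "cv_wall"


class VesselKind(Enum):
    PT = "portal_tract"
    CV = "central_vein"


class SurfaceKind(Enum):
    GLISSON_PERITONEAL = "glisson_peritoneal"
    BARE_AREA = "bare_area"


@dataclass(frozen=True)
class Circle:
    """Vessel cross-section (may be clipped by the cell polygon)."""

    center: tuple[float, float]
    radius: float
    kind: VesselKind

    @property
    def wall_tag(self) -> BoundaryTag:
        return BoundaryTag.PT_WALL if self.kind is VesselKind.PT else BoundaryTag.CV_WALL


@dataclass
class Cell:
    """One convex polygonal cell with vessel cut-outs and per-edge tags.

    ``vertices`` are counter-clockwise; edge ``i`` joins vertex ``i`` to
    vertex ``i+1`` (mod n) and carries ``edge_tags[i]``.
    """

    name: str
    vertices: list[tuple[float, float]]
    edge_tags: list[BoundaryTag]
    circles: list[Circle] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.vertices)
        if len(self.edge_tags) != n:
            raise GeometryError("one tag per polygon edge is required")
        v = np.asarray(self.vertices, dtype=float)
        e1 = np.roll(v, -1, axis=0) - v
        e2 = np.roll(v, -2, axis=0) - np.roll(v, -1, axis=0)
        cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        if np.any(cross <= 0.0):
            raise GeometryError(f"cell {self.name!r} polygon must be convex and CCW")

    @property
    def edges(self) -> list[tuple[tuple[float, float], tuple[float, float], BoundaryTag]]:
        n = len(self.vertices)
        return [(self.vertices[i], self.vertices[(i + 1) % n], self.edge_tags[i])
                for i in range(n)]

    def polygon_area(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def contains(self, p, tol: float = 0.0) -> bool:
        """Point strictly inside the convex polygon (margin ``tol`` >= 0 shrinks it)."""
        v = np.asarray(self.vertices, dtype=float)
        d = np.roll(v, -1, axis=0) - v
        lens = np.hypot(d[:, 0], d[:, 1])
        # signed distance to each edge line, positive inside (CCW)
        s = (d[:, 0] * (p[1] - v[:, 1]) - d[:, 1] * (p[0] - v[:, 0])) / lens
        return bool(np.all(s > tol))


@dataclass
class LobuleGeometry:
    """Single interior lobule (hexagonal or square-variant cross-section)."""

    cell: Cell
    params: PhysiologicalParameters
    lattice: str  # "hexagonal" | "square"

    @property
    def outline_area(self) -> float:
        return self.cell.polygon_area()

    @property
    def vessel_area(self) -> float:
        """Closed-form vessel area inside the outline."""
        r_cv = self.params.D_CV / 2.0
        if self.lattice == "hexagonal":
            r_pt = self.params.D_PT / 2.0
            # six 120-degree PT wedges + one full CV disk
            return math.pi * r_cv**2 + 2.0 * math.pi * r_pt**2
        r_pt = self.cell.circles[1].radius  # scaled corner PT
        return math.pi * r_cv**2 + math.pi * r_pt**2

    @property
    def domain_area(self) -> float:
        return self.outline_area - self.vessel_area


@dataclass
class SlabGeometry:
    """Half-period column of lobules bounded below by the liver surface.

    ``cells[0]`` is the outermost (pentagonal) lobule touching the surface;
    the last cell is a half-lobule terminated by a horizontal symmetry line
    through a CV row, standing in for the far field.
    """

    cells: list[Cell]
    surface_kind: SurfaceKind
    L_edge: float
    params: PhysiologicalParameters
    n_lobule_rows: int

    @property
    def interior_cell_index(self) -> int:
        """Index of the innermost *full* lobule cell (used for far-field checks)."""
        return len(self.cells) - 2


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_vessel_feasibility(params: PhysiologicalParameters) -> None:
    L = params.L_lob
    r_pt, r_cv = params.D_PT / 2.0, params.D_CV / 2.0
    if 2.0 * r_pt >= L:
        raise GeometryError("portal tracts at adjacent vertices overlap")
    if r_pt + r_cv >= L:
        raise GeometryError("portal tract and central vein overlap")
    if r_cv >= L * math.sqrt(3.0) / 2.0:
        raise GeometryError("central vein reaches the lobule boundary")


def build_hexagonal_lobule(params: PhysiologicalParameters) -> LobuleGeometry:
    """Regular hexagon of side (= circumradius) ``L_lob``, PTs at the vertices.

    Pointy-top orientation (vertices at the top and bottom), matching the
    orientation used by the near-surface slab.
    """
    _check_vessel_feasibility(params)
    L = params.L_lob
    angles = [30.0, 90.0, 150.0, 210.0, 270.0, 330.0]
    verts = [(L * math.cos(math.radians(t)), L * math.sin(math.radians(t)))
             for t in angles]
    circles = [Circle((0.0, 0.0), params.D_CV / 2.0, VesselKind.CV)]
    circles += [Circle(v, params.D_PT / 2.0, VesselKind.PT) for v in verts]
    cell = Cell("lobule", verts, [BoundaryTag.SEPTUM] * 6, circles)
    return LobuleGeometry(cell, params, "hexagonal")


def build_square_lobule(params: PhysiologicalParameters) -> LobuleGeometry:
    """Square-lattice variant preserving area and vessel area fractions.

    The square side is ``s = sqrt(3*sqrt(3)/2) * L_lob`` (equal cross-section)
    and the corner PT radius is scaled by ``sqrt(2)`` so that the four
    quarter-disks match the six 120-degree wedges of the hexagon exactly.
    """
    _check_vessel_feasibility(params)
    s = math.sqrt(1.5 * math.sqrt(3.0)) * params.L_lob
    r_pt = params.D_PT / 2.0 * math.sqrt(2.0)
    r_cv = params.D_CV / 2.0
    if 2.0 * r_pt >= s:
        raise GeometryError("scaled portal tracts overlap along the square edge")
    if r_pt + r_cv >= s / math.sqrt(2.0):
        raise GeometryError("scaled portal tract and central vein overlap")
    h = s / 2.0
    verts = [(h, -h), (h, h), (-h, h), (-h, -h)]
    circles = [Circle((0.0, 0.0), r_cv, VesselKind.CV)]
    circles += [Circle(v, r_pt, VesselKind.PT) for v in verts]
    cell = Cell("square_lobule", verts, [BoundaryTag.SEPTUM] * 4, circles)
    return LobuleGeometry(cell, params, "square")


def build_surface_slab(params: PhysiologicalParameters,
                       surface_kind: SurfaceKind,
                       n_lobule_rows: int = 4) -> SlabGeometry:
    """Stack of ``n_lobule_rows`` half-lobule cells above the flat surface.

    The strip occupies ``0 <= x <= sqrt(3) L/2`` (one half lattice period;
    the side walls are mirror-symmetry lines through alternating CV and PT
    columns) and ``y >= 0`` with the surface at ``y = 0``.  CV centres sit at
    ``y = 3L/4 + 3kL/2`` alternating between the two side walls; the
    septa zigzag between the PT centres.  The topmost cell is the lower half
    of a lobule cut by a horizontal symmetry line through its CV.
    """
    if n_lobule_rows < 2:
        raise GeometryError("a slab needs at least 2 lobule rows")
    _check_vessel_feasibility(params)
    L = params.L_lob
    r_pt, r_cv = params.D_PT / 2.0, params.D_CV / 2.0
    if r_pt >= 0.25 * L:
        raise GeometryError("surface cut at L/4 would intersect a portal tract")
    W = math.sqrt(3.0) / 2.0 * L
    n = n_lobule_rows

    def cv_center(k: int) -> tuple[float, float]:
        return ((0.0 if k % 2 == 0 else W), 0.75 * L + 1.5 * L * k)

    def septum(k: int) -> tuple[tuple[float, float], tuple[float, float]]:
        """Septum between cell k and cell k+1 as (left, right) endpoints."""
        xc, yc = cv_center(k)
        near = (xc, yc + L)               # endpoint on the CV-k side wall
        far = (W - xc, yc + 0.5 * L)      # endpoint on the opposite wall
        return (near, far) if near[0] == 0.0 else (far, near)

    T = BoundaryTag
    cells: list[Cell] = []

    # outermost (pentagonal) lobule, halved by the x = 0 mirror line
    s0l, s0r = septum(0)
    pent = Cell(
        "cell0",
        [(0.0, 0.0), (W, 0.0), s0r, s0l],
        [T.SURFACE, T.SYMMETRY, T.SEPTUM, T.SYMMETRY],
        [Circle(s0l, r_pt, VesselKind.PT),
         Circle(s0r, r_pt, VesselKind.PT),
         Circle((W, 0.25 * L), r_pt, VesselKind.PT),
         Circle(cv_center(0), r_cv, VesselKind.CV)],
    )
    cells.append(pent)

    for k in range(1, n - 1):
        bl, br = septum(k - 1)
        tl, tr = septum(k)
        cells.append(Cell(
            f"cell{k}",
            [bl, br, tr, tl],
            [T.SEPTUM, T.SYMMETRY, T.SEPTUM, T.SYMMETRY],
            [Circle(bl, r_pt, VesselKind.PT),
             Circle(br, r_pt, VesselKind.PT),
             Circle(tr, r_pt, VesselKind.PT),
             Circle(tl, r_pt, VesselKind.PT),
             Circle(cv_center(k), r_cv, VesselKind.CV)],
        ))

    bl, br = septum(n - 2)
    y_top = cv_center(n - 1)[1]
    cells.append(Cell(
        f"cell{n - 1}",
        [bl, br, (W, y_top), (0.0, y_top)],
        [T.SEPTUM, T.SYMMETRY, T.SYMMETRY, T.SYMMETRY],
        [Circle(bl, r_pt, VesselKind.PT),
         Circle(br, r_pt, VesselKind.PT),
         Circle(cv_center(n - 1), r_cv, VesselKind.CV)],
    ))

    return SlabGeometry(cells, surface_kind, W, params, n)
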