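"""Finite-element solution of the coupled sinusoidal/interstitial Darcy system.

Strong form on the tissue domain (pressures in Pa):

.. math::

    -\\frac{k_S}{\\mu_S} \\nabla^2 p_S + C_f (p_S - p_I) = 0, \\qquad
    -\\frac{k_I}{\\mu_I} \\nabla^2 p_I - C_f (p_S - p_I)
        + C_l \\max(p_I - p_0, 0) = 0.

Boundary conditions: ``p_S`` is prescribed on the portal-tract and
central-vein walls and satisfies no-flux on septa, symmetry lines and the
liver surface; ``p_I`` satisfies no-flux on the vessel walls (standard
variant) and on symmetry lines, is continuous across septa (shared
unknowns), and on the liver surface obeys either the membrane (Robin)
condition ``u_I . n = M (p_I - p_ext)`` or its infinite-conductance
Dirichlet limit ``p_I = p_ext``.

Discretization: continuous piecewise-linear triangles for both fields.
The filtration, lymph-uptake and Robin terms use lumped (diagonal) mass,
which keeps the discrete operator an M-matrix (discrete maximum
principle), makes the lymph-valve clamp exactly nodal, and lets the global
mass balances and the mean-pressure identity hold to solver precision.
The ``max(.,0)`` nonlinearity is resolved by a primal active-set
iteration: nodes with ``p_I > p_0`` are active; ties count as inactive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import BoundaryTag, SurfaceKind, SlabGeometry
from .meshing import CellMesh, Mesh
from .parameters import PhysiologicalParameters


class SolverError(RuntimeError):
    pass


class SingularSystemError(SolverError):
    """The assembled system has a null space (e.g. pure-Neumann p_I)."""


class ModelVariant(Enum):
    STANDARD = "standard"
    VESSEL_INTERSTITIUM = "vessel_interstitium"


class SurfaceModel(Enum):
    ROBIN = "robin"
    DIRICHLET_LIMIT = "dirichlet_limit"


@dataclass(frozen=True)
class ModelOptions:
    variant: ModelVariant = ModelVariant.STANDARD
    surface_model: SurfaceModel = SurfaceModel.ROBIN
    active_set_tol: float = 1e-10        # [Pa] nonlinear residual tolerance scale
    max_active_set_iters: int = 30

    def __post_init__(self) -> None:
        if self.active_set_tol <= 0:
            raise ValueError("active_set_tol must be positive")
        if self.max_active_set_iters < 1:
            raise ValueError("max_active_set_iters must be >= 1")


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _stiffness(points: np.ndarray, tris: np.ndarray) -> sp.csr_matrix:
    """P1 stiffness matrix for the unit-coefficient Laplacian."""
    p = points[tris]                       # (m, 3, 2)
    b = np.empty_like(p)
    b[:, 0] = p[:, 1] - p[:, 2]
    b[:, 1] = p[:, 2] - p[:, 0]
    b[:, 2] = p[:, 0] - p[:, 1]
    # gradient of basis i is rot90(opposite edge)/2A
    area2 = (b[:, 2, 0] * (-b[:, 1, 1]) - b[:, 2, 1] * (-b[:, 1, 0]))
    # grad phi_i = (-b_i_y, b_i_x) / area2  (CCW)
    gx = -b[:, :, 1] / area2[:, None]
    gy = b[:, :, 0] / area2[:, None]
    area = 0.5 * area2
    ke = (gx[:, :, None] * gx[:, None, :] +
          gy[:, :, None] * gy[:, None, :]) * area[:, None, None]
    rows = np.repeat(tris, 3, axis=1).reshape(-1)
    cols = np.tile(tris, (1, 3)).reshape(-1)
    n = len(points)
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def _boundary_lumped_length(mesh_cell: CellMesh, tag: BoundaryTag) -> np.ndarray:
    """Lumped 1D mass (half edge length to each endpoint) on a tagged boundary."""
    out = np.zeros(len(mesh_cell.points))
    edges = mesh_cell.boundary_edges_with_tag(tag)
    if len(edges):
        p = mesh_cell.points
        lens = np.hypot(*(p[edges[:, 0]] - p[edges[:, 1]]).T)
        np.add.at(out, edges[:, 0], 0.5 * lens)
        np.add.at(out, edges[:, 1], 0.5 * lens)
    return out


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

@dataclass
class PressureFields:
    """Solved nodal pressures with the assembled operator kept for flux extraction."""

    mesh: Mesh
    params: PhysiologicalParameters
    options: ModelOptions
    surface_kind: SurfaceKind | None
    p_S: list[np.ndarray | None]          # per cell (None for vessel patches)
    p_I: np.ndarray                       # global interstitial nodes
    active_lymph_mask: np.ndarray         # bool, global interstitial nodes
    iterations: int
    # internals for consistent-flux extraction
    _x: np.ndarray = field(repr=False, default=None)
    _A: sp.csr_matrix = field(repr=False, default=None)
    _b: np.ndarray = field(repr=False, default=None)
    _pS_offsets: list[int] = field(repr=False, default_factory=list)
    _n_pS: int = field(repr=False, default=0)
    _mI: np.ndarray = field(repr=False, default=None)   # lumped tissue+vessel areas (pI nodes)
    _mI_uptake: np.ndarray = field(repr=False, default=None)
    _mS: list[np.ndarray] = field(repr=False, default_factory=list)
    _robin_weights: np.ndarray = field(repr=False, default=None)  # lumped surface lengths
    _robin_M: float = field(repr=False, default=0.0)
    _robin_p_ext: float = field(repr=False, default=0.0)

    def residual(self) -> np.ndarray:
        """A x - b of the Neumann-assembled system (nonzero only at constrained nodes)."""
        return self._A @ self._x - self._b

    def pS_dof(self, cell_index: int, local_nodes: np.ndarray) -> np.ndarray:
        return self._pS_offsets[cell_index] + local_nodes

    def pI_dof(self, cell_index: int, local_nodes: np.ndarray) -> np.ndarray:
        return self._n_pS + self.mesh.pI_maps[cell_index][local_nodes]

    def pS_range(self) -> float:
        vals = np.concatenate([v for v in self.p_S if v is not None])
        return float(vals.max() - vals.min())

    def pI_range(self) -> float:
        return float(self.p_I.max() - self.p_I.min())


@dataclass
class VelocityFields:
    """Per-triangle Darcy flux vectors [m/s] for each cell."""

    u_S: list[np.ndarray | None]
    u_I: list[np.ndarray]


@dataclass
class ExchangeFields:
    """Nodal filtration and lymph-uptake rates per unit tissue volume [1/s]."""

    q_w: list[np.ndarray | None]    # per cell, tissue only
    q_l: np.ndarray                 # global interstitial nodes


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------

def _surface_condition(params: PhysiologicalParameters,
                       surface_kind: SurfaceKind | None,
                       options: ModelOptions):
    """Return ('robin', M, p_ext) or ('dirichlet', p_ext) or None."""
    if surface_kind is None:
        return None
    if surface_kind is SurfaceKind.GLISSON_PERITONEAL:
        return ("robin", params.M_GP, params.p_PC)
    if math.isinf(params.M_BA) or options.surface_model is SurfaceModel.DIRICHLET_LIMIT:
        return ("dirichlet", params.p_DS)
    return ("robin", params.M_BA, params.p_DS)


def solve_pressures(mesh: Mesh, params: PhysiologicalParameters,
                    options: ModelOptions = ModelOptions(),
                    surface_kind: SurfaceKind | None = None) -> PressureFields:
    """Solve the coupled system on a (possibly multi-cell) mesh.

    ``surface_kind`` selects the membrane model on ``SURFACE``-tagged
    boundaries; it defaults to the slab's own kind when the mesh was built
    from a :class:`SlabGeometry` (pass it explicitly for bare cell lists).
    """
    if options.variant is ModelVariant.VESSEL_INTERSTITIUM and not mesh.vessel_cells:
        raise SolverError("vessel-interstitium variant needs a mesh with "
                          "include_vessel_interiors=True")

    a = params.kappa_S
    b_mob = params.kappa_I
    Cf, Cl, p0 = params.C_f, params.C_l, params.p_0

    tissue = mesh.tissue_cells
    pS_offsets = {}
    off = 0
    for k, c in tissue:
        pS_offsets[k] = off
        off += len(c.points)
    n_pS = off
    n_pI = mesh.n_pI
    n = n_pS + n_pI

    rows, cols, vals = [], [], []
    bvec = np.zeros(n)
    mI = np.zeros(n_pI)          # lumped areas on interstitial nodes
    mI_uptake = np.zeros(n_pI)   # areas where lymph uptake acts
    mS = {}

    def scatter(mat: sp.spmatrix, rmap: np.ndarray, cmap: np.ndarray):
        coo = sp.coo_matrix(mat)
        rows.append(rmap[coo.row])
        cols.append(cmap[coo.col])
        vals.append(coo.data)

    def scatter_diag(d: np.ndarray, rmap: np.ndarray, cmap: np.ndarray):
        nz = d != 0.0
        rows.append(rmap[nz])
        cols.append(cmap[nz])
        vals.append(d[nz])

    for k, c in tissue:
        K = _stiffness(c.points, c.triangles)
        m = c.nodal_areas()
        loc = np.arange(len(c.points))
        s_map = pS_offsets[k] + loc
        i_map = n_pS + mesh.pI_maps[k]
        scatter(a * K, s_map, s_map)
        scatter_diag(Cf * m, s_map, s_map)
        scatter_diag(-Cf * m, s_map, i_map)
        scatter_diag(-Cf * m, i_map, s_map)
        scatter(b_mob * K, i_map, i_map)
        scatter_diag(Cf * m, i_map, i_map)
        np.add.at(mI, mesh.pI_maps[k], m)
        np.add.at(mI_uptake, mesh.pI_maps[k], m)
        mS[k] = m

    for k, c in mesh.vessel_cells:
        K = _stiffness(c.points, c.triangles)
        m = c.nodal_areas()
        i_map = n_pS + mesh.pI_maps[k]
        scatter(b_mob * K, i_map, i_map)
        np.add.at(mI, mesh.pI_maps[k], m)
        # lymphatic uptake also acts inside the vessel cross-sections
        np.add.at(mI_uptake, mesh.pI_maps[k], m)

    # surface condition
    surf = _surface_condition(params, surface_kind, options)
    robin_w = np.zeros(n_pI)
    robin_M = 0.0
    robin_p_ext = 0.0
    dirichlet_pI_nodes = []
    for k, c in enumerate(mesh.cells):
        if BoundaryTag.SURFACE not in c.present_tags():
            continue
        if surf is None:
            raise SolverError("mesh has SURFACE boundaries but no surface_kind given")
        w = _boundary_lumped_length(c, BoundaryTag.SURFACE)
        np.add.at(robin_w, mesh.pI_maps[k], w)
        if surf[0] == "dirichlet":
            dirichlet_pI_nodes.append(mesh.pI_maps[k][c.nodes_with_tag(BoundaryTag.SURFACE)])
    if surf is not None and surf[0] == "robin":
        robin_M, robin_p_ext = surf[1], surf[2]
        scatter_diag(robin_M * robin_w, n_pS + np.arange(n_pI), n_pS + np.arange(n_pI))
        bvec[n_pS:] += robin_M * robin_w * robin_p_ext
    elif surf is not None:
        robin_p_ext = surf[1]

    A_base = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    b_base = bvec

    # Dirichlet sets
    fixed = np.zeros(n, dtype=bool)
    xfix = np.zeros(n)
    for k, c in tissue:
        for tag, val in ((BoundaryTag.PT_WALL, params.p_S_PT),
                         (BoundaryTag.CV_WALL, params.p_S_CV)):
            nodes = c.nodes_with_tag(tag)
            dof = pS_offsets[k] + nodes
            fixed[dof] = True
            xfix[dof] = val
    for glob_nodes in dirichlet_pI_nodes:
        dof = n_pS + glob_nodes
        fixed[dof] = True
        xfix[dof] = surf[1]

    has_pI_dirichlet = bool(dirichlet_pI_nodes)
    if Cf == 0.0 and Cl == 0.0 and robin_M == 0.0 and not has_pI_dirichlet:
        raise SingularSystemError(
            "interstitial pressure is determined only up to a constant "
            "(C_f = C_l = 0 with pure-Neumann boundary conditions)")

    free = ~fixed
    free_idx = np.where(free)[0]

    # active-set iteration on chi = [p_I > p_0]
    chi = np.ones(n_pI, dtype=bool)
    x = xfix.copy()
    iters = 0
    pI_dofs = n_pS + np.arange(n_pI)
    res_scale = max(Cl * float(mI_uptake.sum()) * max(abs(params.p_S_PT), 1.0), 1e-30)
    for it in range(options.max_active_set_iters):
        iters = it + 1
        d_act = Cl * mI_uptake * chi
        A = A_base + sp.diags(
            np.concatenate([np.zeros(n_pS), d_act]), format="csr")
        b = b_base.copy()
        b[pI_dofs] += d_act * p0
        rhs = b[free_idx] - A[free_idx][:, fixed] @ xfix[fixed]
        Aff = A[free_idx][:, free_idx].tocsc()
        try:
            x_free = spla.spsolve(Aff, rhs)
        except RuntimeError as exc:  # pragma: no cover - singular factorization
            raise SingularSystemError(str(exc)) from exc
        if not np.all(np.isfinite(x_free)):
            raise SingularSystemError("linear solve produced non-finite values")
        x = xfix.copy()
        x[free_idx] = x_free
        pI = x[n_pS:]
        chi_new = pI > p0
        # nonlinear residual of the current iterate (free rows only)
        ql = Cl * mI_uptake * np.maximum(pI - p0, 0.0)
        F = A_base @ x - b_base
        F[pI_dofs] += ql
        if np.max(np.abs(F[free_idx])) <= options.active_set_tol * res_scale + 1e-30:
            chi = chi_new
            break
        if np.array_equal(chi_new, chi):
            break
        chi = chi_new
    else:
        raise SolverError("active-set iteration did not converge")

    # store the final Neumann operator (with the final active set) for fluxes
    d_act = Cl * mI_uptake * chi
    A_fin = A_base + sp.diags(np.concatenate([np.zeros(n_pS), d_act]), format="csr")
    b_fin = b_base.copy()
    b_fin[pI_dofs] += d_act * p0

    p_S: list[np.ndarray | None] = []
    offsets_list = []
    for k, c in enumerate(mesh.cells):
        if c.region == "tissue":
            o = pS_offsets[k]
            offsets_list.append(o)
            p_S.append(x[o:o + len(c.points)].copy())
        else:
            offsets_list.append(-1)
            p_S.append(None)

    return PressureFields(
        mesh=mesh, params=params, options=options, surface_kind=surface_kind,
        p_S=p_S, p_I=x[n_pS:].copy(), active_lymph_mask=chi, iterations=iters,
        _x=x, _A=A_fin, _b=b_fin, _pS_offsets=offsets_list, _n_pS=n_pS,
        _mI=mI, _mI_uptake=mI_uptake,
        _mS=[mS.get(k) for k in range(len(mesh.cells))],
        _robin_weights=robin_w, _robin_M=robin_M, _robin_p_ext=robin_p_ext)


def solve_variant_vessel_interstitium(mesh: Mesh, params: PhysiologicalParameters,
                                      options: ModelOptions = ModelOptions(),
                                      surface_kind: SurfaceKind | None = None
                                      ) -> PressureFields:
    """Solve with interstitial flow extending into the vessel cross-sections."""
    opts = ModelOptions(variant=ModelVariant.VESSEL_INTERSTITIUM,
                        surface_model=options.surface_model,
                        active_set_tol=options.active_set_tol,
                        max_active_set_iters=options.max_active_set_iters)
    return solve_pressures(mesh, params, opts, surface_kind)


# ---------------------------------------------------------------------------
# derived fields
# ---------------------------------------------------------------------------

def _tri_gradients(points: np.ndarray, tris: np.ndarray,
                   nodal: np.ndarray) -> np.ndarray:
    p = points[tris]
    v = nodal[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    f1 = v[:, 1] - v[:, 0]
    f2 = v[:, 2] - v[:, 0]
    gx = (f1 * d2[:, 1] - f2 * d1[:, 1]) / det
    gy = (f2 * d1[:, 0] - f1 * d2[:, 0]) / det
    return np.column_stack([gx, gy])


def compute_darcy_velocities(fields: PressureFields,
                             params: PhysiologicalParameters | None = None
                             ) -> VelocityFields:
    """Element-wise Darcy fluxes u = -(k/mu) grad p for both compartments."""
    params = params or fields.params
    u_S, u_I = [], []
    for k, c in enumerate(fields.mesh.cells):
        pI_loc = fields.p_I[fields.mesh.pI_maps[k]]
        u_I.append(-params.kappa_I * _tri_gradients(c.points, c.triangles, pI_loc))
        if c.region == "tissue":
            u_S.append(-params.kappa_S * _tri_gradients(c.points, c.triangles,
                                                        fields.p_S[k]))
        else:
            u_S.append(None)
    return VelocityFields(u_S=u_S, u_I=u_I)


def compute_exchange_fields(fields: PressureFields,
                            params: PhysiologicalParameters | None = None
                            ) -> ExchangeFields:
    """Nodal filtration q_w = C_f (p_S - p_I) and uptake q_l = C_l max(p_I - p_0, 0)."""
    params = params or fields.params
    q_w = []
    for k, c in enumerate(fields.mesh.cells):
        if c.region == "tissue":
            pI_loc = fields.p_I[fields.mesh.pI_maps[k]]
            q_w.append(params.C_f * (fields.p_S[k] - pI_loc))
        else:
            q_w.append(None)
    q_l = params.C_l * np.maximum(fields.p_I - params.p_0, 0.0)
    q_l[~fields.active_lymph_mask] = 0.0
    return ExchangeFields(q_w=q_w, q_l=q_l)


# ---------------------------------------------------------------------------
# consistent boundary fluxes
# ---------------------------------------------------------------------------

def blood_boundary_influx(fields: PressureFields, tag: BoundaryTag,
                          cell_index: int | None = None) -> float:
    """Net blood volume influx [m^2/s per unit axial length] through a tagged wall.

    Uses the residual of the Neumann-assembled discrete system (consistent
    flux extraction), which is conservative to linear-solver precision.
    """
    r = fields.residual()
    total = 0.0
    for k, c in enumerate(fields.mesh.cells):
        if c.region != "tissue" or (cell_index is not None and k != cell_index):
            continue
        nodes = c.nodes_with_tag(tag)
        if len(nodes):
            total += float(r[fields.pS_dof(k, nodes)].sum())
    return total


def interstitial_surface_outflow(fields: PressureFields) -> float:
    """Interstitial outflow [m^2/s per unit axial length] through the SURFACE edge."""
    if fields._robin_M > 0.0:
        return float(fields._robin_M *
                     (fields._robin_weights *
                      (fields.p_I - fields._robin_p_ext)).sum())
    # Dirichlet surface: consistent flux from the residual
    r = fields.residual()
    total = 0.0
    for k, c in enumerate(fields.mesh.cells):
        nodes = c.nodes_with_tag(BoundaryTag.SURFACE)
        if len(nodes):
            gdofs = fields.pI_dof(k, nodes)
            total += -float(r[np.unique(gdofs)].sum())
    return total


def filtration_integral(fields: PressureFields) -> float:
    """Integral of q_w over the tissue cross-section [m^2/s per unit length]."""
    total = 0.0
    for k, c in enumerate(fields.mesh.cells):
        if c.region != "tissue":
            continue
        m = fields._mS[k]
        pI_loc = fields.p_I[fields.mesh.pI_maps[k]]
        total += float((fields.params.C_f * m * (fields.p_S[k] - pI_loc)).sum())
    return total


def lymph_uptake_integral(fields: PressureFields) -> float:
    """Integral of q_l over the cross-section [m^2/s per unit length]."""
    p = fields.params
    excess = np.maximum(fields.p_I - p.p_0, 0.0)
    excess[~fields.active_lymph_mask] = 0.0
    return float((p.C_l * fields._mI_uptake * excess).sum())
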