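"""Whole-liver fluxes, pressure statistics and conservation identities.

A solved 2D cross-section is scaled to the whole organ by the factor
``V_liv / (3 sqrt(3) L_lob^2 / 2)`` (total lobule axial length contained in
the liver).  Internally everything is SI; summaries also carry the
conventional physiological units (l/min for blood, ml/min for lymph).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import BoundaryTag, LobuleGeometry, SlabGeometry, SurfaceKind
from .parameters import MMHG, PhysiologicalParameters
from .solver import (
    PressureFields,
    blood_boundary_influx,
    interstitial_surface_outflow,
    lymph_uptake_integral,
)

#: m^3/s -> l/min
M3S_TO_LMIN = 60.0e3
#: m^3/s -> ml/min
M3S_TO_MLMIN = 60.0e6


@dataclass(frozen=True)
class FluxSummary:
    """Whole-liver fluxes.  SI in m^3/s; printable units as separate fields."""

    Q_blood: float                # m^3/s
    Q_L: float                    # m^3/s
    Q_GP: float                   # m^3/s
    Q_BA: float                   # m^3/s
    scaling_factor: float         # V_liv / (3 sqrt(3) L^2 / 2)  [m]

    @property
    def Q_surface(self) -> float:
        return self.Q_GP + self.Q_BA

    @property
    def Q_liver_lymph(self) -> float:
        return self.Q_L + self.Q_surface

    @property
    def Q_blood_lmin(self) -> float:
        return self.Q_blood * M3S_TO_LMIN

    @property
    def Q_L_mlmin(self) -> float:
        return self.Q_L * M3S_TO_MLMIN

    @property
    def Q_GP_mlmin(self) -> float:
        return self.Q_GP * M3S_TO_MLMIN

    @property
    def Q_BA_mlmin(self) -> float:
        return self.Q_BA * M3S_TO_MLMIN

    @property
    def Q_surface_mlmin(self) -> float:
        return self.Q_surface * M3S_TO_MLMIN

    @property
    def Q_liver_lymph_mlmin(self) -> float:
        return self.Q_liver_lymph * M3S_TO_MLMIN

    @property
    def surface_to_lymphatic_ratio(self) -> float:
        return self.Q_surface / self.Q_L if self.Q_L else math.inf

    @property
    def surface_to_blood_ratio(self) -> float:
        return self.Q_surface / self.Q_blood if self.Q_blood else math.inf

    def as_dict(self) -> dict:
        return {
            "Q_blood_l_per_min": self.Q_blood_lmin,
            "Q_L_ml_per_min": self.Q_L_mlmin,
            "Q_GP_ml_per_min": self.Q_GP_mlmin,
            "Q_BA_ml_per_min": self.Q_BA_mlmin,
            "Q_surface_ml_per_min": self.Q_surface_mlmin,
            "Q_liver_lymph_ml_per_min": self.Q_liver_lymph_mlmin,
            "Q_surface_over_Q_L": self.surface_to_lymphatic_ratio,
            "Q_surface_over_Q_blood": self.surface_to_blood_ratio,
        }


@dataclass(frozen=True)
class FieldStats:
    min: float
    max: float
    mean: float

    @property
    def range(self) -> float:
        return self.max - self.min


@dataclass
class PressureStats:
    """Per-cell and global pressure statistics [mmHg]."""

    p_S: dict[str, FieldStats]
    p_I: dict[str, FieldStats]
    p_S_global: FieldStats
    p_I_global: FieldStats


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def compute_blood_flux(fields: PressureFields,
                       params: PhysiologicalParameters | None = None,
                       cell_index: int = 0) -> float:
    """Whole-liver blood flux [m^3/s].

    Line integral of the inward blood flux around the edge of one lobule
    (the portal-tract arcs carry the inflow; septa are no-flux by
    construction), scaled by ``V_liv / (3 sqrt(3) L_lob^2 / 2)``.
    """
    params = params or fields.params
    influx = blood_boundary_influx(fields, BoundaryTag.PT_WALL, cell_index)
    return params.whole_liver_scaling * influx


def compute_lymphatic_uptake(fields: PressureFields,
                             params: PhysiologicalParameters | None = None
                             ) -> float:
    """Whole-liver lymphatic uptake [m^3/s]: scaled integral of C_l max(p_I - p_0, 0)."""
    params = params or fields.params
    return params.whole_liver_scaling * lymph_uptake_integral(fields)


def compute_surface_fluxes(fields: PressureFields, slab: SlabGeometry,
                           params: PhysiologicalParameters | None = None
                           ) -> float:
    """Whole-liver outflow through the modelled surface kind [m^3/s].

    For the Glisson--peritoneal membrane this is the per-unit-edge integral
    of ``M_GP (p_I - p_PC)`` scaled by ``(1 - chi) A_liv / L_edge``; for the
    bare area it is the per-unit-edge Darcy outflow scaled by
    ``chi A_liv / L_edge``.
    """
    params = params or fields.params
    if fields.surface_kind is not slab.surface_kind:
        raise ValueError("fields were solved with a different surface kind")
    outflow = interstitial_surface_outflow(fields)   # m^2/s per unit length
    if slab.surface_kind is SurfaceKind.GLISSON_PERITONEAL:
        prefactor = (1.0 - params.chi) * params.A_liv / slab.L_edge
    else:
        prefactor = params.chi * params.A_liv / slab.L_edge
    return prefactor * outflow


def summarize_fluxes(single_lobule_fields: PressureFields,
                     gp_fields: PressureFields, gp_slab: SlabGeometry,
                     ba_fields: PressureFields, ba_slab: SlabGeometry,
                     params: PhysiologicalParameters | None = None
                     ) -> FluxSummary:
    """Assemble the whole-liver flux summary from the three solutions."""
    params = params or single_lobule_fields.params
    return FluxSummary(
        Q_blood=compute_blood_flux(single_lobule_fields, params),
        Q_L=compute_lymphatic_uptake(single_lobule_fields, params),
        Q_GP=compute_surface_fluxes(gp_fields, gp_slab, params),
        Q_BA=compute_surface_fluxes(ba_fields, ba_slab, params),
        scaling_factor=params.whole_liver_scaling,
    )


# ---------------------------------------------------------------------------
# statistics and identities
# ---------------------------------------------------------------------------

def _area_weighted_mean(fields: PressureFields, which: str) -> float:
    num = den = 0.0
    for k, c in enumerate(fields.mesh.cells):
        if c.region != "tissue":
            continue
        m = fields._mS[k]
        v = fields.p_S[k] if which == "S" else fields.p_I[fields.mesh.pI_maps[k]]
        num += float((m * v).sum())
        den += float(m.sum())
    return num / den


def check_mean_pressure_identity(fields: PressureFields,
                                 params: PhysiologicalParameters | None = None
                                 ) -> float:
    """Relative residual of the mass-balance mean-pressure relation.

    Integrating the interstitial equation over a lobule with no-flux
    interstitial boundaries gives, when ``p_I > p_0`` everywhere,
    ``mean(p_I) = (C_f mean(p_S) + C_l p_0) / (C_f + C_l)``.  The residual
    is normalised by the sinusoidal pressure range.
    """
    params = params or fields.params
    if not bool(fields.active_lymph_mask.all()):
        raise ValueError("identity inapplicable: inactive lymph-uptake "
                         "region present (p_I <= p_0 somewhere)")
    if params.C_f + params.C_l == 0.0:
        raise ValueError("identity undefined for C_f = C_l = 0")
    pbar_S = _area_weighted_mean(fields, "S")
    pbar_I = _area_weighted_mean(fields, "I")
    predicted = (params.C_f * pbar_S + params.C_l * params.p_0) / (params.C_f + params.C_l)
    scale = fields.pS_range()
    if scale == 0.0:
        scale = max(abs(pbar_S), 1.0)
    return abs(pbar_I - predicted) / scale


def pressure_statistics(fields: PressureFields) -> PressureStats:
    """Min/max/area-weighted-mean per cell and globally, in mmHg."""
    pS_stats: dict[str, FieldStats] = {}
    pI_stats: dict[str, FieldStats] = {}
    allS, allI, allmS = [], [], []
    for k, c in enumerate(fields.mesh.cells):
        if c.region != "tissue":
            continue
        m = fields._mS[k]
        vS = fields.p_S[k] / MMHG
        vI = fields.p_I[fields.mesh.pI_maps[k]] / MMHG
        pS_stats[c.name] = FieldStats(float(vS.min()), float(vS.max()),
                                      float((m * vS).sum() / m.sum()))
        pI_stats[c.name] = FieldStats(float(vI.min()), float(vI.max()),
                                      float((m * vI).sum() / m.sum()))
        allS.append(vS)
        allI.append(vI)
        allmS.append(m)
    vS = np.concatenate(allS)
    vI = np.concatenate(allI)
    m = np.concatenate(allmS)
    return PressureStats(
        p_S=pS_stats, p_I=pI_stats,
        p_S_global=FieldStats(float(vS.min()), float(vS.max()),
                              float((m * vS).sum() / m.sum())),
        p_I_global=FieldStats(float(vI.min()), float(vI.max()),
                              float((m * vI).sum() / m.sum())),
    )


def extract_cut_profiles(fields: PressureFields, geometry: LobuleGeometry,
                         n_samples: int = 200) -> dict[str, np.ndarray]:
    """Pressure profiles along the two natural symmetry cut lines.

    Cut 1 runs from a portal-tract centre through the central-vein centre to
    the opposite portal tract; cut 2 from an edge midpoint through the
    centre to the opposite edge midpoint.  Points falling inside vessels
    yield NaN.
    """
    from matplotlib.tri import LinearTriInterpolator, Triangulation

    cell = fields.mesh.cells[0]
    tri = Triangulation(cell.points[:, 0], cell.points[:, 1], cell.triangles)
    fS = LinearTriInterpolator(tri, fields.p_S[0])
    fI = LinearTriInterpolator(tri, fields.p_I[fields.mesh.pI_maps[0]])

    v0 = np.asarray(geometry.cell.vertices[0], dtype=float)
    v1 = np.asarray(geometry.cell.vertices[1], dtype=float)
    mid = 0.5 * (v0 + v1)
    out = {}
    for name, end in (("cut1_pt_to_pt", v0), ("cut2_mid_to_mid", mid)):
        t = np.linspace(-1.0, 1.0, n_samples)
        pts = t[:, None] * end[None, :]
        s = t * float(np.hypot(*end))
        out[name] = np.column_stack([
            s,
            np.asarray(fS(pts[:, 0], pts[:, 1]).filled(np.nan)) / MMHG,
            np.asarray(fI(pts[:, 0], pts[:, 1]).filled(np.nan)) / MMHG,
        ])
    return out
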