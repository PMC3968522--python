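"""Coupled Darcy solver: exact limits, conservation, oracle equivalence."""

import math

import numpy as np
import pytest

from lobuleflow.analytic import annulus_reference_solution
from lobuleflow.geometry import (
    BoundaryTag,
    Cell,
    Circle,
    SurfaceKind,
    VesselKind,
    build_hexagonal_lobule,
)
from lobuleflow.meshing import generate_mesh
from lobuleflow.parameters import MMHG, PhysiologicalParameters
from lobuleflow.solver import (
    SingularSystemError,
    blood_boundary_influx,
    compute_darcy_velocities,
    compute_exchange_fields,
    filtration_integral,
    interstitial_surface_outflow,
    lymph_uptake_integral,
    solve_pressures,
    solve_variant_vessel_interstitium,
)

H = 15e-6


@pytest.fixture(scope="module")
def params():
    return PhysiologicalParameters()


@pytest.fixture(scope="module")
def hex_mesh(params):
    return generate_mesh(build_hexagonal_lobule(params), H)


class TestTrivialLimits:
    def test_uniform_pressures_give_constant_fields_and_zero_fluxes(self, params, hex_mesh):
        c = 2.0 * MMHG
        pu = params.with_(p_S_PT=c, p_S_CV=c, p_0=c)
        f = solve_pressures(hex_mesh, pu)
        assert np.max(np.abs(f.p_S[0] - c)) < 1e-8 * c
        assert np.max(np.abs(f.p_I - c)) < 1e-8 * c
        assert abs(blood_boundary_influx(f, BoundaryTag.PT_WALL)) < 1e-20
        v = compute_darcy_velocities(f)
        assert np.max(np.hypot(*v.u_S[0].T)) < 1e-12

    def test_no_filtration_pins_interstitium_to_lymph_pressure(self, params, hex_mesh):
        p0 = params.with_(C_f=0.0)
        f = solve_pressures(hex_mesh, p0)
        assert np.max(np.abs(f.p_I - p0.p_0)) == 0.0

    def test_filtration_perturbs_blood_pressure_weakly(self, params, hex_mesh):
        """The p_S field differs from the uncoupled (C_f = 0) Laplace solution
        by a small fraction of its range (reported ~1e-4 relative)."""
        f = solve_pressures(hex_mesh, params)
        f0 = solve_pressures(hex_mesh, params.with_(C_f=0.0))
        rel = np.max(np.abs(f.p_S[0] - f0.p_S[0])) / f.pS_range()
        assert rel < 5e-4
        assert rel > 1e-6  # the coupling is genuinely present


class TestLinearStructure:
    def test_affine_superposition_in_boundary_pressures(self, params, hex_mesh):
        f1 = solve_pressures(hex_mesh, params)
        f2 = solve_pressures(hex_mesh, params.with_(p_S_PT=5.4 * MMHG))
        fm = solve_pressures(hex_mesh, params.with_(p_S_PT=4.9 * MMHG))
        scale = fm.pS_range()
        assert np.max(np.abs(0.5 * (f1.p_I + f2.p_I) - fm.p_I)) < 1e-10 * scale
        assert np.max(np.abs(0.5 * (f1.p_S[0] + f2.p_S[0]) - fm.p_S[0])) < 1e-10 * scale

    def test_doubling_sinusoidal_permeability_doubles_velocity(self, params, hex_mesh):
        f = solve_pressures(hex_mesh, params)
        v1 = compute_darcy_velocities(f)
        v2 = compute_darcy_velocities(f, params.with_(k_S=2 * params.k_S,
                                                     k_I=params.k_I))
        assert np.allclose(v2.u_S[0], 2.0 * v1.u_S[0], rtol=1e-14)

    def test_maximum_principle_for_blood_pressure(self, params, hex_mesh):
        f = solve_pressures(hex_mesh, params)
        lo = min(params.p_S_CV, float(f.p_I.min()))
        assert f.p_S[0].min() >= lo - 1e-9
        assert f.p_S[0].max() <= params.p_S_PT + 1e-9


class TestConservation:
    def test_blood_mass_balance(self, params, hex_mesh):
        f = solve_pressures(hex_mesh, params)
        ipt = blood_boundary_influx(f, BoundaryTag.PT_WALL)
        icv = blood_boundary_influx(f, BoundaryTag.CV_WALL)
        qw = filtration_integral(f)
        assert abs(ipt + icv - qw) < 1e-8 * abs(ipt)

    def test_interstitial_mass_balance_closed_lobule(self, params, hex_mesh):
        f = solve_pressures(hex_mesh, params)
        qw = filtration_integral(f)
        ql = lymph_uptake_integral(f)
        assert abs(qw - ql) < 1e-8 * abs(qw)

    @pytest.mark.parametrize("kind", list(SurfaceKind))
    def test_interstitial_balance_with_surface_outflow(self, params, kind):
        from lobuleflow.geometry import build_surface_slab

        slab = build_surface_slab(params, kind, 3)
        mesh = generate_mesh(slab, H)
        f = solve_pressures(mesh, params, surface_kind=kind)
        qw = filtration_integral(f)
        ql = lymph_uptake_integral(f)
        surf = interstitial_surface_outflow(f)
        assert abs(qw - ql - surf) < 1e-8 * abs(qw)
        assert surf > 0.0


class TestActiveSet:
    def test_high_lymph_pressure_shuts_off_uptake(self, params, hex_mesh):
        ph = params.with_(p_0=5.0 * MMHG)   # above any interstitial pressure
        f = solve_pressures(hex_mesh, ph)
        assert not f.active_lymph_mask.any()
        assert lymph_uptake_integral(f) == 0.0

    def test_partial_activity_is_consistent_with_pressures(self, params, hex_mesh):
        pm = params.with_(p_0=3.2 * MMHG)   # inside the interstitial range
        f = solve_pressures(hex_mesh, pm)
        assert f.active_lymph_mask.any()
        assert not f.active_lymph_mask.all()
        assert np.all(f.p_I[f.active_lymph_mask] > pm.p_0)
        assert np.all(f.p_I[~f.active_lymph_mask] <= pm.p_0 + 1e-12)
        ex = compute_exchange_fields(f)
        assert np.all(ex.q_l >= 0.0)
        assert np.all(ex.q_l[~f.active_lymph_mask] == 0.0)

    def test_active_set_converges_in_few_iterations(self, params, hex_mesh):
        f = solve_pressures(hex_mesh, params.with_(p_0=3.2 * MMHG))
        assert f.iterations <= 10


class TestSingularConfigurations:
    def test_pure_neumann_interstitium_rejected(self, params, hex_mesh):
        with pytest.raises(SingularSystemError):
            solve_pressures(hex_mesh, params.with_(C_f=0.0, C_l=0.0))


class TestOracleEquivalence:
    def test_annulus_solution_matches_closed_form(self, params):
        """Coupled FEM on an annulus vs the exact radial solution (< 0.5% Linf)."""
        r_in, r_out = params.D_CV / 2, 0.9 * params.L_lob
        n_out = 128
        ang = np.linspace(0, 2 * math.pi, n_out, endpoint=False)
        cell = Cell("annulus",
                    [(r_out * math.cos(a), r_out * math.sin(a)) for a in ang],
                    [BoundaryTag.PT_WALL] * n_out,
                    [Circle((0.0, 0.0), r_in, VesselKind.CV)])
        mesh = generate_mesh(cell, 8e-6)
        f = solve_pressures(mesh, params)
        ref = annulus_reference_solution(params, r_in, r_out,
                                         params.p_S_CV, params.p_S_PT)
        r = np.hypot(*mesh.cells[0].points.T)
        S, I = ref.interp(r)
        rng = float(np.ptp(ref.p_S))
        assert np.max(np.abs(f.p_S[0] - S)) / rng < 5e-3
        assert np.max(np.abs(f.p_I[mesh.pI_maps[0]] - I)) / rng < 5e-3


@pytest.fixture(scope="module")
def variant_pair(params):
    geo = build_hexagonal_lobule(params)
    mesh_std = generate_mesh(geo, 10e-6)
    mesh_var = generate_mesh(geo, 10e-6, include_vessel_interiors=True)
    f_std = solve_pressures(mesh_std, params)
    f_var = solve_variant_vessel_interstitium(mesh_var, params)
    return f_std, f_var


class TestVesselInterstitiumVariant:
    def test_lymph_production_increases_by_about_one_percent(self, variant_pair):
        f_std, f_var = variant_pair
        rel = lymph_uptake_integral(f_var) / lymph_uptake_integral(f_std) - 1.0
        assert 0.005 < rel < 0.02

    def test_blood_flux_change_is_much_smaller(self, variant_pair):
        f_std, f_var = variant_pair
        qb_rel = abs(blood_boundary_influx(f_var, BoundaryTag.PT_WALL) /
                     blood_boundary_influx(f_std, BoundaryTag.PT_WALL) - 1.0)
        ql_rel = abs(lymph_uptake_integral(f_var) /
                     lymph_uptake_integral(f_std) - 1.0)
        assert qb_rel < 0.1 * ql_rel

    def test_variant_requires_vessel_patches(self, params, hex_mesh):
        from lobuleflow.solver import SolverError

        with pytest.raises(SolverError):
            solve_variant_vessel_interstitium(hex_mesh, params)
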