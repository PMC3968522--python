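"""Sweeps, lattice comparison, bare-area effect, determinism."""

import numpy as np
import pytest

from lobuleflow.experiments import (
    bare_area_effect,
    compare_square_lattice,
    run_single_lobule,
    sweep_portal_pressure,
    sweep_scalar,
)
from lobuleflow.parameters import MMHG, PhysiologicalParameters

H = 18e-6   # coarse but adequate for signs and linearity


@pytest.fixture(scope="module")
def params():
    return PhysiologicalParameters()


@pytest.fixture(scope="module")
def sweep(params):
    return sweep_portal_pressure(np.array([3.9, 4.4, 4.9]), params, H)


class TestPortalPressureSweep:
    def test_fluxes_increase_with_portal_pressure(self, sweep):
        assert sweep.monotonicity["Q_L_ml_min"] == 1
        assert sweep.monotonicity["Q_surface_ml_min"] == 1
        assert sweep.monotonicity["Q_blood_l_min"] == 1

    def test_response_is_affine_while_fully_active(self, sweep):
        """The solution map is affine in the Dirichlet data, so the linear
        fit must be exact to rounding."""
        for col in ("Q_L_ml_min", "Q_surface_ml_min"):
            assert sweep.fit_residuals[col] < 1e-9 * abs(sweep.slopes[col])

    def test_slopes_have_physiological_magnitude(self, sweep):
        assert 0.01 < sweep.slopes["Q_L_ml_min"] < 0.1
        assert 0.01 < sweep.slopes["Q_surface_ml_min"] < 0.1

    def test_values_must_bracket_baseline(self, params):
        with pytest.raises(ValueError):
            sweep_portal_pressure(np.array([5.0, 6.0]), params, H)


class TestScalarSweeps:
    def test_portal_tract_size_raises_lymph_fluxes(self, params):
        res = sweep_scalar("D_PT", np.array([40e-6, 50e-6, 62.5e-6]), params, H)
        assert res.monotonicity["Q_L_ml_min"] == 1
        assert res.monotonicity["Q_surface_ml_min"] == 1
        assert res.monotonicity["Q_blood_l_min"] == 1

    def test_central_vein_size_lowers_lymph_but_raises_blood(self, params):
        res = sweep_scalar("D_CV", np.array([60e-6, 75e-6, 93.75e-6]), params, H)
        assert res.monotonicity["Q_L_ml_min"] == -1
        assert res.monotonicity["Q_surface_ml_min"] == -1
        assert res.monotonicity["Q_blood_l_min"] == 1

    def test_joint_diameter_scaling_barely_moves_lymph(self, params):
        res = sweep_scalar("vessel_diameters", np.array([0.8, 1.0, 1.25]),
                           params, H)
        q = res.table["Q_L_ml_min"].to_numpy()
        spread = np.ptp(q) / q[1]
        # opposing PT and CV effects partially cancel under joint scaling
        single = sweep_scalar("D_PT", np.array([40e-6, 50e-6, 62.5e-6]),
                              params, H, with_surface=False)
        qs = single.table["Q_L_ml_min"].to_numpy()
        assert spread < 0.8 * np.ptp(qs) / qs[1]

    def test_external_pressure_reverses_surface_flux_but_not_uptake(self, params):
        vals = np.array([0.0, 2.0, 5.0]) * MMHG
        res = sweep_scalar("p_ext", vals, params, H)
        q_surf = res.table["Q_surface_ml_min"].to_numpy()
        q_L = res.table["Q_L_ml_min"].to_numpy()
        assert res.monotonicity["Q_surface_ml_min"] == -1
        assert q_surf[-1] < 0.0           # reversal at high ascitic pressure
        assert np.ptp(q_L) / q_L[0] < 0.02

    def test_lymph_pressure_linearly_extinguishes_uptake(self, params):
        vals = np.array([0.0, 1.5, 3.0, 4.0]) * MMHG
        res = sweep_scalar("p_0", vals, params, H, with_surface=False)
        q = res.table["Q_L_ml_min"].to_numpy()
        assert np.all(np.diff(q) < 0)
        assert q[-1] == pytest.approx(0.0, abs=1e-12)
        # approximately linear while fully active
        slope01 = q[1] - q[0]
        slope12 = q[2] - q[1]
        assert slope12 == pytest.approx(slope01, rel=0.15)

    def test_interstitial_permeability_moves_surface_flux_only(self, params):
        k = 0.002 * params.k_S
        res = sweep_scalar("k_I", np.array([0.04 * k, k, 2.0 * k]), params, H)
        q_L = res.table["Q_L_ml_min"].to_numpy()
        q_surf = res.table["Q_surface_ml_min"].to_numpy()
        assert np.ptp(q_L) / q_L[1] < 0.005
        assert np.all(np.diff(q_surf) > 0)
        assert q_surf[0] < 0.5 * q_surf[1]   # tends to zero with k_I

    def test_infeasible_values_are_skipped_and_logged(self, params):
        res = sweep_scalar("D_PT", np.array([50e-6, 600e-6]), params, H,
                           with_surface=False)
        assert len(res.table) == 1
        assert "600" in res.provenance["skipped"] or "0.0006" in res.provenance["skipped"]

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ValueError):
            sweep_scalar("mu_S", [1.0], params, H)


class TestStructuralComparisons:
    def test_square_lattice_reduces_all_fluxes(self, params):
        res = compare_square_lattice(params, H)
        assert 15.0 < res["Q_blood_reduction_percent"] < 35.0
        assert 5.0 < res["Q_L_reduction_percent"] < 20.0
        assert 5.0 < res["Q_surface_reduction_percent"] < 20.0

    def test_bare_area_raises_surface_and_total_lymph(self, params):
        tbl = bare_area_effect((0.0, 0.2), params, H)
        assert tbl.loc[0.0, "Q_surface_increase_percent"] == 0.0
        assert tbl.loc[0.0, "Q_liver_lymph_increase_percent"] == 0.0
        assert tbl.loc[0.2, "Q_surface_increase_percent"] > 0.0
        assert tbl.loc[0.2, "Q_liver_lymph_increase_percent"] > 0.0
        # surface share responds more strongly than the total
        assert (tbl.loc[0.2, "Q_surface_increase_percent"] >
                tbl.loc[0.2, "Q_liver_lymph_increase_percent"])


class TestDeterminism:
    def test_identical_runs_are_bit_identical(self, params):
        r1 = run_single_lobule(params, H)
        r2 = run_single_lobule(params, H)
        assert r1.Q_blood == r2.Q_blood
        assert r1.Q_L == r2.Q_L
        assert np.array_equal(r1.fields.p_I, r2.fields.p_I)

    def test_sweep_carries_provenance(self, params):
        res = sweep_scalar("p_0", np.array([0.0, 1.0 * MMHG]), params, H,
                           with_surface=False)
        assert "config_hash" in res.provenance
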