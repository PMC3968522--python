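"""Closed-form oracles: validation against brute-force 1D discretizations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobuleflow.analytic import (
    annulus_fd_solution,
    annulus_reference_solution,
    boundary_layer_decay_length,
    half_space_boundary_layer_solution,
    half_space_fd_solution,
    mean_interstitial_pressure,
)
from lobuleflow.parameters import MMHG, PhysiologicalParameters

R_IN, R_OUT = 37.5e-6, 450e-6
P_IN, P_OUT = 1.5 * MMHG, 4.4 * MMHG


@pytest.fixture(scope="module")
def params():
    return PhysiologicalParameters()


class TestDecayLength:
    def test_baseline_value_is_a_few_hundred_micrometres(self, params):
        lam = boundary_layer_decay_length(params)
        # surface effects confined to within roughly one lobule of the surface
        assert 100e-6 < lam < 400e-6

    def test_formula(self, params):
        a, b = params.kappa_S, params.kappa_I
        lam = boundary_layer_decay_length(params)
        assert lam == pytest.approx(math.sqrt(a * b / (params.C_f * (a + b))))

    def test_infinite_without_filtration(self, params):
        assert math.isinf(boundary_layer_decay_length(params.with_(C_f=0.0)))


class TestAnnulus:
    def test_matches_dense_fd_oracle(self, params):
        cf = annulus_reference_solution(params, R_IN, R_OUT, P_IN, P_OUT)
        fd = annulus_fd_solution(params, R_IN, R_OUT, P_IN, P_OUT, n=20000)
        S, I = cf.interp(fd.r)
        rng = np.ptp(fd.p_S)
        # agreement is limited by the FD oracle's own O(h^2) error
        assert np.max(np.abs(S - fd.p_S)) / rng < 5e-5
        assert np.max(np.abs(I - fd.p_I)) / rng < 5e-5

    def test_boundary_conditions_satisfied_exactly(self, params):
        cf = annulus_reference_solution(params, R_IN, R_OUT, P_IN, P_OUT)
        assert cf.p_S[0] == pytest.approx(P_IN, rel=1e-10)
        assert cf.p_S[-1] == pytest.approx(P_OUT, rel=1e-10)

    def test_no_filtration_reduces_to_log_harmonic(self, params):
        p0 = params.with_(C_f=0.0)
        cf = annulus_reference_solution(p0, R_IN, R_OUT, P_IN, P_OUT)
        expected = P_IN + (P_OUT - P_IN) * np.log(cf.r / R_IN) / math.log(R_OUT / R_IN)
        assert np.allclose(cf.p_S, expected, rtol=1e-12)
        assert np.allclose(cf.p_I, p0.p_0)

    def test_no_uptake_makes_mobility_combination_harmonic(self, params):
        """With C_l = 0, a p_S + b p_I is harmonic: it must fit c0 + c1 ln r."""
        p0 = params.with_(C_l=0.0)
        cf = annulus_reference_solution(p0, R_IN, R_OUT, P_IN, P_OUT)
        comb = p0.kappa_S * cf.p_S + p0.kappa_I * cf.p_I
        X = np.column_stack([np.ones_like(cf.r), np.log(cf.r)])
        coef, *_ = np.linalg.lstsq(X, comb, rcond=None)
        resid = np.max(np.abs(comb - X @ coef)) / np.ptp(comb)
        assert resid < 1e-10

    def test_invalid_radii_rejected(self, params):
        with pytest.raises(ValueError):
            annulus_reference_solution(params, R_OUT, R_IN, P_IN, P_OUT)

    def test_inactive_regime_rejected(self, params):
        # lymph pressure far above anything the annulus can sustain
        ph = params.with_(p_0=10.0 * MMHG)
        with pytest.raises(ValueError):
            annulus_reference_solution(ph, R_IN, R_OUT, P_IN, P_OUT)


class TestHalfSpace:
    def test_matches_dense_fd_oracle(self, params):
        lam = boundary_layer_decay_length(params)
        Z = 12 * lam
        cf = half_space_boundary_layer_solution(params, 3.3 * MMHG,
                                                params.M_GP, 0.0, depth=Z)
        fd = half_space_fd_solution(params, 3.3 * MMHG, params.M_GP, 0.0, Z,
                                    n=20000)
        S, I = cf.interp(fd.r)
        rng = np.ptp(fd.p_I)
        assert np.max(np.abs(I - fd.p_I)) / rng < 1e-3
        assert np.max(np.abs(S - fd.p_S)) / rng < 1e-3

    def test_zero_conductance_gives_flat_profile(self, params):
        p0 = params.with_(C_l=0.0)
        cf = half_space_boundary_layer_solution(p0, 3.3 * MMHG, 0.0, 0.0,
                                                depth=2e-3)
        assert np.ptp(cf.p_S) < 1e-10 * MMHG
        assert np.ptp(cf.p_I) < 1e-10 * MMHG

    def test_infinite_conductance_pins_wall_to_external_pressure(self, params):
        p_ext = 0.7 * MMHG
        cf = half_space_boundary_layer_solution(params, 3.3 * MMHG,
                                                math.inf, p_ext)
        assert cf.p_I[0] == pytest.approx(p_ext, rel=1e-9)

    def test_wall_pressure_decreases_monotonically_with_conductance(self, params):
        walls = [half_space_boundary_layer_solution(params, 3.3 * MMHG, M, 0.0).p_I[0]
                 for M in (0.25 * params.M_GP, params.M_GP, 4 * params.M_GP, math.inf)]
        assert all(w1 > w2 for w1, w2 in zip(walls, walls[1:]))
        assert walls[-1] == pytest.approx(0.0, abs=1e-9)

    def test_difference_field_decays_at_the_screening_length(self, params):
        """log-slope of |p_S - p_I - far_offset| near the wall ~ 1/lambda."""
        lam = boundary_layer_decay_length(params)
        cf = half_space_boundary_layer_solution(params, 3.3 * MMHG,
                                                math.inf, 0.0, n_samples=2000)
        d = cf.p_S - cf.p_I
        d_far = d[len(d) // 2]
        y = np.abs(d - d_far)
        sel = (cf.r > 0.5 * lam) & (cf.r < 2.0 * lam)
        slope = np.polyfit(cf.r[sel], np.log(y[sel]), 1)[0]
        assert -slope == pytest.approx(1.0 / lam, rel=0.05)

    def test_negative_conductance_rejected(self, params):
        with pytest.raises(ValueError):
            half_space_boundary_layer_solution(params, 3.3 * MMHG, -1.0, 0.0)


class TestMeanInterstitialPressure:
    def test_equal_coefficients_halve_the_mean(self, params):
        p = params.with_(C_f=1e-6, C_l=1e-6, p_0=0.0)
        assert mean_interstitial_pressure(p, 3.0) == pytest.approx(1.5)

    def test_no_uptake_equilibrates_with_blood(self, params):
        p = params.with_(C_l=0.0)
        assert mean_interstitial_pressure(p, 3.3) == pytest.approx(3.3)

    def test_no_filtration_equilibrates_with_lymph(self, params):
        p = params.with_(C_f=0.0, p_0=2.0)
        assert mean_interstitial_pressure(p, 3.3) == pytest.approx(2.0)

    def test_degenerate_coefficients_guarded(self, params):
        with pytest.raises(ZeroDivisionError):
            mean_interstitial_pressure(params.with_(C_f=0.0, C_l=0.0), 3.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cf=st.floats(1e-9, 1e-3), cl=st.floats(1e-9, 1e-3),
           ps=st.floats(0.0, 10.0), p0=st.floats(0.0, 10.0))
    def test_mean_lies_between_blood_and_lymph_pressures(self, cf, cl, ps, p0):
        p = PhysiologicalParameters(C_f=cf, C_l=cl, p_0=p0)
        m = mean_interstitial_pressure(p, ps)
        assert min(ps, p0) - 1e-12 <= m <= max(ps, p0) + 1e-12
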