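"""Closed-form reference solutions used to verify the finite-element core.

The coupled system

.. math::

    a \\nabla^2 p_S = C_f (p_S - p_I), \\qquad
    b \\nabla^2 p_I = -C_f (p_S - p_I) + C_l (p_I - p_0),

with mobilities ``a = k_S/mu_S`` and ``b = k_I/mu_I`` and a fully active
lymph uptake, is linear, and after subtracting the constant particular
solution ``(p_0, p_0)`` reduces to ``\\nabla^2 x = A x`` with

.. math::

    A = \\begin{pmatrix} C_f/a & -C_f/a \\\\ -C_f/b & (C_f + C_l)/b
    \\end{pmatrix}.

Both eigenvalues of ``A`` are positive when ``C_l > 0``; the radial
solutions are modified Bessel functions ``I_0, K_0`` of the two screening
rates and the 1D solutions are exponentials.  For ``C_l = 0`` the matrix is
singular and the harmonic pair ``(1, 1)(alpha + beta ln r)`` replaces the
slow mode; the remaining screened mode has eigenvector ``(b, -a)`` and rate
``kappa^2 = C_f (a + b)/(a b)``, whose inverse

.. math::

    \\lambda = \\sqrt{\\frac{k_S k_I / (\\mu_S \\mu_I)}
                           {C_f (k_S/\\mu_S + k_I/\\mu_I)}}

is the decay length of the sinusoidal/interstitial pressure difference,
i.e. of surface effects penetrating the tissue.

Every closed form here is independently validated against a dense 1D
finite-difference discretization before being trusted to judge the 2D
solver (see the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import i0, i1, k0, k1

from .parameters import PhysiologicalParameters


@dataclass
class RadialProfile:
    """Sampled reference solution (radial or 1D-in-depth)."""

    r: np.ndarray
    p_S: np.ndarray
    p_I: np.ndarray
    decay_length: float | None = None

    def interp(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.interp(r, self.r, self.p_S), np.interp(r, self.r, self.p_I))


def boundary_layer_decay_length(params: PhysiologicalParameters) -> float:
    """lambda = sqrt[(k_S k_I/(mu_S mu_I)) / (C_f (k_S/mu_S + k_I/mu_I))] [m]."""
    a, b = params.kappa_S, params.kappa_I
    if params.C_f == 0.0:
        return math.inf
    return math.sqrt(a * b / (params.C_f * (a + b)))


def mean_interstitial_pressure(params: PhysiologicalParameters,
                               mean_p_S: float) -> float:
    """Closed-form spatial mean of p_I for a lobule with fully active uptake."""
    denom = params.C_f + params.C_l
    if denom == 0.0:
        raise ZeroDivisionError("mean interstitial pressure undefined for "
                                "C_f = C_l = 0")
    return (params.C_f * mean_p_S + params.C_l * params.p_0) / denom


# ---------------------------------------------------------------------------
# annulus
# ---------------------------------------------------------------------------

def annulus_reference_solution(params: PhysiologicalParameters,
                               r_inner: float, r_outer: float,
                               p_S_inner: float, p_S_outer: float,
                               n_samples: int = 400) -> RadialProfile:
    """Exact axisymmetric solution on an annulus.

    Boundary conditions: ``p_S`` Dirichlet at both radii, ``p_I`` zero flux
    at both radii; lymph uptake assumed fully active (``p_I > p_0``
    everywhere), which is verified on the result and rejected otherwise.
    """
    if not 0.0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    a, b = params.kappa_S, params.kappa_I
    Cf, Cl, p0 = params.C_f, params.C_l, params.p_0
    r = np.linspace(r_inner, r_outer, n_samples)

    if Cf == 0.0:
        # decoupled: log-harmonic blood pressure, equilibrium interstitium
        ln = np.log(r / r_inner) / math.log(r_outer / r_inner)
        pS = p_S_inner + (p_S_outer - p_S_inner) * ln
        pI = np.full_like(r, p0)
        return RadialProfile(r, pS, pI, boundary_layer_decay_length(params))

    if Cl == 0.0:
        # modes: harmonic pair (1,1)(c0 + c1 ln r) and screened (b, -a) mode
        kap = math.sqrt(Cf * (a + b) / (a * b))

        def basis(rv):
            # rows: [pS, pI, pI'], columns: the four coefficients
            return np.array([
                [1.0, math.log(rv), b * i0(kap * rv), b * k0(kap * rv)],
                [1.0, math.log(rv), -a * i0(kap * rv), -a * k0(kap * rv)],
                [0.0, 1.0 / rv, -a * kap * i1(kap * rv), a * kap * k1(kap * rv)],
            ])

        shift = 0.0
    else:
        lam, V = np.linalg.eig(np.array([[Cf / a, -Cf / a],
                                         [-Cf / b, (Cf + Cl) / b]]))
        if np.any(lam <= 0):
            raise ValueError("expected positive screening rates")
        kk = np.sqrt(lam)

        def basis(rv):
            row_S, row_I, row_dI = [], [], []
            for m in range(2):
                vS, vI = V[0, m], V[1, m]
                row_S += [vS * i0(kk[m] * rv), vS * k0(kk[m] * rv)]
                row_I += [vI * i0(kk[m] * rv), vI * k0(kk[m] * rv)]
                row_dI += [vI * kk[m] * i1(kk[m] * rv),
                           -vI * kk[m] * k1(kk[m] * rv)]
            return np.array([row_S, row_I, row_dI])

        shift = p0

    Bin = basis(r_inner)
    Bout = basis(r_outer)
    M = np.vstack([Bin[0], Bout[0], Bin[2], Bout[2]])
    rhs = np.array([p_S_inner - shift, p_S_outer - shift, 0.0, 0.0])
    coef = np.linalg.solve(M, rhs)

    pS = np.array([basis(rv)[0] @ coef for rv in r]) + shift
    pI = np.array([basis(rv)[1] @ coef for rv in r]) + shift
    if Cl > 0.0 and np.any(pI <= p0):
        raise ValueError("parameter regime breaks full lymph-uptake activity; "
                         "the closed form does not apply")
    return RadialProfile(r, pS, pI, boundary_layer_decay_length(params))


def annulus_fd_solution(params: PhysiologicalParameters,
                        r_inner: float, r_outer: float,
                        p_S_inner: float, p_S_outer: float,
                        n: int = 10000) -> RadialProfile:
    """Brute-force radial finite-difference oracle for the annulus problem.

    Independent of the closed form: discretizes the radial operator
    ``(1/r) d/dr (r d/dr)`` with second-order differences on a fine grid and
    solves the coupled linear system (fully active uptake).
    """
    a, b = params.kappa_S, params.kappa_I
    Cf, Cl, p0 = params.C_f, params.C_l, params.p_0
    r = np.linspace(r_inner, r_outer, n)
    h = r[1] - r[0]

    def radial_lap(coef):
        rp = r[1:-1] + 0.5 * h
        rm = r[1:-1] - 0.5 * h
        main = np.zeros(n)
        lo = np.zeros(n - 1)
        up = np.zeros(n - 1)
        main[1:-1] = -coef * (rp + rm) / (r[1:-1] * h * h)
        lo[:-1] = coef * rm / (r[1:-1] * h * h)
        up[1:] = coef * rp / (r[1:-1] * h * h)
        return sp.diags([lo, main, up], [-1, 0, 1], format="lil")

    LS = radial_lap(a)
    LI = radial_lap(b)
    n2 = 2 * n
    A = sp.lil_matrix((n2, n2))
    rhs = np.zeros(n2)
    A[:n, :n] = -LS
    A[n:, n:] = -LI
    for i in range(1, n - 1):
        A[i, i] += Cf
        A[i, n + i] -= Cf
        A[n + i, i] -= Cf
        A[n + i, n + i] += Cf + Cl
        rhs[n + i] = Cl * p0
    # p_S Dirichlet
    A[0, 0] = 1.0
    rhs[0] = p_S_inner
    A[n - 1, n - 1] = 1.0
    rhs[n - 1] = p_S_outer
    # p_I one-sided second-order zero-gradient
    A[n, n:n + 3] = [-3.0, 4.0, -1.0]
    A[n2 - 1, n2 - 3:] = [1.0, -4.0, 3.0]
    rhs[n] = rhs[n2 - 1] = 0.0
    x = spla.spsolve(A.tocsc(), rhs)
    return RadialProfile(r, x[:n], x[n:], boundary_layer_decay_length(params))


# ---------------------------------------------------------------------------
# half-space boundary layer
# ---------------------------------------------------------------------------

def half_space_boundary_layer_solution(params: PhysiologicalParameters,
                                       far_field_p_S: float,
                                       M: float, p_ext: float,
                                       depth: float | None = None,
                                       n_samples: int = 400) -> RadialProfile:
    """1D boundary-layer solution below a flat liver surface.

    Depth coordinate ``z >= 0`` with the surface at ``z = 0``.  Boundary
    conditions: no blood flux at the wall; interstitial Robin
    ``b p_I'(0) = M (p_I(0) - p_ext)`` (Dirichlet for ``M = inf``); at the
    truncation depth ``p_S`` is pinned to the far-field value and ``p_I``
    has zero flux.  The default depth is 12 boundary-layer decay lengths,
    deep enough that the wall no longer feels the truncation.
    """
    if M < 0.0:
        raise ValueError("surface conductance M must be non-negative")
    a, b = params.kappa_S, params.kappa_I
    Cf, Cl, p0 = params.C_f, params.C_l, params.p_0
    lam = boundary_layer_decay_length(params)
    if depth is None:
        if not math.isfinite(lam):
            raise ValueError("specify a depth when C_f = 0")
        depth = 12.0 * lam
    Z = float(depth)
    z = np.linspace(0.0, Z, n_samples)

    if Cl == 0.0:
        kap = math.sqrt(Cf * (a + b) / (a * b))

        def basis(zv):
            e0 = math.exp(-kap * zv)
            e1 = math.exp(-kap * (Z - zv))
            return np.array([
                [1.0, zv, b * e0, b * e1],
                [1.0, zv, -a * e0, -a * e1],
                [0.0, 1.0, -b * kap * e0, b * kap * e1],     # pS'
                [0.0, 1.0, a * kap * e0, -a * kap * e1],     # pI'
            ])

        shift = 0.0
    else:
        lamv, V = np.linalg.eig(np.array([[Cf / a, -Cf / a],
                                          [-Cf / b, (Cf + Cl) / b]]))
        kk = np.sqrt(lamv)

        def basis(zv):
            rS, rI, rdS, rdI = [], [], [], []
            for m in range(2):
                vS, vI = V[0, m], V[1, m]
                e0 = math.exp(-kk[m] * zv)
                e1 = math.exp(-kk[m] * (Z - zv))
                rS += [vS * e0, vS * e1]
                rI += [vI * e0, vI * e1]
                rdS += [-vS * kk[m] * e0, vS * kk[m] * e1]
                rdI += [-vI * kk[m] * e0, vI * kk[m] * e1]
            return np.array([rS, rI, rdS, rdI])

        shift = p0

    B0 = basis(0.0)
    BZ = basis(Z)
    rows = [B0[2]]                      # no blood flux at the wall
    rhs = [0.0]
    if math.isinf(M):
        rows.append(B0[1])
        rhs.append(p_ext - shift)
    else:
        # b p_I'(0) = M (p_I(0) - p_ext)
        rows.append(b * B0[3] - M * B0[1])
        rhs.append(M * (shift - p_ext))
    rows.append(BZ[0])                  # far-field blood pressure
    rhs.append(far_field_p_S - shift)
    rows.append(BZ[3])                  # no interstitial flux at depth
    rhs.append(0.0)
    coef = np.linalg.solve(np.array(rows), np.array(rhs))

    pS = np.array([basis(zv)[0] @ coef for zv in z]) + shift
    pI = np.array([basis(zv)[1] @ coef for zv in z]) + shift
    return RadialProfile(z, pS, pI, lam)


def half_space_fd_solution(params: PhysiologicalParameters,
                           far_field_p_S: float, M: float, p_ext: float,
                           depth: float, n: int = 20000) -> RadialProfile:
    """Dense 1D finite-difference oracle for the half-space problem."""
    a, b = params.kappa_S, params.kappa_I
    Cf, Cl, p0 = params.C_f, params.C_l, params.p_0
    z = np.linspace(0.0, depth, n)
    h = z[1] - z[0]
    n2 = 2 * n
    A = sp.lil_matrix((n2, n2))
    rhs = np.zeros(n2)
    for i in range(1, n - 1):
        A[i, i - 1] = A[i, i + 1] = -a / h**2
        A[i, i] = 2 * a / h**2 + Cf
        A[i, n + i] = -Cf
        A[n + i, n + i - 1] = A[n + i, n + i + 1] = -b / h**2
        A[n + i, n + i] = 2 * b / h**2 + Cf + Cl
        A[n + i, i] = -Cf
        rhs[n + i] = Cl * p0
    A[0, 0:3] = [-3.0, 4.0, -1.0]                      # pS'(0) = 0
    if math.isinf(M):
        A[n, n] = 1.0
        rhs[n] = p_ext
    else:
        # b (-3 pI0 + 4 pI1 - pI2)/(2h) = M (pI0 - p_ext)
        A[n, n] = -1.5 * b / h - M
        A[n, n + 1] = 2.0 * b / h
        A[n, n + 2] = -0.5 * b / h
        rhs[n] = -M * p_ext
    A[n - 1, n - 1] = 1.0
    rhs[n - 1] = far_field_p_S
    A[n2 - 1, n2 - 3:] = [1.0, -4.0, 3.0]              # pI'(Z) = 0
    x = spla.spsolve(A.tocsc(), rhs)
    return RadialProfile(z, x[:n], x[n:],
                         boundary_layer_decay_length(params))
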