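"""Physiological parameter set for the lobule perfusion model.

All quantities are stored internally in SI units (pressures in Pa,
conductances per Pa); the constructors convert from the conventional
physiological units (mmHg) used in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dc_fields

#: Pa per mmHg.
MMHG = 133.322387415

#: Pa per cmH2O (conventional value).
CMH2O = 98.0665


@dataclass(frozen=True)
class PhysiologicalParameters:
    """Parameter set for one model run (SI units).

    Attributes
    ----------
    L_lob:
        Distance between neighbouring portal tracts = hexagon side length [m].
    D_PT, D_CV:
        Diameters of the portal tracts and the central vein [m].
    V_liv, A_liv:
        Total liver tissue volume [m^3] and liver surface area [m^2].
    chi:
        Fraction of the liver surface occupied by the bare area (the rest is
        covered by the Glisson--peritoneal membrane).
    k_S, k_I:
        Darcy permeabilities of the sinusoidal and interstitial compartments
        [m^2].
    mu_S, mu_I:
        Dynamic viscosities of sinusoidal blood and interstitial plasma
        [Pa s].
    C_f:
        Hepatic filtration coefficient: volume flux from sinusoids to
        interstitium per unit pressure difference per unit tissue volume
        [1/(Pa s)].
    C_l:
        Lymphatic conductance: uptake rate per unit excess interstitial
        pressure over ``p_0`` per unit tissue volume [1/(Pa s)].
    p_0:
        Pressure of the flowing lymph; uptake is clamped to zero where
        ``p_I <= p_0`` [Pa].
    p_S_PT, p_S_CV:
        Prescribed sinusoidal pressures at the portal tracts and at the
        central veins [Pa].
    M_BA, M_GP:
        Hydraulic conductances of the bare area and of the Glisson--
        peritoneal membrane [m/(s Pa)]; ``M_BA = inf`` denotes the
        perfectly conducting (Dirichlet) limit.
    p_DS, p_PC:
        Pressures in the diaphragmatic space and the peritoneal cavity [Pa].
    """

    L_lob: float = 500e-6
    D_PT: float = 50e-6
    D_CV: float = 75e-6
    V_liv: float = 1474e-6
    A_liv: float = 1190e-4
    chi: float = 0.2
    k_S: float = 1.56e-14
    k_I: float = 0.002 * 1.56e-14
    mu_S: float = 0.0024
    mu_I: float = 0.0018
    C_f: float = 5.3e-5 / MMHG
    C_l: float = 5.9e-7 / MMHG
    p_0: float = 0.0
    p_S_PT: float = 4.4 * MMHG
    p_S_CV: float = 1.5 * MMHG
    M_BA: float = math.inf
    M_GP: float = 2.15e-8 / MMHG
    p_DS: float = 0.0
    p_PC: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("L_lob", "D_PT", "D_CV", "V_liv", "A_liv",
                    "k_S", "k_I", "mu_S", "mu_I")
        for name in positive:
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("C_f", "C_l", "M_GP"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.M_BA < 0.0:
            raise ValueError("M_BA must be non-negative (or inf)")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError(f"chi must lie in [0, 1], got {self.chi}")
        # Necessary condition; detailed feasibility is re-checked geometrically.
        if self.D_CV + self.D_PT >= 2.0 * self.L_lob:
            raise ValueError("vessel diameters too large for the lobule")

    # -- convenience -----------------------------------------------------

    @property
    def kappa_S(self) -> float:
        """Sinusoidal mobility k_S / mu_S [m^2/(Pa s)]."""
        return self.k_S / self.mu_S

    @property
    def kappa_I(self) -> float:
        """Interstitial mobility k_I / mu_I [m^2/(Pa s)]."""
        return self.k_I / self.mu_I

    @property
    def lobule_cross_section(self) -> float:
        """Area of the full hexagonal lobule cross-section, 3*sqrt(3)/2 L^2 [m^2]."""
        return 1.5 * math.sqrt(3.0) * self.L_lob**2

    @property
    def whole_liver_scaling(self) -> float:
        """V_liv / (3*sqrt(3) L_lob^2 / 2): lobule axial length summed over the liver [m]."""
        return self.V_liv / self.lobule_cross_section

    def with_(self, **overrides: float) -> "PhysiologicalParameters":
        """Return a copy with the given SI-valued fields replaced.

        If ``k_S`` is overridden without an explicit ``k_I``, the interstitial
        permeability keeps the default proportionality ``k_I = 0.002 k_S``.
        """
        if "k_S" in overrides and "k_I" not in overrides:
            overrides["k_I"] = 0.002 * overrides["k_S"]
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}
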