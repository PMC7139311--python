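"""Internal unit system and physical constants.

Everything inside the package uses a single unit system:

==============  ======================
quantity        unit
==============  ======================
length          Å (angstrom)
energy          kJ mol⁻¹
charge          e (elementary charge)
mass            g mol⁻¹
time            ps
temperature     K
==============  ======================

Velocities are Å ps⁻¹ and angular momenta g mol⁻¹ Å² ps⁻¹.  Because
kinetic energy in (g mol⁻¹)(Å ps⁻¹)² is not numerically a kJ mol⁻¹, the
conversion factor :data:`ENERGY_TO_INTERNAL` (= 100 exactly) bridges the
two whenever potential-energy forces act on masses.  All user-facing
inputs (eV spring constants, mol L⁻¹ ionic strengths) are converted at
the API boundary.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kJ mol⁻¹ K⁻¹ (CODATA 2018, exact).
KB = 0.008_314_462_618

#: Coulomb prefactor k_e·e²·N_A in kJ mol⁻¹ Å: energy of two unit point
#: charges 1 Å apart in vacuum.
COULOMB = 1389.354_576_4

#: 1 eV per particle expressed in kJ mol⁻¹.
EV_TO_KJ_MOL = 96.485_332_12

#: 1 kJ mol⁻¹ expressed in internal kinetic units, g mol⁻¹ Å² ps⁻².
#: (1 kJ mol⁻¹ = 1000 J mol⁻¹ = 1000 · 10²⁰ Å²·kg / (10¹² ps)² ·10³ g/kg)
ENERGY_TO_INTERNAL = 100.0

# Raw SI constants used only for the Debye screening parameter.
_E_CHARGE = 1.602_176_634e-19  # C
_EPS0 = 8.854_187_8128e-12  # F m⁻¹
_KB_SI = 1.380_649e-23  # J K⁻¹
_N_AVOGADRO = 6.022_140_76e23  # mol⁻¹


def kT(temperature: float) -> float:
    """Thermal energy k_B·T in kJ mol⁻¹."""
    return KB * temperature


def debye_kappa(ionic_strength: float, temperature: float = 298.0,
                dielectric: float = 78.5) -> float:
    """Inverse Debye screening length κ in Å⁻¹.

    κ = sqrt(2·N_A·e²·I / (ε₀·ε_r·k_B·T)) with the ionic strength ``I``
    given in mol L⁻¹.  ``ionic_strength = 0`` returns 0 (unscreened
    Coulomb limit).

    For a 0.145 mol L⁻¹ electrolyte at 298 K in water (ε_r = 78.5) the
    screening length 1/κ is ≈ 8 Å, matching the 0.304/√I nm
    rule of thumb.
    """
    if ionic_strength < 0:
        raise ValueError(f"ionic strength must be >= 0, got {ionic_strength}")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if dielectric <= 0:
        raise ValueError(f"dielectric must be > 0, got {dielectric}")
    if ionic_strength == 0.0:
        return 0.0
    number_density = 1000.0 * ionic_strength * _N_AVOGADRO  # ions m⁻³
    kappa_sq = (2.0 * number_density * _E_CHARGE ** 2
                / (_EPS0 * dielectric * _KB_SI * temperature))  # m⁻²
    return math.sqrt(kappa_sq) * 1e-10  # Å⁻¹
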