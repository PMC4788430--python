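"""Physical constants and unit conventions.

Units used throughout the package:

* length      -- angstrom (A)
* energy      -- kcal/mol
* temperature -- kelvin
* charge      -- elementary charge units
* time        -- internal MD time unit tau; with bead masses of 1
                 kcal/mol * tau^2 / A^2 the thermal velocity at 300 K
                 is ~0.77 A/tau.
"""

#: Gas constant in kcal/mol/K.
GAS_CONSTANT = 1.98720e-3

#: Coulomb prefactor e^2/(4 pi eps0) in kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Avogadro's number (1/mol).
AVOGADRO = 6.02214076e23

#: e^2/(4 pi eps0 kB) in A*K -- Bjerrum length = this / (dielectric * T).
BJERRUM_PREFACTOR = COULOMB_CONSTANT / GAS_CONSTANT  # ~1.6714e5 A*K


def rt(temperature: float) -> float:
    """RT in kcal/mol at the given temperature."""
    return GAS_CONSTANT * temperature
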