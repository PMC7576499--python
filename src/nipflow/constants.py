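"""Physical constants and unit conversions used throughout the package.

Internally all permeabilities are in cm s^-1, lengths in cm (structures use
Angstrom), concentrations in mol cm^-3, energies in kcal mol^-1.
"""

import math

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.987e-3

#: Molar volume of water, cm^3 mol^-1.
VW_WATER: float = 18.07

#: osmol L^-1 -> mol cm^-3 (1 L = 1000 cm^3).
OSMOLAR_TO_MOL_PER_CM3: float = 1e-3

#: Celsius offset to kelvin.
CELSIUS_OFFSET: float = 273.15

#: Default volume-to-area ratio of a yeast cell, cm.  Sphere of radius
#: 2.5 um: V/A = r/3 = 8.3e-5 cm.
DEFAULT_V0_OVER_A: float = 8.3e-5


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def arrhenius_factor(ea_kcal: float, t_celsius: float, t_ref_celsius: float) -> float:
    """Multiplicative Arrhenius scaling of a rate from ``t_ref`` to ``t``.

    ``exp(-Ea/R * (1/T - 1/T_ref))`` with temperatures in kelvin; equals 1 at
    the reference temperature and is >1 above it for positive ``ea_kcal``.
    """
    t = celsius_to_kelvin(t_celsius)
    t_ref = celsius_to_kelvin(t_ref_celsius)
    return math.exp(-ea_kcal / R_KCAL * (1.0 / t - 1.0 / t_ref))
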