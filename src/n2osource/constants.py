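"""Physical and isotopic constants used throughout the package.

Single source of truth: every module imports from here, never redefines.
"""

from types import MappingProxyType

#: 15N/14N isotope ratio of atmospheric N2 (the AIR-N2 reference scale).
R15_AIR_N2: float = 0.0036765

#: 18O/16O and 17O/16O ratios of Vienna Standard Mean Ocean Water.
R18_VSMOW: float = 0.0020052
R17_VSMOW: float = 0.0003799

#: Exponent of the mass-dependent triple-oxygen relation 17R ~ K * (18R)**beta.
BETA_O17: float = 0.516

#: K anchored so that VSMOW satisfies the relation exactly.
K_O17: float = R17_VSMOW / R18_VSMOW**BETA_O17

#: Molar mass of nitrogen, g mol-1.
MOLAR_MASS_N: float = 14.007

#: Universal gas constant, J mol-1 K-1 (CODATA 2018).
GAS_CONSTANT: float = 8.314462618

#: Default chamber pressure, Pa (standard atmosphere; not measured on site).
STANDARD_PRESSURE: float = 101325.0

#: 15N atom fraction of the AIR-N2 reference (natural abundance).
A15_NATURAL: float = R15_AIR_N2 / (1.0 + R15_AIR_N2)

#: Same in atom-% units.
A15_NATURAL_PCT: float = 100.0 * A15_NATURAL

#: Versioned, read-only table of all constants (for run logs).
CONSTANTS = MappingProxyType(
    {
        "R15_AIR_N2": R15_AIR_N2,
        "R18_VSMOW": R18_VSMOW,
        "R17_VSMOW": R17_VSMOW,
        "BETA_O17": BETA_O17,
        "K_O17": K_O17,
        "MOLAR_MASS_N": MOLAR_MASS_N,
        "GAS_CONSTANT": GAS_CONSTANT,
        "STANDARD_PRESSURE": STANDARD_PRESSURE,
        "A15_NATURAL": A15_NATURAL,
        "version": "1",
    }
)
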