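"""Unit conversions and elemental constants used across the package.

Depths are stored in micrometres, reaction-diffusion model lengths in
centimetres, concentrations in micromolar (solutes) or micromoles per
square centimetre (areal loadings).  All conversions between those
conventions go through the constants below so there is a single place
to audit the arithmetic.
"""

#: micrometres per centimetre
UM_PER_CM = 1.0e4

#: micromolar expressed as micromoles per cubic centimetre (1 uM = 1e-3 umol/cm3)
UM_TO_UMOL_PER_CM3 = 1.0e-3

#: days per month used when converting mm/month vertical growth to um/day
DAYS_PER_MONTH = 30.0

#: molar masses, g/mol (overridable by callers that need other elements)
MOLAR_MASSES = {
    "Fe": 55.845,
    "As": 74.922,
    "P": 30.974,
    "W": 183.84,
    "S": 32.06,
    "Si": 28.086,
}


def molar_mass(element: str, overrides: dict | None = None) -> float:
    """Return the molar mass of ``element`` in g/mol.

    ``overrides`` takes precedence over the packaged table; unknown
    elements raise ``KeyError`` with the element name.
    """
    if overrides and element in overrides:
        return float(overrides[element])
    try:
        return MOLAR_MASSES[element]
    except KeyError:
        raise KeyError(f"no molar mass known for element {element!r}; pass an override")
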