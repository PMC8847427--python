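"""Unit constants and rounding conventions.

Column units are fixed package-wide: fiber diameters in micrometres,
particle (min-Feret) sizes in nanometres, masses in micrograms, air
concentrations in mg/m^3, inhaled volumes in m^3.
"""

import math

#: Molar-mass ratio TiO2 / Ti (79.88 g/mol over 47.88 g/mol).  ICP-OES
#: measures elemental titanium; multiplying by this factor re-expresses it
#: as TiO2 assuming all Ti is present as the dioxide.
MOLAR_MASS_TIO2 = 79.88
MOLAR_MASS_TI = 47.88
TIO2_PER_TI = MOLAR_MASS_TIO2 / MOLAR_MASS_TI  # = 1.668 to 4 significant figures

NM_PER_UM = 1000.0
UG_PER_MG = 1000.0


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed
    survey tables, unlike banker's rounding).

    >>> round_half_away(2.5)
    3.0
    >>> round_half_away(-2.5)
    -3.0
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
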