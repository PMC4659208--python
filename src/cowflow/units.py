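"""Unit conventions and conversion constants.

The package works in clinically reported units throughout: pressures in
mmHg, flows in ml/s, lengths and diameters in mm, viscosity in Pa·s,
shear rate in 1/s.  All conversions between this mixed system and SI are
concentrated here so no other module carries literal conversion factors.
"""

#: Pascals per millimetre of mercury (conventional definition).
PA_PER_MMHG: float = 133.322387415

#: Cubic millimetres per millilitre.
MM3_PER_ML: float = 1000.0

#: Seconds per minute (flow-rate conversions ml/s <-> ml/min).
S_PER_MIN: float = 60.0

#: Hydraulic-resistance conversion: a resistance expressed in
#: Pa/(m^3/s) times this factor is in mmHg/(ml/s).
RESISTANCE_SI_TO_MMHG_ML_S: float = 1e-6 / PA_PER_MMHG


def poiseuille_resistance_mmhg_ml_s(viscosity_pa_s: float, length_mm: float,
                                    diameter_mm: float) -> float:
    """Hagen–Poiseuille resistance 128·mu·L/(pi·d^4) of a rigid tube,
    returned in mmHg/(ml/s) for inputs in the package's working units."""
    import math
    length_m = length_mm * 1e-3
    diameter_m = diameter_mm * 1e-3
    r_si = 128.0 * viscosity_pa_s * length_m / (math.pi * diameter_m ** 4)
    return r_si * RESISTANCE_SI_TO_MMHG_ML_S
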