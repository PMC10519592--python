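"""Unit conversions between physiological I/O units and internal SI.

All network geometry is stored in mm (positions) and um (diameters,
lengths); pressures are exchanged in mmHg and flow rates in mL/min.
Every hydraulic computation happens in SI (Pa, m, m^3/s), and every
conversion goes through the constants below so that no module carries
its own factors.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_PER_MIN_TO_M3_PER_S = 1.0e-6 / 60.0
M3_PER_S_TO_ML_PER_MIN = 60.0e6

UM_TO_M = 1.0e-6
MM_TO_M = 1.0e-3

# terminal resistance: mmHg·min/mL  ->  Pa·s/m^3
RESISTANCE_TO_SI = MMHG_TO_PA / ML_PER_MIN_TO_M3_PER_S
RESISTANCE_FROM_SI = 1.0 / RESISTANCE_TO_SI


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p * PA_TO_MMHG


def ml_min_to_m3_s(q):
    return q * ML_PER_MIN_TO_M3_PER_S


def m3_s_to_ml_min(q):
    return q * M3_PER_S_TO_ML_PER_MIN
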