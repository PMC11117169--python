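"""Unit conversion constants.

Internal computations run in SI (Pa, m3, s); public interfaces speak the
clinical units of the field (mmHg, mL, s). All conversions go through the
constants below so there is exactly one place where they can be wrong.
"""

MMHG_TO_PA: float = 133.322387415
PA_TO_MMHG: float = 1.0 / MMHG_TO_PA

ML_TO_M3: float = 1e-6
M3_TO_ML: float = 1.0 / ML_TO_M3

UM_TO_M: float = 1e-6
MM_TO_M: float = 1e-3

#: mmHg.s/mL -> Pa.s/m3
RU_TO_SI: float = MMHG_TO_PA / ML_TO_M3
SI_TO_RU: float = 1.0 / RU_TO_SI

#: mL/mmHg -> m3/Pa
COMPL_TO_SI: float = ML_TO_M3 / MMHG_TO_PA
SI_TO_COMPL: float = 1.0 / COMPL_TO_SI


def mmhg(p_pa: float) -> float:
    """Pressure in mmHg from Pa."""
    return p_pa * PA_TO_MMHG


def pa(p_mmhg: float) -> float:
    """Pressure in Pa from mmHg."""
    return p_mmhg * MMHG_TO_PA
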