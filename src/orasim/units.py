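"""Unit conversions between clinical and SI units.

All solver internals work in SI (m, s, Pa, kg); public interfaces use the
clinical units customary in ophthalmology (mm, um, mmHg, MPa, ms).
"""

MMHG_TO_PA = 133.322387415
"""One millimetre of mercury in pascal."""


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p / MMHG_TO_PA


def mpa_to_pa(p):
    return p * 1.0e6


def pa_to_mpa(p):
    return p * 1.0e-6


def mm_to_m(x):
    return x * 1.0e-3


def m_to_mm(x):
    return x * 1.0e3


def um_to_mm(x):
    return x * 1.0e-3


def mm_to_um(x):
    return x * 1.0e3


def s_to_ms(t):
    return t * 1.0e3


def ms_to_s(t):
    return t * 1.0e-3
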