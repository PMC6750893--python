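"""Unit conventions and conversions.

Files use micrometres and mmHg (the conventions of the microcirculation
literature); all internal computation is SI (m, Pa, s).  Conversion happens
only at I/O boundaries so that the resistance law never sees mixed units.
"""

MMHG_TO_PA = 133.322387415
PA_TO_MMHG = 1.0 / MMHG_TO_PA

UM_TO_M = 1e-6
M_TO_UM = 1e6


def mmhg_to_pa(p_mmhg):
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    return p_pa * PA_TO_MMHG
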