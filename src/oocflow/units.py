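"""Unit conversions used throughout.

Everything internal is SI (m, s, Pa). Microfluidics literature quotes flow
rates in uL/min and shear stresses in dyne/cm^2, so converters for those two
are provided rather than pulling in a units framework.
"""

#: 1 Pa = 10 dyne/cm^2
PA_TO_DYNE_PER_CM2 = 10.0


def ul_per_min_to_m3_per_s(q_ul_min: float) -> float:
    """Convert a flow rate from uL/min to m^3/s."""
    return q_ul_min * 1e-9 / 60.0


def m3_per_s_to_ul_per_min(q_si: float) -> float:
    """Convert a flow rate from m^3/s to uL/min."""
    return q_si * 60.0 / 1e-9


def pa_to_dyne_per_cm2(tau_pa: float) -> float:
    """Convert a stress from Pa to dyne/cm^2."""
    return tau_pa * PA_TO_DYNE_PER_CM2


def dyne_per_cm2_to_pa(tau_dyne: float) -> float:
    """Convert a stress from dyne/cm^2 to Pa."""
    return tau_dyne / PA_TO_DYNE_PER_CM2
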