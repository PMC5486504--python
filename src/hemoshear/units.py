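"""Unit conversions between interface units and SI.

All user-facing quantities use clinical units (mm, ml/min, bpm, Pa);
everything inside the solver is SI (m, m^3/s or m^2/s per depth, Hz, Pa).
Conversions are centralized here so no module carries its own factors.
"""

MM_PER_M = 1e3

def mm_to_m(x_mm: float) -> float:
    return x_mm / MM_PER_M

def m_to_mm(x_m: float) -> float:
    return x_m * MM_PER_M

def mlmin_to_m3s(q_mlmin: float) -> float:
    """Volumetric flow rate: ml/min -> m^3/s."""
    return q_mlmin * 1e-6 / 60.0

def m3s_to_mlmin(q_m3s: float) -> float:
    return q_m3s * 60.0 / 1e-6

def bpm_to_hz(rate_bpm: float) -> float:
    """Heart rate in beats/min -> cardiac frequency in Hz."""
    return rate_bpm / 60.0

def bpm_to_rad_s(rate_bpm: float) -> float:
    """Heart rate in beats/min -> angular frequency omega in rad/s."""
    import math
    return 2.0 * math.pi * rate_bpm / 60.0
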