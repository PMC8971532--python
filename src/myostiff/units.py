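"""Unit conventions and conversions.

Internally everything is kPa, mm, ul (1 mm^3 == 1 ul).  Pressures cross the
I/O boundary in mmHg and are converted here.
"""

MMHG_TO_KPA: float = 0.133322
"""Conversion factor, 1 mmHg in kPa."""


def mmhg_to_kpa(p_mmhg):
    return p_mmhg * MMHG_TO_KPA


def kpa_to_mmhg(p_kpa):
    return p_kpa / MMHG_TO_KPA
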