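"""Unit system helpers.

The whole package works in a fixed kg-mm-s unit system, which makes all
quantities of a vascular/perfusion model O(1)-ish and matches common
physiological tables:

========================  =======================
quantity                  unit
========================  =======================
length, radius            mm
flow                      mm^3/s
pressure                  kg mm^-1 s^-2  (= kPa)
dynamic viscosity         kg mm^-1 s^-1  (= kPa s)
hydraulic resistance      kg mm^-4 s^-1
permeability K            mm^3 s kg^-1
perfusion coefficient     mm s kg^-1
power                     kg mm^2 s^-3  (= uW)
metabolic demand          uW mm^-3
========================  =======================

No implicit conversion happens anywhere; the helpers below are for user
convenience at the boundaries of the package.
"""

MMHG_PER_KPA = 7.50061683


def kpa_to_mmhg(p: float) -> float:
    """Convert a pressure from kg mm^-1 s^-2 (kPa) to mmHg."""
    return p * MMHG_PER_KPA


def mmhg_to_kpa(p: float) -> float:
    """Convert a pressure from mmHg to kg mm^-1 s^-2 (kPa)."""
    return p / MMHG_PER_KPA


def centipoise_to_kg_per_mm_s(eta_cp: float) -> float:
    """Convert a dynamic viscosity from cP to kg mm^-1 s^-1.

    1 cP = 1e-3 Pa s = 1e-6 kg mm^-1 s^-1, so blood at 3.6 cP becomes
    3.6e-6 kg mm^-1 s^-1.
    """
    return eta_cp * 1e-6


def kg_per_mm_s_to_centipoise(eta: float) -> float:
    return eta * 1e6
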