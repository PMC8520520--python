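"""Unit conversions for the package's internal CGS system.

Everything inside the package is stored in CGS units (cm, g, s, dyn).
Microfluidics literature mixes µL/hr flow rates, µm cell dimensions, and
viscosities quoted in N·s/cm², dyn·s/cm², Pa·s or cP; converting once at
the boundary avoids the classic 10^5 dyn-per-newton slip.
"""

from __future__ import annotations

#: 1 µL/hr in cm³/s.
UL_PER_HR = 1.0e-3 / 3600.0

#: 1 µm in cm.
UM = 1.0e-4

#: 1 N·s/cm² in dyn·s/cm² (1 N = 10^5 dyn).
N_S_PER_CM2 = 1.0e5

#: 1 Pa·s in dyn·s/cm² (1 Pa·s = 10 poise = 10 dyn·s/cm²).
PA_S = 10.0

#: 1 cP (mPa·s) in dyn·s/cm².
CP = 1.0e-2


def ul_per_hr_to_cm3_s(q_ul_hr: float) -> float:
    """Convert a volumetric flow rate from µL/hr to cm³/s."""
    return q_ul_hr * UL_PER_HR


def cm3_s_to_ul_per_hr(q_cm3_s: float) -> float:
    """Convert a volumetric flow rate from cm³/s to µL/hr."""
    return q_cm3_s / UL_PER_HR


def um_to_cm(x_um: float) -> float:
    """Convert a length from µm to cm."""
    return x_um * UM


def cm_to_um(x_cm: float) -> float:
    """Convert a length from cm to µm."""
    return x_cm / UM


_VISCOSITY_FACTORS = {
    "dyn.s/cm2": 1.0,
    "dyn·s/cm²": 1.0,
    "poise": 1.0,
    "N.s/cm2": N_S_PER_CM2,
    "N·s/cm²": N_S_PER_CM2,
    "Pa.s": PA_S,
    "Pa·s": PA_S,
    "cP": CP,
    "mPa.s": CP,
}


def viscosity_to_cgs(value: float, units: str) -> float:
    """Convert a dynamic viscosity to dyn·s/cm² (poise).

    Parameters
    ----------
    value
        Viscosity magnitude in ``units``.
    units
        One of ``dyn.s/cm2``, ``N.s/cm2``, ``Pa.s``, ``cP`` (plus the
        unicode spellings and ``poise``/``mPa.s`` aliases).
    """
    try:
        factor = _VISCOSITY_FACTORS[units]
    except KeyError:
        known = sorted(set(_VISCOSITY_FACTORS))
        raise ValueError(f"unknown viscosity unit {units!r}; known: {known}") from None
    return value * factor
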