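"""Unit conversions between bench units and SI.

All internal computation uses SI (volts, amperes, siemens, farads) with
concentrations in mol/cm^3, so that a permeability in cm^3/s times a
concentration in mol/cm^3 times the Faraday constant yields amperes
directly.  Public interfaces accept the units electrophysiologists write
down (mV, pA, pS, pF, mM, ms) and convert here.
"""

from __future__ import annotations

#: multiplicative factors to SI
MV = 1e-3   # millivolt -> volt
PA = 1e-12  # picoampere -> ampere
PS = 1e-12  # picosiemens -> siemens
PF = 1e-12  # picofarad -> farad
NS = 1e-9   # nanosiemens -> siemens
MS = 1e-3   # millisecond -> second

#: 1 mM = 1e-3 mol/L = 1e-6 mol/cm^3 (i.e. mol/mL)
MM_TO_MOL_PER_CM3 = 1e-6

ZERO_CELSIUS = 273.15


def mv_to_v(x: float) -> float:
    return x * MV


def v_to_mv(x: float) -> float:
    return x / MV


def pa_to_a(x: float) -> float:
    return x * PA


def a_to_pa(x: float) -> float:
    return x / PA


def ps_to_s(x: float) -> float:
    return x * PS


def mm_to_mol_per_cm3(x: float) -> float:
    return x * MM_TO_MOL_PER_CM3


def celsius_to_kelvin(x: float) -> float:
    return x + ZERO_CELSIUS


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``:
    100 * (value - reference) / reference."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (value - reference) / reference
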