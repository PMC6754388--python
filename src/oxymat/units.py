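"""Unit conversion constants and helpers.

Internal computations run in SI (m, s, mol m^-3); user-facing I/O uses the
field's customary units (mm, µmol L^-1, nmol L^-1 s^-1, mmol m^-2 d^-1).
All conversions are exact rational factors, so round trips are lossless to
floating-point precision.
"""

from __future__ import annotations

SECONDS_PER_DAY = 86_400.0
DAYS_PER_YEAR = 365.0

#: carbon molar mass [g mol^-1]
MOLAR_MASS_C = 12.011

# --- length ---
MM_PER_M = 1e3
CM_PER_M = 1e2


def mm_to_m(x):
    return x / MM_PER_M


def m_to_mm(x):
    return x * MM_PER_M


# --- concentration ---
# 1 µmol L^-1 (µM) = 1e-3 mol m^-3; 1 nmol L^-1 (nM) = 1e-6 mol m^-3.


def um_to_molm3(x):
    return x * 1e-3


def molm3_to_um(x):
    return x * 1e3


def nm_to_molm3(x):
    return x * 1e-6


def molm3_to_nm(x):
    return x * 1e6


# --- volumetric rate ---
# 1 nmol L^-1 s^-1 = 1e-6 mol m^-3 s^-1.


def nmps_to_molm3s(x):
    return x * 1e-6


def molm3s_to_nmps(x):
    return x * 1e6


# --- diffusivity ---
# 1 cm^2 s^-1 = 1e-4 m^2 s^-1.


def cm2s_to_m2s(x):
    return x * 1e-4


# --- areal flux ---
# 1 mol m^-2 s^-1 = 1000 * 86400 mmol m^-2 d^-1.


def molm2s_to_mmolm2d(x):
    return x * 1e3 * SECONDS_PER_DAY


def mmolm2d_to_molm2s(x):
    return x / (1e3 * SECONDS_PER_DAY)


# --- concentration gradient ---
# 1 µmol L^-1 mm^-1 = 1 mol m^-4 (1e-3 mol m^-3 / 1e-3 m).


def umpermm_to_molm4(x):
    return x * 1.0


def molm4_to_umpermm(x):
    return x * 1.0


# --- areal rate annualisation ---


def mmolm2d_to_molm2yr(x):
    """mmol m^-2 d^-1 -> mol m^-2 yr^-1."""
    return x * DAYS_PER_YEAR / 1e3


def mmolm2d_to_mmol_km2yr(x):
    """mmol m^-2 d^-1 -> Mmol km^-2 yr^-1 (1e6 m^2 per km^2, 1e9 mmol per Mmol)."""
    return x * DAYS_PER_YEAR * 1e6 / 1e9
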