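"""Physical constants and unit conversions.

Internal unit system: energy in kcal/mol, length in nm, time in s,
angle in rad, temperature in K.  Forces are energy gradients in
kcal/mol/nm and are converted to pN only at reporting boundaries.
"""

import math

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872

#: default simulation temperature, K (37 C)
T_DEFAULT = 310.0

#: default solvent viscosity, Pa s (water at body temperature)
ETA_DEFAULT = 1.0e-3

#: 1 kcal/mol expressed in joule
KCAL_PER_MOL_J = 4184.0 / 6.02214076e23

#: conversion factor: (kcal/mol/nm) -> pN
KCALMOL_NM_TO_PN = KCAL_PER_MOL_J / 1e-9 * 1e12  # ~6.9477


def thermal_energy(T: float = T_DEFAULT) -> float:
    """k_B*T in kcal/mol (~0.616 at 310 K)."""
    return KB * T


def gamma_translation(r_nm: float, eta: float = ETA_DEFAULT) -> float:
    """Stokes drag 6*pi*r*eta for a sphere, in kcal mol^-1 s nm^-2."""
    gamma_si = 6.0 * math.pi * (r_nm * 1e-9) * eta  # kg/s
    # kg/s = J s / m^2 ; convert J -> kcal/mol and m^2 -> nm^2
    return gamma_si * 1e-18 / KCAL_PER_MOL_J


def gamma_rotation(r_nm: float, eta: float = ETA_DEFAULT) -> float:
    """Rotational drag 8*pi*r^3*eta for a sphere, in kcal mol^-1 s rad^-2."""
    gamma_si = 8.0 * math.pi * (r_nm * 1e-9) ** 3 * eta  # J s
    return gamma_si / KCAL_PER_MOL_J
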