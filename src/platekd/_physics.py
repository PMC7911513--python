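"""Shared single-angle DLS physics: scattering vector and Stokes-Einstein."""

from __future__ import annotations

import math

BOLTZMANN_J_PER_K = 1.380649e-23


def scattering_vector_m(wavelength_nm: float, angle_deg: float, refractive_index: float) -> float:
    """q = (4 pi n / lambda) sin(theta / 2), in 1/m."""
    if wavelength_nm <= 0 or refractive_index <= 0:
        raise ValueError("wavelength and refractive index must be positive")
    if not 0.0 < angle_deg < 180.0:
        raise ValueError("scattering angle must lie in (0, 180) degrees")
    lam_m = wavelength_nm * 1e-9
    return 4.0 * math.pi * refractive_index / lam_m * math.sin(math.radians(angle_deg) / 2.0)


def stokes_einstein_radius_nm(d_m2_s: float, temperature_k: float, viscosity_mpas: float) -> float:
    """Hydrodynamic radius R_H = k_B T / (6 pi eta D), returned in nm."""
    if d_m2_s <= 0 or temperature_k <= 0 or viscosity_mpas <= 0:
        raise ValueError("D, temperature and viscosity must be positive")
    eta = viscosity_mpas * 1e-3
    return BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * eta * d_m2_s) * 1e9


def diffusion_from_radius_nm(rh_nm: float, temperature_k: float, viscosity_mpas: float) -> float:
    """Inverse of :func:`stokes_einstein_radius_nm`: D in m^2/s from R_H in nm."""
    if rh_nm <= 0 or temperature_k <= 0 or viscosity_mpas <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    eta = viscosity_mpas * 1e-3
    return BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * eta * rh_nm * 1e-9)
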