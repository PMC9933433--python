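"""Unit system and physical constants.

Package-wide internal units: length Å, time fs, mass u (unified atomic mass
unit), charge e, temperature K, wavenumber cm⁻¹.  Dipoles are e·Å and dipole
velocities e·Å/fs.  The derived energy unit is u·Å²/fs² (≈ 103.64 eV); the
Boltzmann constant below is expressed in it.  All conversions to SI happen in
this module only.
"""

from __future__ import annotations

import scipy.constants as _sc

#: speed of light in cm/fs (wavenumber ν̃ [cm⁻¹] = ν [1/fs] / C_CM_PER_FS)
C_CM_PER_FS = _sc.c * 100.0 * 1e-15

#: Boltzmann constant in u·Å²·fs⁻²·K⁻¹
KB_U_A2_FS2 = _sc.k / (_sc.atomic_mass * (1e-10) ** 2 / (1e-15) ** 2)

#: one internal energy unit (u·Å²/fs²) in joule
ENERGY_UNIT_J = _sc.atomic_mass * (1e-10) ** 2 / (1e-15) ** 2

#: one e·Å/fs in C·m/s
DIPOLE_VELOCITY_SI = _sc.e * 1e-10 / 1e-15

ATOMIC_MASSES = {"H": 1.008, "D": 2.014, "O": 15.999, "C": 12.011, "N": 14.007}


def wavenumber_to_angular_fs(nu_tilde: float) -> float:
    """ω in rad/fs for a wavenumber in cm⁻¹."""
    return 2.0 * 3.141592653589793 * C_CM_PER_FS * nu_tilde


def beer_lambert_prefactor(temperature: float, volume: float) -> float:
    """Prefactor β/(6 ε0 V c) converting ∫⟨Ṁ(0)·Ṁ(t)⟩e^{-iωt}dt to n(ω)α(ω).

    With the dipole-velocity autocorrelation in (e·Å/fs)² and the time
    integral in fs, multiplying by this factor yields the absorption
    coefficient times refractive index, n(ω)α(ω), in cm⁻¹.  The harmonic
    quantum correction is already implicit in the velocity form.

    Parameters
    ----------
    temperature : K
    volume : Å³
    """
    beta = 1.0 / (_sc.k * temperature)                      # 1/J
    v_si = volume * 1e-30                                   # m³
    acf_si = DIPOLE_VELOCITY_SI**2                          # (C m/s)²
    dt_si = 1e-15                                           # fs → s
    alpha_per_m = beta / (6.0 * _sc.epsilon_0 * v_si * _sc.c) * acf_si * dt_si
    return alpha_per_m / 100.0                              # 1/m → 1/cm
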