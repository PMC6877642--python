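"""Electron collision stopping power and CSDA ranges.

Collision (ionisation) stopping power follows the relativistic
Berger–Seltzer/ICRU formula for electrons,

    S/ρ = (0.153536/β²)(Z/A)[ ln(τ²(τ+2)/2(I/m_ec²)²) + F⁻(τ) ],

with τ the kinetic energy in electron rest-mass units and
``F⁻(τ) = 1 − β² + [τ²/8 − (2τ+1)ln2]/(τ+1)²``.  The density-effect
correction δ is omitted — a few-percent overestimate of S above ~1 MeV,
acceptable for the sub-2.3 MeV betas transported here.  Mean excitation
energies combine by Bragg additivity over ln I weighted by w·Z/A.
Bremsstrahlung losses (< ~2% of the total below 2.3 MeV in tissue) are
neglected.
"""

from __future__ import annotations

import numpy as np

from ..materials import ELEMENTS, Material

__all__ = ["electron_stopping_power", "electron_csda_range_cm", "radiation_length_g_cm2"]

MEC2_MEV = 0.51099895

#: mean excitation energies, eV
_I_EV = {
    "H": 19.2, "C": 78.0, "N": 82.0, "O": 95.0, "Na": 149.0, "Mg": 156.0,
    "P": 173.0, "S": 180.0, "Cl": 174.0, "K": 190.0, "Ca": 191.0,
    "Fe": 286.0, "I": 491.0, "U": 890.0,
}


def _z_over_a(mat: Material) -> float:
    return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in mat.mass_fractions.items())


def _mean_excitation_MeV(mat: Material) -> float:
    za = _z_over_a(mat)
    ln_i = (
        sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1] * np.log(_I_EV[el])
            for el, w in mat.mass_fractions.items()
        )
        / za
    )
    return np.exp(ln_i) * 1e-6


def electron_stopping_power(mat: Material, kinetic_MeV) -> np.ndarray:
    """Collision stopping power in MeV/cm (linear, includes density)."""
    e = np.asarray(kinetic_MeV, float)
    tau = e / MEC2_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    i_ratio = _mean_excitation_MeV(mat) / MEC2_MEV
    ln_term = np.log(np.clip(tau**2 * (tau + 2.0) / (2.0 * i_ratio**2), 1e-30, None))
    f_minus = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (tau + 1.0) ** 2
    mass_sp = 0.153536 / beta2 * _z_over_a(mat) * (ln_term + f_minus)
    return np.clip(mass_sp, 1e-6, None) * mat.density_g_cc


def electron_csda_range_cm(kinetic_MeV: float, mat: Material, e_min_MeV: float = 1e-3) -> float:
    """CSDA range ∫ dE/S(E) from ``e_min`` to E, in cm."""
    if kinetic_MeV <= e_min_MeV:
        return 0.0
    e = np.geomspace(e_min_MeV, kinetic_MeV, 512)
    return float(np.trapezoid(1.0 / electron_stopping_power(mat, e), e))


def radiation_length_g_cm2(mat: Material) -> float:
    """Mixture radiation length by reciprocal additivity (Tsai-style fit)."""
    inv = 0.0
    for el, w in mat.mass_fractions.items():
        z, a = ELEMENTS[el]
        x0 = 716.4 * a / (z * (z + 1.0) * np.log(287.0 / np.sqrt(z)))
        inv += w / x0
    return 1.0 / inv
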