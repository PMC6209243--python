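"""Chemical potentials of solvent, network and dissolved ions (kBT units).

The short-range mixing energy carries a crosslink-dependent interaction
parameter I(alpha), an affine function of the crosslink fraction: with the
default energies I(1) = 0 (a fully crosslinked network has no propensity to
swell) and I(0) = -45 (an uncrosslinked network swells strongly) — the
Flory-chi-like coefficient is rewired locally by the calcium chemistry.
Electrostatics enters through the thermal-voltage potential Psi acting on
ion valences and on the network site charge z_tilde.
"""

from __future__ import annotations

import numpy as np

from .params import InteractionEnergies

__all__ = [
    "ionic_molality", "interaction_parameter", "network_standard_energy",
    "solvent_potential", "network_potential", "ion_potential",
]

_LOG_FLOOR = 1e-300


def ionic_molality(*phi):
    """Total ionic molality sigma_I = sum_j phi_j, with phi_j = c_j/c_water."""
    arrs = [np.asarray(p, float) for p in phi]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("number ratios phi_j must be non-negative")
    out = sum(arrs) if arrs else np.float64(0.0)
    return out if np.ndim(out) else float(out)


def interaction_parameter(alpha, energies: InteractionEnergies, *, tol=1e-9):
    """Crosslink-dependent interaction parameter
    I(alpha) = 6(eps1+eps2) - 2(1-1/N) eps1 - eps1*alpha.
    """
    alpha = np.asarray(alpha, float)
    if np.any(alpha < -tol) or np.any(alpha > 1.0 + tol):
        raise ValueError("alpha outside [0, 1]")
    e = energies
    I = 6.0 * (e.eps1 + e.eps2) - 2.0 * (1.0 - 1.0 / e.N) * e.eps1 \
        - e.eps1 * alpha
    return I if I.ndim else float(I)


def network_standard_energy(alpha, energies: InteractionEnergies):
    """Standard free energy of the network phase,
    mu_n0 = -3 eps3 + eps4 (1 - 1/N) + (alpha/2) eps3.

    Only the alpha-dependent term produces potential gradients; the rest is
    an additive constant (and eps4 = 0 in all shipped experiments).
    """
    e = energies
    out = -3.0 * e.eps3 + e.eps4 * (1.0 - 1.0 / e.N) \
        + 0.5 * np.asarray(alpha, float) * e.eps3
    return out if np.ndim(out) else float(out)


def solvent_potential(theta_n, sigma_I, I, energies: InteractionEnergies):
    """Solvent chemical potential (kBT):
    mu_s = ln(theta_s) + (1 - 1/N) theta_n - sigma_I + (I/2) theta_n^2 + mu_s0.
    """
    theta_n = np.asarray(theta_n, float)
    theta_s = 1.0 - theta_n
    if np.any(theta_s <= 0.0):
        raise ValueError("theta_s must be positive (log singularity)")
    out = (np.log(np.maximum(theta_s, _LOG_FLOOR))
           + (1.0 - 1.0 / energies.N) * theta_n
           - sigma_I + 0.5 * I * theta_n**2 + energies.mu_s0)
    return out if np.ndim(out) else float(out)


def network_potential(theta_n, I, mu_n0, Psi, energies: InteractionEnergies):
    """Network chemical potential (kBT):
    mu_n = (1/N) ln(theta_n) + (1/N - 1) theta_s + (I/2) theta_s^2
           + mu_n0 - z_tilde*Psi.
    """
    theta_n = np.asarray(theta_n, float)
    if np.any(theta_n <= 0.0):
        raise ValueError("theta_n must be positive (log singularity)")
    theta_s = 1.0 - theta_n
    N = energies.N
    out = (np.log(np.maximum(theta_n, _LOG_FLOOR)) / N
           + (1.0 / N - 1.0) * theta_s + 0.5 * I * theta_s**2
           + mu_n0 - energies.z_tilde * Psi)
    return out if np.ndim(out) else float(out)


def ion_potential(phi_j, sigma_I, z_j, Psi):
    """Dissolved-ion chemical potential (kBT):
    mu_j = ln(phi_j) + 1 - 2 sigma_I + z_j*Psi.
    """
    phi_j = np.asarray(phi_j, float)
    if np.any(phi_j <= 0.0):
        raise ValueError("phi_j must be positive (log singularity)")
    out = np.log(phi_j) + 1.0 - 2.0 * sigma_I + z_j * Psi
    return out if np.ndim(out) else float(out)
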