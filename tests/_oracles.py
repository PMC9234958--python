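"""Independent closed-form oracles, deliberately coded apart from the package."""

import numpy as np

MU0_4PI = 1.0e-7
HBAR = 1.054571817e-34
KB = 1.380649e-23
GAMMA_H = 267.52218744e6
GAMMA_C = 67.2828e6


def lorentzian_j(tau, omega):
    """J(omega) = (2/5) tau / (1 + omega^2 tau^2)."""
    return 0.4 * tau / (1.0 + (omega * tau) ** 2)


def solomon_rates(b, tau, B0, gamma_i=GAMMA_H, gamma_s=GAMMA_C):
    """Longitudinal auto- and cross-relaxation of an isolated heteronuclear pair.

    rho_I = (b^2/4) [J(wI-wS) + 3 J(wI) + 6 J(wI+wS)]
    sigma = (b^2/4) [6 J(wI+wS) - J(wI-wS)]
    """
    wi, ws = gamma_i * B0, gamma_s * B0
    j = lambda w: lorentzian_j(tau, w)
    rho_i = (b**2 / 4.0) * (j(wi - ws) + 3 * j(wi) + 6 * j(wi + ws))
    rho_s = (b**2 / 4.0) * (j(wi - ws) + 3 * j(ws) + 6 * j(wi + ws))
    sigma = (b**2 / 4.0) * (6 * j(wi + ws) - j(wi - ws))
    return rho_i, rho_s, sigma


def dipolar_b(r_angstrom, gamma_i=GAMMA_H, gamma_s=GAMMA_C):
    return -MU0_4PI * gamma_i * gamma_s * HBAR / (r_angstrom * 1e-10) ** 3


def geometric_depletion(signal0, flip_deg, n_scans):
    """Per-scan longitudinal signal under a pulse train with relaxation off:
    scan k (0-based) sees signal0 * cos(theta)^k and detects sin(theta) of it."""
    c = np.cos(np.deg2rad(flip_deg))
    s = np.sin(np.deg2rad(flip_deg))
    return signal0 * s * c ** np.arange(n_scans)


def boltzmann_populations(energies_rad_s, temperature=298.0):
    """Populations of levels with energies given as angular frequencies."""
    e = HBAR * np.asarray(energies_rad_s)
    w = np.exp(-(e - e.min()) / (KB * temperature))
    return w / w.sum()


def lorentzian_integral_numeric(amps, centers, fwhm, lo, hi, n=200001):
    """Trapezoid quadrature of a sum of Lorentzians (integral of each = amp)."""
    x = np.linspace(lo, hi, n)
    y = np.zeros_like(x)
    for a, c in zip(amps, centers):
        hw = fwhm / 2.0
        y += (a / np.pi) * hw / ((x - c) ** 2 + hw**2)
    return np.trapezoid(y, x)
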