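"""Field-dependent solvent paramagnetic relaxation enhancement (sPRE) for nitroxides.

Outer-sphere, force-free translational-diffusion model: the nuclear spin relaxes
through the dipolar coupling to freely diffusing radical electrons, with the
Hwang-Freed/Ayant spectral density (the form used by Okuno and co-workers for
sPRE predictions),

    j(omega) = (1 + 5 z / 8 + z^2 / 8) /
               (1 + z + z^2 / 2 + z^3 / 6 + 4 z^4 / 81 + z^5 / 81 + z^6 / 648),
    z = sqrt(2 omega tau_t),   tau_t = d^2 / D,

where d is the distance of closest approach and D the relative translational
diffusion coefficient.  The longitudinal enhancement at field B0 is

    Gamma_1 = C * [ 3 j(omega_I) + 7 j(omega_S) ],
    C = (32 pi / 405) (mu0/4pi)^2 gamma_I^2 gamma_S^2 hbar^2 S(S+1) N_s / (d D),

with N_s the radical number density; Gamma_1 is linear in concentration.  An
optional field-independent electron relaxation time shortens the effective
correlation time (1/tau_eff = 1/tau_t + 1/T1e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GAMMA, HBAR, MU0_OVER_4PI, NA

__all__ = ["SPREModel", "spre_rate", "spre_profile", "tempol_water"]


@dataclass(frozen=True)
class SPREModel:
    """Outer-sphere sPRE parameters for a dissolved radical.

    concentration_mM : radical concentration in mmol/L
    diffusion : relative translational diffusion coefficient D in m^2 s^-1
    distance : distance of closest approach d in m
    spin : electron spin quantum number (1/2 for nitroxides)
    t1e : optional electron longitudinal relaxation time in s (None = slow)
    gamma_i, gamma_s : nuclear and electron gyromagnetic ratios, rad s^-1 T^-1
    """

    concentration_mM: float = 0.36
    diffusion: float = 2.71e-9
    distance: float = 3.5e-10
    spin: float = 0.5
    t1e: float | None = None
    gamma_i: float = GAMMA["1H"]
    gamma_s: float = GAMMA["e"]

    def __post_init__(self):
        if self.concentration_mM < 0:
            raise ValueError("concentration must be >= 0")
        for name in ("diffusion", "distance", "spin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t1e is not None and self.t1e <= 0:
            raise ValueError("t1e must be > 0 when given")

    @property
    def tau_t(self) -> float:
        """Translational correlation time d^2 / D, shortened by T1e if given."""
        tau = self.distance**2 / self.diffusion
        if self.t1e is not None:
            tau = 1.0 / (1.0 / tau + 1.0 / self.t1e)
        return tau

    @property
    def number_density(self) -> float:
        """Radicals per m^3."""
        return self.concentration_mM * 1e-3 * 1e3 * NA


def tempol_water(concentration_mM: float = 0.36, **kw) -> SPREModel:
    """TEMPOL in aqueous solution with standard diffusion/contact parameters."""
    return SPREModel(concentration_mM=concentration_mM, **kw)


def _hwang_freed(z: np.ndarray) -> np.ndarray:
    num = 1.0 + 5.0 * z / 8.0 + z**2 / 8.0
    den = (1.0 + z + z**2 / 2.0 + z**3 / 6.0 + 4.0 * z**4 / 81.0
           + z**5 / 81.0 + z**6 / 648.0)
    return num / den


def spre_rate(model: SPREModel, B0) -> float | np.ndarray:
    """Longitudinal sPRE rate Gamma_1 (s^-1) at field(s) B0 (Tesla)."""
    B0 = np.asarray(B0, dtype=float)
    if np.any(B0 < 0):
        raise ValueError("B0 must be >= 0")
    tau = model.tau_t
    w_i = np.abs(model.gamma_i) * B0
    w_s = np.abs(model.gamma_s) * B0
    j_i = _hwang_freed(np.sqrt(2.0 * w_i * tau))
    j_s = _hwang_freed(np.sqrt(2.0 * w_s * tau))
    pref = (32.0 * np.pi / 405.0) * MU0_OVER_4PI**2 \
        * model.gamma_i**2 * model.gamma_s**2 * HBAR**2 \
        * model.spin * (model.spin + 1.0) \
        * model.number_density / (model.distance * model.diffusion) * tau / tau
    # tau enters only through z; the prefactor carries d and D explicitly
    out = pref * (3.0 * j_i + 7.0 * j_s) * tau
    return float(out) if out.ndim == 0 else out


def spre_profile(model: SPREModel, fields) -> pd.DataFrame:
    """Dispersion table Gamma_1(B0) over the given fields (Tesla)."""
    fields = np.atleast_1d(np.asarray(fields, dtype=float))
    if fields.size == 0:
        raise ValueError("fields must be nonempty")
    rates = spre_rate(model, fields)
    return pd.DataFrame({"B0_T": fields, "Gamma1_s-1": np.atleast_1d(rates)})
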