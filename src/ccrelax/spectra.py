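"""Multiplet line intensities, 1-D spectrum synthesis and Lorentzian fitting.

A first-order 13C multiplet of a CHn group has n+1 lines indexed by the total
proton Zeeman projection m = n/2 .. -n/2; lines are ordered left to right from
the highest to the lowest proton projection, so "line 1" is the outer line of
the highest-m proton states.  The detected intensity of line m is the carbon
transverse amplitude within the proton projection-m subspace after the read
pulse; it decomposes exactly into the contributions of the longitudinal spin
orders Cz, CzHz, CzHzHz and CzHzHzHz present before the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import expm

from .dynamics import DensityState
from .spinsys import SpinSystem

__all__ = [
    "Multiplet",
    "FitResult",
    "multiplet_intensities",
    "synth_spectrum",
    "fit_multiplet",
    "order_operators",
    "order_pattern_matrix",
]


@dataclass
class Multiplet:
    """Signed line intensities of a first-order multiplet."""

    nucleus: str
    offsets_hz: np.ndarray          # line positions relative to the multiplet center
    intensities: np.ndarray         # signed amplitudes, left to right
    order_amplitudes: dict = field(default_factory=dict)   # Cz, CzHz, ... weights
    in_phase: np.ndarray | None = None
    anti_phase: np.ndarray | None = None

    @property
    def n_lines(self) -> int:
        return len(self.intensities)

    def normalized(self, line: int = -1) -> np.ndarray:
        """Intensities scaled so the given line (default: the last) equals 1."""
        ref = self.intensities[line]
        if ref == 0:
            raise ZeroDivisionError("reference line has zero intensity")
        return self.intensities / ref


@dataclass
class FitResult:
    """Estimates with uncertainties from a nonlinear least-squares fit."""

    params: dict
    stderr: dict
    residual_norm: float
    converged: bool
    degenerate: bool = False
    report: str = ""

    @property
    def amplitudes(self) -> np.ndarray:
        keys = sorted(k for k in self.params if k.startswith("amp"))
        return np.array([self.params[k] for k in keys])

    @property
    def amplitude_stderr(self) -> np.ndarray:
        keys = sorted(k for k in self.params if k.startswith("amp"))
        return np.array([self.stderr.get(k, np.nan) for k in keys])


# ---------------------------------------------------------------------------
# line projections


def _proton_projection_projectors(system: SpinSystem):
    """Projectors onto total proton Zeeman projection m, highest m first."""
    protons = system.indices("1H")
    n = len(protons)
    d = system.dim
    mz = np.zeros(d)
    for i in protons:
        mz += np.real(np.diag(system.op(i, "z")))
    ms = sorted(set(np.round(mz, 9)), reverse=True)
    projs = []
    for m in ms:
        P = np.diag((np.abs(mz - m) < 1e-9).astype(complex))
        projs.append((m, P))
    return projs


def order_operators(system: SpinSystem) -> dict:
    """Longitudinal carbon x proton spin orders Cz, CzHz^(1), ... (symmetrized)."""
    c = system.indices("13C")
    if len(c) != 1:
        raise ValueError("order decomposition requires exactly one 13C")
    protons = system.indices("1H")
    Cz2 = 2.0 * system.op(c[0], "z")
    orders = {"Cz": Cz2}
    names = ["CzHz", "CzHzHz", "CzHzHzHz"]
    for k in range(1, len(protons) + 1):
        O = np.zeros_like(Cz2)
        for sub in combinations(protons, k):
            term = Cz2.copy()
            for i in sub:
                term = term @ (2.0 * system.op(i, "z"))
            O += term
        orders[names[k - 1]] = O
    return orders


def multiplet_intensities(rho: DensityState, system: SpinSystem, nucleus: str = "13C",
                          flip_angle: float | None = 30.0, _rotated=None) -> Multiplet:
    """Signed multiplet line intensities after a read pulse on ``nucleus``.

    The read rotation (``flip_angle`` degrees about +y) is applied to the carbon
    channel; line m's intensity is Tr(rho_rot * 2 Cx P_m) with P_m the projector
    onto total proton projection m.  The same projection applied to the rotated
    unit spin orders yields the per-order decomposition; the 'Cz' row is the
    in-phase contribution, the remaining orders are anti-phase.
    """
    idx = system.indices(nucleus)
    if len(idx) != 1:
        raise ValueError(f"system has no unique {nucleus} spin")
    spin = idx[0]
    if _rotated is None:
        rho_rot = _rotate(rho.operator, system, spin, flip_angle)
    else:
        rho_rot = _rotated
    intensities = _line_intensities(rho_rot, system, spin)
    projs = _proton_projection_projectors(system)
    jch = 0.0
    for h in system.indices("1H"):
        jch = max(jch, abs(system.j_hz[spin, h]))
    offsets = np.array([-m * jch for m, _ in projs])  # highest m drawn left (lowest offset)

    orders = order_operators(system) if nucleus == "13C" else {}
    amps = {}
    d = system.dim
    for name, O in orders.items():
        amps[name] = float(np.real(np.trace(rho.operator @ O)) * d / np.real(np.trace(O @ O)))
    in_phase = anti_phase = None
    if orders:
        M = order_pattern_matrix(system, flip_angle if flip_angle is not None else 90.0)
        a = np.array([amps[k] for k in orders])
        contrib = M * a[None, :]
        in_phase = contrib[:, 0]
        anti_phase = contrib[:, 1:].sum(axis=1)
    return Multiplet(nucleus, offsets, intensities, amps, in_phase, anti_phase)


def _rotate(rho_op: np.ndarray, system: SpinSystem, spin: int, flip_angle: float) -> np.ndarray:
    U = expm(-1j * np.deg2rad(flip_angle) * system.op(spin, "y"))
    return U @ rho_op @ U.conj().T


def _line_intensities(rho_rot: np.ndarray, system: SpinSystem, spin: int) -> np.ndarray:
    det = 2.0 * system.op(spin, "x")
    projs = _proton_projection_projectors(system)
    return np.array([np.real(np.trace(rho_rot @ det @ P)) for _, P in projs])


def order_pattern_matrix(system: SpinSystem, flip_angle: float = 90.0) -> np.ndarray:
    """Matrix mapping unit spin-order amplitudes to line-intensity vectors.

    Column k is the multiplet of the k-th order operator alone (unit amplitude,
    state 1/d + O_k/d); the line vector of any longitudinal state equals this
    matrix times its order amplitudes.
    """
    orders = order_operators(system)
    d = system.dim
    spin = system.indices("13C")[0]
    cols = []
    for O in orders.values():
        rho_rot = _rotate(np.eye(d, dtype=complex) / d + O.astype(complex) / d,
                          system, spin, flip_angle)
        cols.append(_line_intensities(rho_rot, system, spin))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# spectrum synthesis


def synth_spectrum(multiplet: Multiplet, linewidth_hz: float, grid_hz: np.ndarray,
                   center_hz: float = 0.0) -> np.ndarray:
    """Sum of Lorentzians, one per line; each component integrates to its amplitude.

    L(x) = (A / pi) * (w/2) / ((x - x0)^2 + (w/2)^2), peak height 2A/(pi w).
    """
    if linewidth_hz <= 0:
        raise ValueError("linewidth must be > 0")
    grid_hz = np.asarray(grid_hz, dtype=float)
    span = multiplet.offsets_hz + center_hz
    if span.size and (grid_hz.min() > span.min() or grid_hz.max() < span.max()):
        import warnings
        warnings.warn("frequency grid does not cover the multiplet span", stacklevel=2)
    hw = 0.5 * linewidth_hz
    out = np.zeros_like(grid_hz)
    for x0, amp in zip(span, multiplet.intensities):
        out += (amp / np.pi) * hw / ((grid_hz - x0) ** 2 + hw ** 2)
    return out


# ---------------------------------------------------------------------------
# multiplet fitting


def fit_multiplet(grid_hz, spectrum, n_lines: int, j_hz: float,
                  center_hz: float = 0.0, linewidth_hz: float = 1.0,
                  shared_linewidth: bool = True) -> FitResult:
    """Nonlinear least squares of a sum of Lorentzians to a 1-D spectrum.

    Free parameters: one signed amplitude per line, a shared linewidth (or one
    per line with ``shared_linewidth=False``) and a common center offset.  Line
    positions are fixed relative to the center by the known J coupling.  An
    all-zero input is flagged degenerate; non-convergence is flagged and the
    partial result returned.
    """
    import lmfit

    grid_hz = np.asarray(grid_hz, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    offsets = j_hz * (np.arange(n_lines) - (n_lines - 1) / 2.0)
    if np.max(np.abs(spectrum)) == 0.0:
        params = {f"amp{k + 1}": 0.0 for k in range(n_lines)}
        params.update({"center": center_hz, "fwhm": linewidth_hz})
        return FitResult(params, {k: 0.0 for k in params}, 0.0, True, degenerate=True,
                         report="degenerate: all-zero input")

    p = lmfit.Parameters()
    peak0 = 2.0 / (np.pi * linewidth_hz)
    for k in range(n_lines):
        guess = spectrum[np.argmin(np.abs(grid_hz - (center_hz + offsets[k])))] / peak0
        p.add(f"amp{k + 1}", value=float(guess))
    p.add("center", value=center_hz)
    if shared_linewidth:
        p.add("fwhm", value=linewidth_hz, min=1e-6)
    else:
        for k in range(n_lines):
            p.add(f"fwhm{k + 1}", value=linewidth_hz, min=1e-6)

    def model(pars):
        v = pars.valuesdict()
        out = np.zeros_like(grid_hz)
        for k in range(n_lines):
            w = v["fwhm"] if shared_linewidth else v[f"fwhm{k + 1}"]
            hw = 0.5 * w
            x0 = v["center"] + offsets[k]
            out += (v[f"amp{k + 1}"] / np.pi) * hw / ((grid_hz - x0) ** 2 + hw ** 2)
        return out

    res = lmfit.minimize(lambda pars: model(pars) - spectrum, p)
    params = {k: float(v.value) for k, v in res.params.items()}
    stderr = {k: float(v.stderr) if v.stderr is not None else np.nan
              for k, v in res.params.items()}
    return FitResult(params, stderr, float(np.linalg.norm(res.residual)),
                     bool(res.success), report=lmfit.fit_report(res))
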