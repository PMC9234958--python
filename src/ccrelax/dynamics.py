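"""Hyperpolarized initial states, propagation, detection trains and transfer windows.

The master equation is the inhomogeneous form

    d rho / dt = -i [H, rho] - R (rho - rho_eq)

solved exactly by matrix exponentiation of the (augmented) Liouvillian on each
requested interval; H is the rotating-frame coherent Hamiltonian, R the
relaxation superoperator built at the same field, and rho_eq either the
Boltzmann state at 298 K or the infinite-temperature state 1/d (useful to
isolate mechanism effects on the hyperpolarized scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .constants import HBAR, KB
from .relaxation import RelaxationSuperoperator
from .spinsys import SpinSystem, coherent_hamiltonian, proton_manifolds

__all__ = [
    "DensityState",
    "InitialCombination",
    "Trajectory",
    "FieldProfile",
    "thermal_state",
    "imbalance_operator",
    "unit_operators",
    "initial_state",
    "propagate",
    "detection_train",
    "backpropagate_window",
    "transfer_scaling",
]

DEFAULT_TEMPERATURE = 298.0  # K


# ---------------------------------------------------------------------------
# states and combinations


@dataclass
class DensityState:
    """Hermitian, unit-trace density operator in the Zeeman product basis."""

    operator: np.ndarray
    time: float = 0.0
    basis: str = "zeeman-product"

    def __post_init__(self):
        op = np.asarray(self.operator, dtype=complex)
        if np.max(np.abs(op - op.conj().T)) > 1e-12 * max(np.max(np.abs(op)), 1.0):
            raise ValueError("density operator must be Hermitian")
        if abs(np.trace(op).real - 1.0) > 1e-9:
            raise ValueError("density operator must have unit trace")
        self.operator = op

    @property
    def dim(self) -> int:
        return self.operator.shape[0]

    def expect(self, observable: np.ndarray) -> float:
        return float(np.real(np.trace(self.operator @ observable)))


@dataclass(frozen=True)
class InitialCombination:
    """Weights of the hyperpolarized orders: Hz, Cz and a manifold imbalance.

    ``imbalance`` is 'AE' (methyl) or 'TS' (methylene); a positive imbalance
    coefficient overpopulates the E (respectively S) manifold, the situation
    expected after negative DNP.  Coefficient 1 on Hz corresponds to 100%
    proton polarization at reference_polarization 1.
    """

    hz: float = 0.0
    cz: float = 0.0
    imbalance: float = 0.0
    kind: str = "AE"

    def __post_init__(self):
        if self.kind not in ("AE", "TS"):
            raise ValueError("imbalance kind must be 'AE' or 'TS'")
        if self.hz == self.cz == self.imbalance == 0.0:
            # the all-zero combination is allowed and yields 1/d
            pass

    @classmethod
    def from_mapping(cls, combo: dict) -> "InitialCombination":
        kind = "AE" if "AE" in combo else ("TS" if "TS" in combo else "AE")
        return cls(hz=float(combo.get("Hz", 0.0)), cz=float(combo.get("Cz", 0.0)),
                   imbalance=float(combo.get("AE", combo.get("TS", 0.0))), kind=kind)


@dataclass
class Trajectory:
    """Time series of named observables (and optionally stored states)."""

    times: np.ndarray
    observables: dict                      # name -> array over times
    states: list | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for name, vals in self.observables.items():
            for t, v in zip(self.times, vals):
                rows.append((t, name, v))
        return pd.DataFrame(rows, columns=["time_s", "observable", "value"])


@dataclass
class FieldProfile:
    """Piecewise-constant magnetic field during sample transfer."""

    segments: list                         # list of (duration_s, B0_T)
    name: str = "custom"

    def __post_init__(self):
        for dur, b in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if b < 0:
                raise ValueError("fields must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(d for d, _ in self.segments))


# ---------------------------------------------------------------------------
# operators and initial states


def thermal_state(system: SpinSystem, B0: float, temperature: float = DEFAULT_TEMPERATURE) -> DensityState:
    """Boltzmann state of the lab-frame Hamiltonian at (B0, T)."""
    H = coherent_hamiltonian(system, B0, frame="lab")
    M = expm(-HBAR * H / (KB * temperature))
    rho = M / np.trace(M).real
    return DensityState(0.5 * (rho + rho.conj().T) / np.trace(rho).real)


def unit_operators(system: SpinSystem) -> dict:
    """The deviation operators behind the combination coefficients.

    Hz -> sum_i 2 H_iz (coefficient = per-proton polarization),
    Cz -> 2 Cz, AE/TS -> manifold imbalance operator.
    """
    ops = {"Hz": 2.0 * system.total_op("1H", "z")}
    if system.indices("13C"):
        ops["Cz"] = 2.0 * system.total_op("13C", "z")
    md = proton_manifolds(system)
    if md is not None and len(system.indices("1H")) == 3:
        ops["AE"] = imbalance_operator(system, "AE")
    if md is not None and len(system.indices("1H")) == 2:
        ops["TS"] = imbalance_operator(system, "TS")
    return ops


def imbalance_operator(system: SpinSystem, kind: str) -> np.ndarray:
    """Traceless manifold-imbalance operator.

    AE (three protons): Q = P_E - P_A, eigenvalue +1 on every E level and -1 on
    every A level (the manifolds have equal rank).  TS (two protons):
    Q = P_S - P_T/3, rank-balanced so that the trace vanishes; eigenvalue +1 on
    the singlet levels.  A positive coefficient overpopulates E (or S), the
    distribution expected after negative DNP.  At coefficient 1 the per-level
    population deviation matches that of a fully polarized proton (1/d).
    """
    md = proton_manifolds(system)
    nh = len(system.indices("1H"))
    if kind == "AE":
        if md is None or nh != 3:
            raise ValueError("AE imbalance requires a three-proton (methyl) system")
        q_h = md.projector("Ea") + md.projector("Eb") - md.projector("A")
    elif kind == "TS":
        if md is None or nh != 2:
            raise ValueError("TS imbalance requires a two-proton (methylene) system")
        q_h = md.projector("S") - md.projector("T") / 3.0
    else:
        raise ValueError("kind must be 'AE' or 'TS'")
    n_extra = system.nspins - nh
    if n_extra:
        q = np.kron(np.eye(2 ** n_extra, dtype=complex), q_h)  # carbon listed first
    else:
        q = q_h
    return q


def initial_state(system: SpinSystem, combo, reference_polarization: float = 1.0) -> DensityState:
    """Hyperpolarized initial density operator.

    rho = 1/d + (p/d) * (c_Hz sum_i 2 H_iz + c_Cz 2 Cz + c_X Q_X)
    with p = ``reference_polarization``: at p = 1, coefficient 1 on Hz means
    100% proton polarization.  Combinations whose populations leave [0, 1] are
    rejected, reporting the offending level.
    """
    if isinstance(combo, dict):
        combo = InitialCombination.from_mapping(combo)
    d = system.dim
    ops = unit_operators(system)
    dev = np.zeros((d, d), dtype=complex)
    if combo.hz:
        dev += combo.hz * ops["Hz"]
    if combo.cz:
        if "Cz" not in ops:
            raise ValueError("combination has a Cz coefficient but the system has no 13C")
        dev += combo.cz * ops["Cz"]
    if combo.imbalance:
        if combo.kind not in ops:
            raise ValueError(f"imbalance kind {combo.kind!r} incompatible with this system")
        dev += combo.imbalance * ops[combo.kind]
    rho = np.eye(d, dtype=complex) / d + reference_polarization * dev / d
    evals, evecs = np.linalg.eigh(rho)
    if evals.min() < -1e-12:
        k = int(np.argmin(evals))
        raise ValueError(
            f"combination yields negative population {evals[k]:.3e} "
            f"(level with largest weight on product state "
            f"{int(np.argmax(np.abs(evecs[:, k])**2))}); "
            "reduce reference_polarization or the coefficients")
    return DensityState(rho)


# ---------------------------------------------------------------------------
# propagation


def _liouvillian(H: np.ndarray, R: np.ndarray | None) -> np.ndarray:
    d = H.shape[0]
    eye = np.eye(d)
    L = -1j * (np.kron(eye, H) - np.kron(H.T, eye))
    if R is not None:
        L = L - R
    return L


def _equilibrium(system, B0, rho_eq, temperature):
    d = system.dim
    if rho_eq is None or rho_eq == "thermal":
        return thermal_state(system, B0, temperature).operator
    if isinstance(rho_eq, str) and rho_eq in ("unit", "infinite-temperature"):
        return np.eye(d, dtype=complex) / d
    if isinstance(rho_eq, DensityState):
        return rho_eq.operator
    return np.asarray(rho_eq, dtype=complex)


class _Stepper:
    """Exact affine propagator y' = L y + b over cached step lengths."""

    def __init__(self, H, R_matrix, rho_eq_vec):
        self.L = _liouvillian(H, R_matrix)
        self.b = R_matrix @ rho_eq_vec if R_matrix is not None else np.zeros(len(rho_eq_vec))
        self.n = self.L.shape[0]
        self._cache = {}

    def step_matrix(self, dt: float):
        key = round(float(dt), 15)
        if key not in self._cache:
            aug = np.zeros((self.n + 1, self.n + 1), dtype=complex)
            aug[:self.n, :self.n] = self.L * dt
            aug[:self.n, self.n] = self.b * dt
            self._cache[key] = expm(aug)
        return self._cache[key]

    def advance(self, y: np.ndarray, dt: float) -> np.ndarray:
        if dt == 0.0:
            return y
        M = self.step_matrix(dt)
        return M[:-1, :-1] @ y + M[:-1, -1]


def _default_observables(system: SpinSystem, diagram=None) -> dict:
    obs = {}
    for i, s in enumerate(system.spins):
        obs[f"2Iz({s.label})"] = 2.0 * system.op(i, "z")
    if system.indices("13C"):
        obs["Cz"] = 2.0 * system.total_op("13C", "z")
    if system.indices("1H"):
        obs["Hz_total"] = 2.0 * system.total_op("1H", "z") / max(len(system.indices("1H")), 1)
    md = proton_manifolds(system)
    if md is not None:
        nh = len(system.indices("1H"))
        n_extra = system.nspins - nh
        for m in md.manifolds:
            P = md.projector(m)
            if n_extra:
                P = np.kron(np.eye(2 ** n_extra, dtype=complex), P)
            obs[f"pop({m})"] = P
    return obs


def propagate(rho0: DensityState, system: SpinSystem, B0: float,
              R: RelaxationSuperoperator | None, times,
              rho_eq="thermal", temperature: float = DEFAULT_TEMPERATURE,
              observables: dict | None = None, store_states: bool = True,
              check: bool = True) -> Trajectory:
    """Propagate under coherent + relaxation dynamics at fixed field.

    ``times`` are absolute time tags; the state ``rho0`` applies at times[0].
    Raises if the Liouvillian has a significantly positive real eigenvalue
    (divergence) or if trace/Hermiticity drift beyond 1e-10.
    """
    if R is not None and abs(R.B0 - B0) > 1e-12:
        raise ValueError("relaxation superoperator was built at a different field")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    H = coherent_hamiltonian(system, B0, frame="rotating")
    eq = _equilibrium(system, B0, rho_eq, temperature)
    stepper = _Stepper(H, R.matrix if R is not None else None, eq.reshape(-1, order="F"))
    obs = observables or _default_observables(system)
    d = system.dim
    y = rho0.operator.reshape(-1, order="F").astype(complex)
    out = {k: np.zeros(len(times)) for k in obs}
    states = [] if store_states else None
    tol = 1e-9  # runtime guard; single steps spanning hundreds of seconds
                # accumulate ~1e-10 of expm round-off
    for k, t in enumerate(times):
        if k > 0:
            y = stepper.advance(y, times[k] - times[k - 1])
        rho = y.reshape(d, d, order="F")
        if check:
            if abs(np.trace(rho).real - 1.0) > tol:
                raise RuntimeError(f"trace drift {np.trace(rho).real - 1.0:.2e} at t={t}")
            if np.max(np.abs(rho - rho.conj().T)) > 1e-9:
                raise RuntimeError(f"Hermiticity loss at t={t}")
        for name, O in obs.items():
            out[name][k] = np.real(np.trace(rho @ O))
        if store_states:
            states.append(DensityState(0.5 * (rho + rho.conj().T), time=float(t)))
    return Trajectory(times, out, states, meta={"B0": B0, "rho_eq": str(rho_eq)})


# ---------------------------------------------------------------------------
# detection


def _rotation(system: SpinSystem, flip_angles: dict) -> np.ndarray:
    """Simultaneous read rotation about +y on each listed channel (degrees)."""
    gen = np.zeros((system.dim, system.dim), dtype=complex)
    for isotope, deg in flip_angles.items():
        if not (0.0 <= deg <= 90.0):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        gen += np.deg2rad(deg) * system.total_op(isotope, "y")
    return expm(-1j * gen)


def _populations_only(rho: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Project onto eigenstate populations (coherences dephase between scans)."""
    r = V.conj().T @ rho @ V
    return V @ np.diag(np.diag(r)) @ V.conj().T


def detection_train(rho_entry: DensityState, system: SpinSystem, B0: float,
                    R: RelaxationSuperoperator | None,
                    flip_angles: dict, interval: float, n_scans: int,
                    rho_eq="thermal", temperature: float = DEFAULT_TEMPERATURE,
                    readout=None):
    """Small-flip-angle pulse train, one readout per ``interval`` seconds.

    Each scan applies the read rotation, hands the rotated state to ``readout``
    (a callable returning a dict of per-scan quantities, by default the signed
    13C multiplet line intensities and per-channel transverse/longitudinal
    amplitudes), keeps the cos(angle)-scaled longitudinal part (coherences are
    dropped: they dephase within the 1 s between scans and, secularized, do not
    feed back into populations), and propagates one interval.

    Returns (times, records) with records a list of per-scan dicts.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if readout is None:
        from .spectra import multiplet_intensities

        def readout(rho_rot, rho_before):
            rec = {}
            if system.indices("13C"):
                m = multiplet_intensities(DensityState(rho_before), system, "13C",
                                          flip_angle=None, _rotated=rho_rot)
                for k, amp in enumerate(m.intensities):
                    rec[f"line{k + 1}"] = amp
            for iso in ("1H", "13C"):
                if system.indices(iso):
                    Ix = system.total_op(iso, "x")
                    rec[f"Mx({iso})"] = float(np.real(np.trace(rho_rot @ (2 * Ix))))
            return rec

    U = _rotation(system, flip_angles)
    V = R.diagram.vectors if R is not None else np.eye(system.dim)
    H = coherent_hamiltonian(system, B0, frame="rotating")
    eq = _equilibrium(system, B0, rho_eq, temperature)
    stepper = _Stepper(H, R.matrix if R is not None else None, eq.reshape(-1, order="F"))
    rho = rho_entry.operator.copy()
    times, records = [], []
    for scan in range(n_scans):
        rho_rot = U @ rho @ U.conj().T
        records.append(readout(rho_rot, rho))
        times.append(scan * interval)
        rho = _populations_only(rho_rot, V)
        y = stepper.advance(rho.reshape(-1, order="F"), interval)
        rho = y.reshape(system.dim, system.dim, order="F")
        rho = 0.5 * (rho + rho.conj().T)
    return np.asarray(times), records


# ---------------------------------------------------------------------------
# pre-detection window and transfer scaling


def transfer_scaling(profile: FieldProfile, spre_model, system: SpinSystem,
                     detection_field: float = 11.7) -> dict:
    """Per-segment random-field multipliers from the field-dependent sPRE.

    Each segment's random-field amplitudes are augmented by the solvent PRE rate
    at that segment's field: a_seg = a + Gamma_1(B_seg)/2 (an isolated spin
    relaxes at R1 = 2a).  The report includes the 'equivalent time' the transfer
    is worth at the detection field, i.e. sum(duration * rate) / rate(det).
    """
    from .spre import spre_rate
    base = np.array(system.random_field, dtype=float)
    if np.all(base == 0):
        base_scalar = 0.0
    else:
        base_scalar = float(np.max(base))
    g_det = spre_rate(spre_model, detection_field) if spre_model is not None else 0.0
    segs = []
    equiv = 0.0
    denom = 2 * base_scalar + 2 * g_det
    for dur, b in profile.segments:
        g = spre_rate(spre_model, b) if spre_model is not None else 0.0
        mult = 1.0 if denom == 0 else (2 * base_scalar + 2 * g) / denom
        segs.append({"duration_s": dur, "B0_T": b, "spre_rate_s-1": g,
                     "rnd_multiplier": mult,
                     "amplitudes": base + 0.5 * g})
        equiv += dur * mult
    return {"segments": segs, "equivalent_time_s": equiv,
            "detection_field_T": detection_field, "spre_rate_det_s-1": g_det}


def backpropagate_window(system: SpinSystem, combo, pre_delay: float, B0: float,
                         R: RelaxationSuperoperator | None = None,
                         reference_polarization: float = 1.0,
                         flip_angles: dict | None = None, interval: float = 1.0,
                         n_scans: int = 60, rho_eq="thermal",
                         temperature: float = DEFAULT_TEMPERATURE,
                         field_profile: FieldProfile | None = None,
                         spre_model=None, mechanisms=None,
                         pre_times=None) -> dict:
    """Apply the initial combination at t = -pre_delay and detect from t = 0.

    The pre-detection segment runs at the spectrometer field by default; if a
    ``field_profile`` (plus optional sPRE model) is given, the system is
    propagated through each segment at that segment's field with random-field
    amplitudes augmented by the sPRE rate, and the profile duration replaces
    ``pre_delay``.  Returns a dict with the pre-detection Trajectory (t <= 0),
    detection-scan times and per-scan records, and the t = 0 state.
    """
    from .relaxation import MECHANISMS, assemble_relaxation
    if pre_delay < 0:
        raise ValueError("pre_delay must be >= 0")
    mechanisms = tuple(mechanisms or MECHANISMS)
    if R is None:
        R = assemble_relaxation(system, B0, include=mechanisms)
    rho = initial_state(system, combo, reference_polarization)

    if field_profile is None:
        if pre_times is None:
            n = max(int(round(pre_delay * 2)), 1) + 1
            pre_times = np.linspace(-pre_delay, 0.0, n)
        else:
            pre_times = np.asarray(pre_times, dtype=float)
        traj = propagate(rho, system, B0, R, pre_times + pre_delay, rho_eq=rho_eq,
                         temperature=temperature)
        traj.times = pre_times
        rho0 = traj.states[-1]
    else:
        scaling = transfer_scaling(field_profile, spre_model, system, detection_field=B0)
        t = -field_profile.duration
        seg_trajs = []
        state = rho
        for seg in scaling["segments"]:
            sub = SpinSystem([(s.label, s.isotope) for s in system.spins],
                             system.shifts_ppm, system.j_hz, system.coordinates,
                             csa=system.csa, tau_c=system.tau_c,
                             random_field=seg["amplitudes"], name=system.name,
                             rotation_axis=system.rotation_axis,
                             tau_rotation=system.tau_rotation)
            Rseg = assemble_relaxation(sub, seg["B0_T"], include=mechanisms)
            tt = np.linspace(0.0, seg["duration_s"], max(int(seg["duration_s"] * 2), 2))
            tr = propagate(state, sub, seg["B0_T"], Rseg, tt, rho_eq=rho_eq,
                           temperature=temperature)
            tr.times = tt + t
            t += seg["duration_s"]
            state = tr.states[-1]
            seg_trajs.append(tr)
        traj = seg_trajs[0]
        for tr in seg_trajs[1:]:
            traj.times = np.concatenate([traj.times, tr.times])
            for k in traj.observables:
                traj.observables[k] = np.concatenate([traj.observables[k], tr.observables[k]])
            traj.states.extend(tr.states)
        traj.meta["transfer_scaling"] = scaling
        rho0 = state

    result = {"pre_trajectory": traj, "state_t0": rho0}
    if flip_angles:
        times, records = detection_train(rho0, system, B0, R, flip_angles, interval,
                                         n_scans, rho_eq=rho_eq, temperature=temperature)
        result["scan_times"] = times
        result["scans"] = records
    return result
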