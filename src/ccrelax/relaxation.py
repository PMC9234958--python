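"""Semi-classical (Redfield) relaxation superoperators with mechanism decomposition.

Mechanisms: dipole-dipole auto- and cross-correlated terms, chemical-shift
anisotropy (axially symmetric), CSA-DD interference, and uncorrelated per-spin
random fields.  All rank-2 interactions share the spectral density

    J(omega) = (2/5) * tau_c / (1 + omega^2 tau_c^2)

for rigid isotropic tumbling; every interaction carries its own amplitude so
that observable rates are convention-independent (the heteronuclear two-spin
limit reproduces the Solomon equations exactly).

The superoperator is assembled in the eigenbasis of the lab-frame Hamiltonian
(so the spectral densities are sampled at the true eigenfrequency differences),
secularized there, and returned in the Zeeman product basis.  Liouville vectors
follow column-major (Fortran) vec ordering: vec(A rho B) = kron(B.T, A) vec(rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .spinsys import EnergyLevelDiagram, SpinSystem, eigenstate_labels

__all__ = [
    "spectral_density",
    "dipolar_superoperator",
    "csa_superoperator",
    "csa_dd_cross_superoperator",
    "random_field_superoperator",
    "assemble_relaxation",
    "population_relaxation_matrix",
    "pathway_graph",
    "calibrate_random_field",
    "RelaxationSuperoperator",
    "PopulationRelaxationMatrix",
    "MECHANISMS",
]

MECHANISMS = ("DD_CH-CH", "DD_HH-HH", "DD_CH-HH", "CSA", "CSA-DD", "rnd")

#: factor by which an eigenfrequency mismatch must exceed the largest relaxation
#: rate for the corresponding Redfield element to be dropped (secular cutoff)
SECULAR_FACTOR = 10.0


def spectral_density(tau_c: float, omega) -> np.ndarray:
    """Lorentzian spectral density J(omega) = (2/5) tau_c / (1 + omega^2 tau_c^2)."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    omega = np.asarray(omega, dtype=float)
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


# ---------------------------------------------------------------------------
# interactions


@dataclass
class _Interaction:
    """An axial rank-2 interaction: amplitude (rad/s), axis, spin tensor ops."""

    kind: str          # 'DD_CH', 'DD_HH', 'CSA'
    amplitude: float   # Haeberlen anisotropy delta of the coupling, rad/s
    axis: np.ndarray   # unit vector, molecular frame
    tensors: list      # T_{2,q}, q = -2..2, in the product basis


def _bilinear_tensors(system: SpinSystem, i: int, j: int) -> list:
    """Rank-2 spherical tensor operators built from spins i and j."""
    Iz, Sz = system.op(i, "z"), system.op(j, "z")
    Ip, Sp = system.op(i, "+"), system.op(j, "+")
    Im, Sm = system.op(i, "-"), system.op(j, "-")
    t20 = (2.0 * Iz @ Sz - 0.5 * (Ip @ Sm + Im @ Sp)) / np.sqrt(6.0)
    t2p1 = -0.5 * (Ip @ Sz + Iz @ Sp)
    t2m1 = +0.5 * (Im @ Sz + Iz @ Sm)
    t2p2 = +0.5 * Ip @ Sp
    t2m2 = +0.5 * Im @ Sm
    return [t2m2, t2m1, t20, t2p1, t2p2]


def _csa_tensors(system: SpinSystem, i: int) -> list:
    """Rank-2 tensors of a single-spin coupling to the static field (CSA)."""
    Iz = system.op(i, "z")
    Ip, Im = system.op(i, "+"), system.op(i, "-")
    zero = np.zeros_like(Iz)
    t20 = np.sqrt(2.0 / 3.0) * Iz
    return [zero, 0.5 * Im, t20, -0.5 * Ip, zero]


def _dd_interaction(system: SpinSystem, pair) -> _Interaction:
    i, j = pair
    iso = {system.spins[i].isotope, system.spins[j].isotope}
    kind = "DD_HH" if iso == {"1H"} else "DD_CH"
    return _Interaction(kind, 2.0 * system.dipolar_constant(i, j),
                        system.pair_axis(i, j), _bilinear_tensors(system, i, j))


def _csa_interaction(system: SpinSystem, i: int, B0: float) -> _Interaction:
    csa = system.csa[i]
    omega0 = -system.spins[i].gamma * B0
    return _Interaction("CSA", (2.0 / 3.0) * csa.delta_ppm * 1e-6 * omega0,
                        csa.axis, _csa_tensors(system, i))


def _p2cos(a: np.ndarray, b: np.ndarray) -> float:
    c = float(np.dot(a, b))
    return 0.5 * (3.0 * c * c - 1.0)


# ---------------------------------------------------------------------------
# Redfield double-commutator engine


def _d2m0(m: int, beta: float) -> float:
    """Reduced Wigner elements d^2_{m0}(beta)."""
    if m == 0:
        return 0.5 * (3.0 * np.cos(beta) ** 2 - 1.0)
    if m == 1:
        return -np.sqrt(1.5) * np.sin(beta) * np.cos(beta)
    if m == 2:
        return np.sqrt(3.0 / 8.0) * np.sin(beta) ** 2
    raise ValueError(m)


def _correlation_terms(system, axis_a: np.ndarray, axis_b: np.ndarray):
    """Orientational weights and correlation times for a correlated pair.

    Rigid isotropic tumbling: the single term (P2(cos theta_ab), tau_c).
    With internal rotation about ``system.rotation_axis`` (Woessner rotating
    top), the correlation function splits into m = 0, 1, 2 components with

        weight_m = (2 - delta_m0) d^2_m0(beta_a) d^2_m0(beta_b) cos(m dphi),
        1/tau_m  = 1/tau_c + m^2 / tau_rotation,

    which sums back to P2(cos theta_ab) when tau_rotation -> infinity.
    """
    if system.rotation_axis is None:
        return [(_p2cos(axis_a, axis_b), system.tau_c)]
    n = system.rotation_axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    def angles(a):
        beta = np.arccos(np.clip(np.dot(a, n), -1.0, 1.0))
        phi = np.arctan2(np.dot(a, e2), np.dot(a, e1))
        return beta, phi

    ba, pa = angles(axis_a)
    bb, pb = angles(axis_b)
    out = []
    for m in range(3):
        w = _d2m0(m, ba) * _d2m0(m, bb) * np.cos(m * (pa - pb))
        if m > 0:
            w *= 2.0
        tau_m = 1.0 / (1.0 / system.tau_c + m**2 / system.tau_rotation)
        if w != 0.0:
            out.append((w, tau_m))
    return out


def _pair_superop(inter_a: _Interaction, inter_b: _Interaction, E: np.ndarray,
                  V: np.ndarray, system) -> np.ndarray:
    """Redfield contribution of the correlated pair (a, b) in the eigenbasis.

    R(rho) = (3/4) delta_a delta_b sum_terms w_term
             * sum_q [T^a_q, [K^b_q, rho]]  (+ the (b, a) term added by caller),
    with K^b_q elementwise (T^b_q+)_{kl} J_term(omega_kl); omega_kl = E_k - E_l.
    """
    d = len(E)
    w = E[:, None] - E[None, :]
    terms = _correlation_terms(system, inter_a.axis, inter_b.axis)
    R = np.zeros((d * d, d * d), dtype=complex)
    eye = np.eye(d)
    Aq = [V.conj().T @ t @ V for t in inter_a.tensors]
    Bq = [V.conj().T @ t.conj().T @ V for t in inter_b.tensors]
    for weight, tau in terms:
        Jw = spectral_density(tau, w)
        scale = 0.75 * inter_a.amplitude * inter_b.amplitude * weight
        for q in range(5):
            A = Aq[q]
            K = Bq[q] * Jw
            AK = A @ K
            KA = K @ A
            # [A, [K, rho]] = A K rho - A rho K - K rho A + rho K A
            R += scale * (np.kron(eye, AK) - np.kron(K.T, A)
                          - np.kron(A.T, K) + np.kron(KA.T, eye))
    return R


def _hermitize(R: np.ndarray, d: int) -> np.ndarray:
    """Average R with its adjoint-conjugated image so it maps Hermitian to Hermitian."""
    idx = np.arange(d * d).reshape(d, d, order="F")
    perm = idx.T.reshape(-1, order="F")
    Rc = R.conj()[np.ix_(perm, perm)]
    return 0.5 * (R + Rc)


def _secularize(R: np.ndarray, E: np.ndarray, cutoff: float) -> np.ndarray:
    """Zero Redfield elements connecting coherences with mismatched frequencies.

    An element coupling rho_(kl) to rho_(mn) is kept only when
    |omega_kl - omega_mn| <= cutoff; population rows/columns (omega = 0) are
    always retained together.
    """
    d = len(E)
    w = (E[:, None] - E[None, :]).reshape(-1, order="F")
    keep = np.abs(w[:, None] - w[None, :]) <= cutoff
    return np.where(keep, R, 0.0)


# ---------------------------------------------------------------------------
# public component builders (product-basis matrices)


def _eig(system: SpinSystem, B0: float, diagram=None):
    diagram = diagram or eigenstate_labels(system, B0)
    V = diagram.vectors
    W = np.kron(V.conj(), V)     # vec_prod = W vec_eig
    return diagram, V, W


def _to_product(R_eig, W):
    return W @ R_eig @ W.conj().T


def dipolar_superoperator(system: SpinSystem, pair_a, pair_b, B0: float,
                          diagram=None) -> np.ndarray:
    """DD auto (pair_a == pair_b) or cross-correlated (pair_a != pair_b) term.

    Returned in the Zeeman product basis, unsecularized.  Cross terms are
    weighted by P2(cos theta) between the two internuclear axes and include
    both (a,b) and (b,a) orderings.
    """
    for p in (pair_a, pair_b):
        if system.distance(*p) <= 0:
            raise ValueError(f"unknown geometry for pair {p}")
    diagram, V, W = _eig(system, B0, diagram)
    ia, ib = _dd_interaction(system, tuple(pair_a)), _dd_interaction(system, tuple(pair_b))
    R = _pair_superop(ia, ib, diagram.energies, V, system)
    if tuple(pair_a) != tuple(pair_b):
        R += _pair_superop(ib, ia, diagram.energies, V, system)
    return _to_product(_hermitize(R, system.dim), W)


def csa_superoperator(system: SpinSystem, spin: int, B0: float, diagram=None) -> np.ndarray:
    """CSA auto-relaxation of one spin; scales with B0^2."""
    if spin not in system.csa:
        raise ValueError(f"no CSA parameters for spin {spin}")
    diagram, V, W = _eig(system, B0, diagram)
    ia = _csa_interaction(system, spin, B0)
    R = _pair_superop(ia, ia, diagram.energies, V, system)
    return _to_product(_hermitize(R, system.dim), W)


def csa_dd_cross_superoperator(system: SpinSystem, spin: int, pair, B0: float,
                               diagram=None) -> np.ndarray:
    """CSA-DD interference term; scales with B0^1 and P2 of the inter-axis angle."""
    if spin not in system.csa:
        raise ValueError(f"no CSA orientation for spin {spin}")
    diagram, V, W = _eig(system, B0, diagram)
    ia = _csa_interaction(system, spin, B0)
    ib = _dd_interaction(system, tuple(pair))
    R = (_pair_superop(ia, ib, diagram.energies, V, system)
         + _pair_superop(ib, ia, diagram.energies, V, system))
    return _to_product(_hermitize(R, system.dim), W)


def _rnd_groups(system: SpinSystem, amps: np.ndarray, correlation: str):
    """Group spins sharing one fluctuating field.

    ``correlation='isotope'`` (default): all spins of one isotope feel the same
    random field (e.g. a global fluctuating field over the equivalent protons),
    which preserves the proton exchange symmetry — singlet/triplet and A/E
    manifold populations are then not mixed by the random field, while spins of
    different isotopes fluctuate independently, so proton polarization cannot
    relax into carbon polarization.  ``'independent'`` gives one field per spin.
    """
    if correlation == "independent":
        return [([i], amps[i]) for i in range(system.nspins)]
    if correlation != "isotope":
        raise ValueError("correlation must be 'isotope' or 'independent'")
    groups = []
    for iso in dict.fromkeys(system.isotopes):
        idx = system.indices(iso)
        a = amps[idx]
        if np.ptp(a) > 1e-12 * max(np.max(a), 1e-30):
            raise ValueError(
                f"correlated random field requires equal amplitudes within {iso}")
        groups.append((idx, float(a[0])))
    return groups


def _rnd_superop_eig(system: SpinSystem, amps, tau_rf, E, V, correlation="isotope"):
    d = len(E)
    w = E[:, None] - E[None, :]
    lor = 1.0 / (1.0 + (w * tau_rf) ** 2)
    eye = np.eye(d)
    R = np.zeros((d * d, d * d), dtype=complex)
    for idx, a in _rnd_groups(system, amps, correlation):
        if a == 0.0:
            continue
        for comp in ("x", "y", "z"):
            F = sum(system.op(i, comp) for i in idx)
            A = V.conj().T @ F @ V
            K = A * lor   # A is Hermitian for x, y, z
            AK, KA = A @ K, K @ A
            R += a * (np.kron(eye, AK) - np.kron(K.T, A)
                      - np.kron(A.T, K) + np.kron(KA.T, eye))
    return R


def random_field_superoperator(system: SpinSystem, amplitudes=None, tau_rf=None,
                               B0: float = 0.0, diagram=None,
                               correlation: str = "isotope") -> np.ndarray:
    """Random-field relaxation (sum of double commutators over Ix, Iy, Iz).

    ``amplitudes`` a_i (s^-1) aggregate the squared fluctuation amplitude and
    its correlation time (omega_rf^2 * tau_rf); an isolated spin relaxes at
    R1 = 2 a_i in the extreme-narrowing limit.  See :func:`_rnd_groups` for the
    correlation convention: fields on different isotopes are always
    independent, so a level pair differing in both the proton and the carbon
    state is never connected.
    """
    amps = system.random_field if amplitudes is None else np.asarray(amplitudes, dtype=float)
    if np.ndim(amps) == 0:
        amps = np.full(system.nspins, float(amps))
    if np.any(amps < 0):
        raise ValueError("random-field amplitudes must be >= 0")
    tau_rf = tau_rf or system.tau_c
    diagram, V, W = _eig(system, B0, diagram)
    R = _rnd_superop_eig(system, amps, tau_rf, diagram.energies, V, correlation)
    return _to_product(_hermitize(R, system.dim), W)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class RelaxationSuperoperator:
    """Liouville-space relaxation matrix with per-mechanism decomposition.

    ``matrix`` acts on column-major vec(rho) in the Zeeman product basis; the
    master equation used throughout is d rho/dt = -i[H, rho] - R(rho - rho_eq).
    """

    matrix: np.ndarray
    mechanism_terms: dict
    diagram: EnergyLevelDiagram
    system: SpinSystem
    B0: float
    secularized: bool
    basis: str = "zeeman-product/vec-column-major"

    @property
    def dim(self) -> int:
        return self.system.dim

    def __call__(self, rho: np.ndarray) -> np.ndarray:
        d = self.dim
        return (self.matrix @ rho.reshape(-1, order="F")).reshape(d, d, order="F")

    def to_frame(self, dataframe_labels=True):
        """Dense labeled DataFrame of the total superoperator (CSV-exportable)."""
        import pandas as pd
        d = self.dim
        names = [f"r{k // d}c{k % d}" for k in range(d * d)]
        return pd.DataFrame(self.matrix.real, index=names, columns=names)


def _grouped_interactions(system: SpinSystem, B0: float):
    """Classify every correlated interaction pair into the named mechanism groups."""
    dds = [_dd_interaction(system, p) for p in system.dd_pairs()]
    csas = [_csa_interaction(system, i, B0) for i in sorted(system.csa)] if B0 > 0 else []
    groups = {m: [] for m in MECHANISMS[:-1]}
    for a in range(len(dds)):
        for b in range(a, len(dds)):
            kinds = {dds[a].kind, dds[b].kind}
            if kinds == {"DD_CH"}:
                g = "DD_CH-CH"
            elif kinds == {"DD_HH"}:
                g = "DD_HH-HH"
            else:
                g = "DD_CH-HH"
            groups[g].append((dds[a], dds[b]))
    for a in range(len(csas)):
        for b in range(a, len(csas)):
            groups["CSA"].append((csas[a], csas[b]))
    for c in csas:
        for dd in dds:
            groups["CSA-DD"].append((c, dd))
    return groups


def assemble_relaxation(system: SpinSystem, B0: float, include=MECHANISMS,
                        secular: bool = True, rnd_tau: float | None = None,
                        rnd_correlation: str = "isotope") -> RelaxationSuperoperator:
    """Build the total relaxation superoperator from the requested mechanisms.

    ``include`` names any subset of ``MECHANISMS``; the total is the elementwise
    sum of the named components.  Secularization drops Redfield elements
    connecting coherences whose eigenfrequencies differ by more than
    ``SECULAR_FACTOR`` times the largest relaxation rate; populations are always
    retained.
    """
    include = tuple(include)
    unknown = set(include) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms {sorted(unknown)}; valid: {MECHANISMS}")
    if not include:
        raise ValueError("at least one relaxation mechanism must be enabled")
    diagram = eigenstate_labels(system, B0)
    V = diagram.vectors
    W = np.kron(V.conj(), V)
    d = system.dim
    E = diagram.energies

    groups = _grouped_interactions(system, B0)
    terms = {}
    for name in MECHANISMS[:-1]:
        R = np.zeros((d * d, d * d), dtype=complex)
        for ia, ib in groups[name]:
            R += _pair_superop(ia, ib, E, V, system)
            if ia is not ib:
                R += _pair_superop(ib, ia, E, V, system)
        terms[name] = _hermitize(R, d)
    # random field (built directly in the eigenbasis)
    tau_rf = rnd_tau or system.tau_c
    Rrnd = _rnd_superop_eig(system, system.random_field, tau_rf, E, V,
                            correlation=rnd_correlation)
    terms["rnd"] = _hermitize(Rrnd, d)

    total = sum(terms[m] for m in include)
    if secular:
        max_rate = max(np.max(np.abs(total)), 1e-30)
        cutoff = SECULAR_FACTOR * max_rate
        total = _secularize(total, E, cutoff)
        terms = {m: _secularize(terms[m], E, cutoff) for m in terms}
    total_prod = W @ total @ W.conj().T
    terms_prod = {m: W @ terms[m] @ W.conj().T for m in terms}
    return RelaxationSuperoperator(total_prod, terms_prod, diagram, system, B0,
                                   secularized=secular)


# ---------------------------------------------------------------------------
# population projection and pathway graph


@dataclass
class PopulationRelaxationMatrix:
    """Rates (s^-1) connecting eigenstate populations: dp/dt = -M (p - p_eq)."""

    matrix: np.ndarray
    labels: list
    diagram: EnergyLevelDiagram
    mechanism_variants: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self):
        import pandas as pd
        names = [self.diagram.label_str(i) for i in range(self.dim)]
        return pd.DataFrame(self.matrix, index=names, columns=names)


def _population_block(R_prod: np.ndarray, V: np.ndarray) -> np.ndarray:
    d = V.shape[0]
    W = np.kron(V.conj(), V)
    R_eig = W.conj().T @ R_prod @ W
    idx = np.arange(d) * d + np.arange(d)   # diagonal elements in column-major vec
    return R_eig[np.ix_(idx, idx)].real


def population_relaxation_matrix(R: RelaxationSuperoperator,
                                 diagram: EnergyLevelDiagram | None = None) -> PopulationRelaxationMatrix:
    """Project the superoperator onto the eigenstate-population subspace.

    Couplings between populations and coherences are discarded here (they are
    retained in the full superoperator used for propagation).
    """
    diagram = diagram or R.diagram
    if diagram.dim != R.dim or abs(diagram.B0 - R.B0) > 1e-12:
        raise ValueError("diagram and superoperator were built for different systems/fields")
    V = diagram.vectors
    M = _population_block(R.matrix, V)
    variants = {m: _population_block(Rm, V) for m, Rm in R.mechanism_terms.items()}
    labels = [diagram.label_str(i) for i in range(diagram.dim)]
    return PopulationRelaxationMatrix(M, labels, diagram, variants)


def _ring_positions(popR: PopulationRelaxationMatrix):
    """Circular layout: alpha-carbon levels on the left, beta on the right;
    T/A manifolds toward the top, S/E toward the bottom."""
    diagram = popR.diagram
    order_key = []
    for i in range(popR.dim):
        lab = diagram.labels[i]
        man = lab[0] if lab else f"z{i}"
        carbon = lab[1] if lab else "a"
        top = 0 if man.startswith(("T", "A")) else 1
        order_key.append((carbon, top, man, i))
    left = sorted([k for k in order_key if k[0] == "a"], key=lambda t: (t[1], t[2]))
    right = sorted([k for k in order_key if k[0] != "a"], key=lambda t: (t[1], t[2]))
    pos = {}
    nl, nr = max(len(left), 1), max(len(right), 1)
    for rank, (_, _, _, i) in enumerate(left):     # sweep the left semicircle top to bottom
        ang = np.pi / 2 + np.pi * (rank + 0.5) / nl
        pos[i] = (np.cos(ang), np.sin(ang))
    for rank, (_, _, _, i) in enumerate(right):
        ang = np.pi / 2 - np.pi * (rank + 0.5) / nr
        pos[i] = (np.cos(ang), np.sin(ang))
    return pos


def pathway_graph(popR: PopulationRelaxationMatrix, threshold: float = 0.01) -> nx.Graph:
    """Circular relaxation-pathway graph.

    Nodes are labeled eigenstates on a ring; edges carry |rate| with the sign as
    an attribute (negative rates are the hallmark of cross-correlated terms).
    Edges below ``threshold`` times the largest off-diagonal |rate| are omitted,
    mirroring the 1% pruning used in the reference figures.
    """
    M = popR.matrix
    d = popR.dim
    off = np.abs(M - np.diag(np.diag(M)))
    mx = off.max()
    G = nx.Graph(threshold=threshold)
    pos = _ring_positions(popR)
    for i in range(d):
        G.add_node(i, label=popR.labels[i], x=float(pos[i][0]), y=float(pos[i][1]))
    if mx == 0:
        return G
    cut = threshold * mx
    for i in range(d):
        for j in range(i + 1, d):
            if np.abs(M[i, j]) >= cut and np.abs(M[i, j]) > 0:
                G.add_edge(i, j, weight=float(np.abs(M[i, j])),
                           sign=int(np.sign(M[i, j])), rate=float(M[i, j]))
    return G


# ---------------------------------------------------------------------------
# calibration


def fitted_proton_r1(system: SpinSystem, B0: float = 11.7, t_max: float = 60.0,
                     include=MECHANISMS) -> float:
    """Mono-exponential rate fitted to the simulated total-proton decay.

    This is the quantity the experimental fixture pins down: the proton-only
    species is started at uniform proton polarization and the total 1H signal
    over ``t_max`` (sampled once per second, as detected) is fitted to a single
    exponential.
    """
    from scipy.optimize import curve_fit

    from .dynamics import initial_state, propagate
    nh = len(system.indices("1H"))
    R = assemble_relaxation(system, B0, include=include)
    rho0 = initial_state(system, {"Hz": 1.0}, 1.0 / nh)
    ts = np.arange(0.0, t_max + 1.0)
    tr = propagate(rho0, system, B0, R, ts, rho_eq="unit", store_states=False)
    h = tr.observables["Hz_total"]
    p, _ = curve_fit(lambda t, a, r: a * np.exp(-r * t), ts, h, p0=[h[0], 0.1])
    return float(p[1])


def calibrate_random_field(make_system, target_r1: float, B0: float = 11.7,
                           tol: float = 1e-7, max_iter: int = 20) -> float:
    """Random-field amplitude a (s^-1, same on every spin) such that the fitted
    mono-exponential proton decay rate of the proton-only species equals
    ``target_r1`` (the bundled fixture time constant).

    ``make_system(a)`` must build the proton-only (carbon-12) species with
    random-field amplitude ``a``.  The coherent (DD/CSA) mechanisms contribute
    whatever the system's declared correlation times give; the random field
    supplies the remainder (an isolated spin relaxes at R1 = 2a).
    """
    a = 0.0
    r = fitted_proton_r1(make_system(a), B0)
    if r >= target_r1:
        return 0.0
    for _ in range(max_iter):
        a += 0.5 * (target_r1 - r)
        r = fitted_proton_r1(make_system(a), B0)
        if abs(r - target_r1) <= tol:
            break
    return float(a)


def calibrate_relaxation(make_system, target_r1: float, B0: float = 11.7,
                         dd_fraction: float = 0.5, tol: float = 1e-7):
    """Solve (tau_c, random-field amplitude) against the fixture proton decay.

    ``make_system(tau_c, a)`` must build the proton-only (carbon-12) species.
    The single fixture rate cannot pin down two parameters, so a declared split
    is used: the coherent (DD + CSA) mechanisms supply ``dd_fraction`` of the
    fitted rate, the random field the rest.  In the extreme-narrowing regime
    the coherent rate is linear in tau_c, which the secant iteration exploits.
    Returns (tau_c, amplitude).
    """
    if not (0.0 < dd_fraction <= 1.0):
        raise ValueError("dd_fraction must lie in (0, 1]")
    goal = dd_fraction * target_r1
    tau = make_system(1e-12, 0.0).tau_c
    r1 = fitted_proton_r1(make_system(tau, 0.0), B0)
    for _ in range(40):
        if abs(r1 - goal) <= tol:
            break
        tau *= goal / r1
        r1 = fitted_proton_r1(make_system(tau, 0.0), B0)
    a = calibrate_random_field(lambda a: make_system(tau, a), target_r1, B0, tol=tol)
    return float(tau), float(a)
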