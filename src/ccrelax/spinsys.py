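"""Spin systems, coherent Hamiltonians and symmetry-adapted manifolds for CHn groups.

The Hilbert space is the tensor product of spin-1/2 spaces ordered as the spins are
listed (the bundled builders put the carbon first, then the protons), with the
|m=+1/2> (alpha) state before |m=-1/2> within each spin.  This ordering is fixed so
that serialized matrices are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM, GAMMA, HBAR, MU0_OVER_4PI

__all__ = [
    "Spin",
    "SpinSystem",
    "ManifoldDecomposition",
    "EnergyLevelDiagram",
    "build_spin_system",
    "coherent_hamiltonian",
    "singlet_triplet_states",
    "methyl_symmetry_states",
    "eigenstate_labels",
    "ch3_system",
    "ch2_system",
]

# ---------------------------------------------------------------------------
# elementary operators

_SZ = np.diag([0.5, -0.5]).astype(complex)
_SP = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)
_SM = _SP.T.conj()
_SX = 0.5 * (_SP + _SM)
_SY = -0.5j * (_SP - _SM)
_ID2 = np.eye(2, dtype=complex)


def _embed(op: np.ndarray, index: int, n: int) -> np.ndarray:
    """Embed a single-spin operator at position *index* in an n-spin product space."""
    out = np.array([[1.0 + 0j]])
    for k in range(n):
        out = np.kron(out, op if k == index else _ID2)
    return out


@dataclass(frozen=True)
class Spin:
    label: str
    isotope: str
    gamma: float  # rad s^-1 T^-1


@dataclass
class CSA:
    """Axially symmetric chemical-shift anisotropy.

    ``delta_ppm`` is the shift anisotropy (the usual "delta sigma" quoted in
    ppm); ``axis`` is the unique principal axis in the molecular frame.
    """

    delta_ppm: float
    axis: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("CSA axis must be a nonzero vector")
        self.axis = a / n


class SpinSystem:
    """A rigid, isotropically tumbling system of spin-1/2 nuclei.

    Parameters
    ----------
    spins : list of (label, isotope) or Spin
    shifts_ppm : isotropic chemical shifts, one per spin
    j_hz : symmetric matrix of scalar couplings in Hz
    coordinates : (n, 3) Cartesian coordinates in Angstrom
    csa : mapping spin index -> CSA (optional per spin)
    tau_c : rotational correlation time in seconds
    random_field : per-spin random-field amplitude a_i in s^-1, defined as the
        squared fluctuation amplitude times its correlation time (omega_rf^2 * tau);
        an isolated spin then relaxes longitudinally at R1 = 2 a_i in the
        extreme-narrowing limit.
    """

    def __init__(self, spins, shifts_ppm, j_hz, coordinates, csa=None, tau_c=1e-11,
                 random_field=None, name="", rotation_axis=None, tau_rotation=None):
        self.spins = [
            s if isinstance(s, Spin) else Spin(s[0], s[1], GAMMA[s[1]]) for s in spins
        ]
        n = len(self.spins)
        self.shifts_ppm = np.asarray(shifts_ppm, dtype=float)
        self.j_hz = np.asarray(j_hz, dtype=float)
        self.coordinates = np.asarray(coordinates, dtype=float)
        self.csa = dict(csa or {})
        self.tau_c = float(tau_c)
        rf = np.zeros(n) if random_field is None else np.asarray(random_field, dtype=float)
        if np.isscalar(random_field):
            rf = np.full(n, float(random_field))
        self.random_field = rf
        self.name = name
        # optional internal rotation (Woessner rotating-top model): unit axis in
        # the molecular frame plus the internal rotational correlation time
        if rotation_axis is not None:
            rotation_axis = np.asarray(rotation_axis, dtype=float)
            rotation_axis = rotation_axis / np.linalg.norm(rotation_axis)
            if tau_rotation is None or tau_rotation <= 0:
                raise ValueError("tau_rotation must be > 0 when rotation_axis is set")
        self.rotation_axis = rotation_axis
        self.tau_rotation = tau_rotation
        self._validate()
        self._ops_cache: dict = {}

    # -- validation ---------------------------------------------------------
    def _validate(self):
        n = self.nspins
        if self.shifts_ppm.shape != (n,):
            raise ValueError("shifts_ppm must have one entry per spin")
        if self.j_hz.shape != (n, n):
            raise ValueError("j_hz must be an n x n matrix")
        if not np.allclose(self.j_hz, self.j_hz.T):
            raise ValueError("j_hz must be symmetric")
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n, 3) in Angstrom")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if any(s.gamma == 0 for s in self.spins):
            raise ValueError("gyromagnetic ratios must be nonzero")
        if np.any(self.random_field < 0):
            raise ValueError("random-field amplitudes must be >= 0")
        for i in range(n):
            for j in range(i + 1, n):
                if self.distance(i, j) <= 0:
                    raise ValueError(f"coincident spins {i}, {j}: zero internuclear distance")

    # -- basic queries --------------------------------------------------------
    @property
    def nspins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.nspins

    @property
    def isotopes(self):
        return [s.isotope for s in self.spins]

    def indices(self, isotope: str):
        return [i for i, s in enumerate(self.spins) if s.isotope == isotope]

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def pair_axis(self, i: int, j: int) -> np.ndarray:
        v = self.coordinates[i] - self.coordinates[j]
        return v / np.linalg.norm(v)

    def dipolar_constant(self, i: int, j: int) -> float:
        """b_ij = -(mu0/4pi) gamma_i gamma_j hbar / r_ij^3 in rad s^-1."""
        r = self.distance(i, j) * ANGSTROM
        return -MU0_OVER_4PI * self.spins[i].gamma * self.spins[j].gamma * HBAR / r**3

    def dd_pairs(self):
        """All spin pairs (i < j), each a candidate dipolar interaction."""
        n = self.nspins
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    # -- operators ------------------------------------------------------------
    def op(self, index: int, component: str) -> np.ndarray:
        key = (index, component)
        if key not in self._ops_cache:
            base = {"x": _SX, "y": _SY, "z": _SZ, "+": _SP, "-": _SM}[component]
            self._ops_cache[key] = _embed(base, index, self.nspins)
        return self._ops_cache[key]

    def total_op(self, isotope: str, component: str) -> np.ndarray:
        out = np.zeros((self.dim, self.dim), dtype=complex)
        for i in self.indices(isotope):
            out += self.op(i, component)
        return out

    def larmor(self, index: int, B0: float, with_shift: bool = True) -> float:
        """Lab-frame Larmor frequency omega_0 = -gamma B0 (1 + delta) in rad/s."""
        d = self.shifts_ppm[index] * 1e-6 if with_shift else 0.0
        return -self.spins[index].gamma * B0 * (1.0 + d)

    def __repr__(self):
        iso = "".join(self.isotopes)
        return f"SpinSystem({self.name or iso}, n={self.nspins}, dim={self.dim})"


# ---------------------------------------------------------------------------
# construction from a structured config


def build_spin_system(spec: dict) -> SpinSystem:
    """Build a validated SpinSystem from a structured (already parsed) config.

    Expected keys: ``spins`` (list of {label, isotope, shift_ppm, xyz, csa_ppm,
    csa_axis}), ``j_couplings`` (list of {pair: [label, label], hz}), ``tau_c``,
    ``random_field`` (scalar or per-spin map), optional ``name``.
    """
    spins_cfg = spec["spins"]
    labels = [s["label"] for s in spins_cfg]
    if len(set(labels)) != len(labels):
        raise ValueError("spin labels must be unique")
    for s in spins_cfg:
        if s["isotope"] not in GAMMA:
            raise ValueError(f"unknown isotope {s['isotope']!r}; supported: 1H, 13C, 2H")
    spins = [(s["label"], s["isotope"]) for s in spins_cfg]
    shifts = [float(s.get("shift_ppm", 0.0)) for s in spins_cfg]
    coords = [s["xyz"] for s in spins_cfg]
    n = len(spins)
    j = np.zeros((n, n))
    for c in spec.get("j_couplings", []):
        a, b = (labels.index(x) for x in c["pair"])
        j[a, b] = j[b, a] = float(c["hz"])
    csa = {}
    for i, s in enumerate(spins_cfg):
        if s.get("csa_ppm"):
            csa[i] = CSA(float(s["csa_ppm"]), np.asarray(s["csa_axis"], dtype=float))
    rf = spec.get("random_field", 0.0)
    if isinstance(rf, dict):
        rf = [float(rf.get(lab, 0.0)) for lab in labels]
    tau_c = float(spec.get("tau_c", 0.0))
    if tau_c <= 0:
        raise ValueError("tau_c must be given and positive")
    rot = spec.get("rotation_axis")
    tau_rot = spec.get("tau_rotation")
    return SpinSystem(spins, shifts, j, coords, csa=csa, tau_c=tau_c,
                      random_field=rf, name=spec.get("name", ""),
                      rotation_axis=np.asarray(rot, dtype=float) if rot is not None else None,
                      tau_rotation=float(tau_rot) if tau_rot else None)


def _tetrahedral_h(r_ch: float, n: int) -> np.ndarray:
    """Cartesian proton positions of an ideal CHn fragment, carbon at the origin.

    The (pseudo) threefold axis is along +z; protons point 'down'.
    """
    theta = np.deg2rad(180.0 - 109.4712206)  # angle from -z
    out = []
    for k in range(n):
        phi = 2 * np.pi * k / 3.0
        out.append(r_ch * np.array([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            -np.cos(theta),
        ]))
    return np.array(out)


def ch3_system(tau_c=5e-12, random_field=0.0, j_ch=140.0, j_hh=-12.0,
               shift_c=50.0, shift_h=3.4, csa_c=25.0, csa_h=1.0,
               r_ch=1.09, carbon=True, tau_rotation=None) -> SpinSystem:
    """Methanol-like (13)CH3 fragment with ideal tetrahedral geometry.

    With ``carbon=False`` the 12CH3 isotopologue is returned (protons only),
    which is the natural-abundance species dominating the 1H signal.  A finite
    ``tau_rotation`` turns on internal rotation about the C3 (z) axis
    (Woessner rotating-top motional model).
    """
    hpos = _tetrahedral_h(r_ch, 3)
    if carbon:
        spins = [("C", "13C"), ("H1", "1H"), ("H2", "1H"), ("H3", "1H")]
        coords = np.vstack([[0.0, 0.0, 0.0], hpos])
        shifts = [shift_c, shift_h, shift_h, shift_h]
        n = 4
        j = np.zeros((4, 4))
        j[0, 1:] = j[1:, 0] = j_ch
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                if a != b:
                    j[a, b] = j_hh
        csa = {0: CSA(csa_c, np.array([0.0, 0.0, 1.0]))}
        for i in (1, 2, 3):
            csa[i] = CSA(csa_h, coords[i] / np.linalg.norm(coords[i]))
    else:
        spins = [("H1", "1H"), ("H2", "1H"), ("H3", "1H")]
        coords = hpos
        shifts = [shift_h] * 3
        j = np.full((3, 3), j_hh)
        np.fill_diagonal(j, 0.0)
        csa = {i: CSA(csa_h, coords[i] / np.linalg.norm(coords[i])) for i in range(3)}
    rot = np.array([0.0, 0.0, 1.0]) if tau_rotation else None
    return SpinSystem(spins, shifts, j, coords, csa=csa, tau_c=tau_c,
                      random_field=random_field, name="ch3" if carbon else "ch3_12c",
                      rotation_axis=rot, tau_rotation=tau_rotation)


def ch2_system(tau_c=2e-11, random_field=0.0, j_ch=142.0, j_hh=-12.0,
               shift_c=63.0, shift_h=3.7, csa_c=30.0, csa_h=1.0,
               r_ch=1.09, carbon=True) -> SpinSystem:
    """Ethylene-glycol-like (13)CH2 fragment with ideal tetrahedral geometry."""
    half = np.deg2rad(109.4712206 / 2.0)
    h1 = r_ch * np.array([np.sin(half), 0.0, -np.cos(half)])
    h2 = r_ch * np.array([-np.sin(half), 0.0, -np.cos(half)])
    if carbon:
        spins = [("C", "13C"), ("H1", "1H"), ("H2", "1H")]
        coords = np.vstack([[0.0, 0.0, 0.0], h1, h2])
        shifts = [shift_c, shift_h, shift_h]
        j = np.array([[0.0, j_ch, j_ch], [j_ch, 0.0, j_hh], [j_ch, j_hh, 0.0]])
        csa = {
            0: CSA(csa_c, np.array([0.0, 0.0, 1.0])),
            1: CSA(csa_h, h1 / np.linalg.norm(h1)),
            2: CSA(csa_h, h2 / np.linalg.norm(h2)),
        }
    else:
        spins = [("H1", "1H"), ("H2", "1H")]
        coords = np.vstack([h1, h2])
        shifts = [shift_h] * 2
        j = np.array([[0.0, j_hh], [j_hh, 0.0]])
        csa = {i: CSA(csa_h, coords[i] / np.linalg.norm(coords[i])) for i in range(2)}
    return SpinSystem(spins, shifts, j, coords, csa=csa, tau_c=tau_c,
                      random_field=random_field, name="ch2" if carbon else "ch2_12c")


# ---------------------------------------------------------------------------
# coherent Hamiltonian


def coherent_hamiltonian(system: SpinSystem, B0: float, frame: str = "rotating") -> np.ndarray:
    """Zeeman + scalar-coupling Hamiltonian in rad/s.

    ``frame='rotating'`` gives the doubly (multiply) rotating frame at each
    isotope's unshifted Larmor frequency: Zeeman terms reduce to chemical-shift
    offsets and heteronuclear J couplings are truncated to their secular
    2*pi*J Iz*Sz part.  ``frame='lab'`` keeps absolute Zeeman energies and the
    full isotropic J couplings; it is used for Boltzmann populations and for the
    eigenfrequencies entering the relaxation superoperator.
    """
    if B0 < 0:
        raise ValueError("B0 must be >= 0")
    n, d = system.nspins, system.dim
    H = np.zeros((d, d), dtype=complex)
    for i in range(n):
        if frame == "lab":
            w = system.larmor(i, B0)
        elif frame == "rotating":
            w = -system.spins[i].gamma * B0 * system.shifts_ppm[i] * 1e-6
        else:
            raise ValueError("frame must be 'lab' or 'rotating'")
        H += w * system.op(i, "z")
    for i in range(n):
        for j in range(i + 1, n):
            jij = system.j_hz[i, j]
            if jij == 0.0:
                continue
            hetero = system.spins[i].isotope != system.spins[j].isotope
            zz = system.op(i, "z") @ system.op(j, "z")
            if frame == "rotating" and hetero:
                H += 2 * np.pi * jij * zz
            else:
                flip = 0.5 * (system.op(i, "+") @ system.op(j, "-")
                              + system.op(i, "-") @ system.op(j, "+"))
                H += 2 * np.pi * jij * (zz + flip)
    return H


# ---------------------------------------------------------------------------
# symmetry manifolds


@dataclass
class ManifoldDecomposition:
    """Symmetry-adapted orthonormal basis of a proton Zeeman product space."""

    basis: np.ndarray          # columns are state vectors
    labels: list               # manifold tag per column, e.g. "T0" or "Ea,+1/2"
    manifolds: dict = field(default_factory=dict)  # manifold -> list of column indices

    @property
    def dim(self) -> int:
        return self.basis.shape[0]

    def projector(self, manifold: str) -> np.ndarray:
        cols = self.manifolds[manifold]
        V = self.basis[:, cols]
        return V @ V.conj().T

    def projectors(self) -> dict:
        return {m: self.projector(m) for m in self.manifolds}


def _ket(bits, n):
    """Product state |b1 b2 ... bn> with 0 = alpha (m=+1/2)."""
    v = np.zeros(2 ** n, dtype=complex)
    idx = 0
    for b in bits:
        idx = (idx << 1) | b
    v[idx] = 1.0
    return v


def singlet_triplet_states(dim: int = 4) -> ManifoldDecomposition:
    """Singlet/triplet decomposition of a two-proton Zeeman space.

    The triplet manifold is symmetric under proton exchange, the singlet
    antisymmetric; population flow between them is symmetry-forbidden for
    in-pair dipolar and uncorrelated random-field relaxation.
    """
    if dim != 4:
        raise ValueError("two spin-1/2 protons required (dimension 4)")
    s2 = 1.0 / np.sqrt(2.0)
    basis = np.column_stack([
        _ket([0, 0], 2),
        s2 * (_ket([0, 1], 2) + _ket([1, 0], 2)),
        _ket([1, 1], 2),
        s2 * (_ket([0, 1], 2) - _ket([1, 0], 2)),
    ])
    labels = ["T+1", "T0", "T-1", "S"]
    manifolds = {"T": [0, 1, 2], "S": [3]}
    return ManifoldDecomposition(basis, labels, manifolds)


def methyl_symmetry_states(dim: int = 8) -> ManifoldDecomposition:
    """A/Ea/Eb decomposition of a three-proton Zeeman space.

    The eight proton states split into the three irreducible representations of
    the C3 permutation group: four A states (totally symmetric, F = 3/2) and two
    conjugate E manifolds of two states each, picking up phases exp(+-2*pi*i/3)
    under cyclic permutation.
    """
    if dim != 8:
        raise ValueError("three spin-1/2 protons required (dimension 8)")
    w = np.exp(2j * np.pi / 3.0)
    s3 = 1.0 / np.sqrt(3.0)
    up_perms = [[0, 0, 1], [0, 1, 0], [1, 0, 0]]      # one proton down, m = +1/2
    dn_perms = [[1, 1, 0], [1, 0, 1], [0, 1, 1]]      # one proton up,  m = -1/2

    def combo(perms, phases):
        return s3 * sum(p * _ket(b, 3) for p, b in zip(phases, perms))

    cols = [
        _ket([0, 0, 0], 3),
        combo(up_perms, [1, 1, 1]),
        combo(dn_perms, [1, 1, 1]),
        _ket([1, 1, 1], 3),
        combo(up_perms, [1, w, w**2]),
        combo(dn_perms, [1, w, w**2]),
        combo(up_perms, [1, w**2, w]),
        combo(dn_perms, [1, w**2, w]),
    ]
    basis = np.column_stack(cols)
    labels = ["A,+3/2", "A,+1/2", "A,-1/2", "A,-3/2",
              "Ea,+1/2", "Ea,-1/2", "Eb,+1/2", "Eb,-1/2"]
    manifolds = {"A": [0, 1, 2, 3], "Ea": [4, 5], "Eb": [6, 7]}
    return ManifoldDecomposition(basis, labels, manifolds)


def proton_manifolds(system: SpinSystem) -> ManifoldDecomposition | None:
    """Manifold decomposition of the proton subspace for CH2/CH3-type systems."""
    nh = len(system.indices("1H"))
    if nh == 2:
        return singlet_triplet_states()
    if nh == 3:
        return methyl_symmetry_states()
    return None


def exchange_operator(system: SpinSystem, perm: dict) -> np.ndarray:
    """Unitary permutation of spins, given as a map old index -> new index."""
    n = system.nspins
    d = system.dim
    U = np.zeros((d, d))
    for s in range(d):
        bits = [(s >> (n - 1 - k)) & 1 for k in range(n)]
        new = [0] * n
        for old_i, new_i in perm.items():
            new[new_i] = bits[old_i]
        for k in range(n):
            if k not in perm:
                new[k] = bits[k]
        t = 0
        for b in new:
            t = (t << 1) | b
        U[t, s] = 1.0
    return U


# ---------------------------------------------------------------------------
# labeled energy-level diagram


@dataclass
class EnergyLevelDiagram:
    """Hamiltonian eigenstates tagged by (proton manifold, 13C alpha/beta)."""

    energies: np.ndarray      # rad/s, ascending
    vectors: np.ndarray       # columns, symmetry-adapted within degenerate clusters
    labels: list              # (manifold_label, carbon_label) or None if ambiguous
    ambiguous: list           # indices of levels that could not be labeled
    B0: float = 0.0

    @property
    def dim(self) -> int:
        return len(self.energies)

    def label_str(self, i: int) -> str:
        lab = self.labels[i]
        if lab is None:
            return f"level{i}(?)"
        man, carbon = lab
        return f"{man}|{carbon}" if carbon else man


_OVERLAP_THRESHOLD = 0.8  # squared overlap below which a label is reported ambiguous


def eigenstate_labels(system: SpinSystem, B0: float,
                      cluster_tol: float = 0.5) -> EnergyLevelDiagram:
    """Diagonalize the lab-frame Hamiltonian and tag each eigenstate.

    Tags are assigned by maximal squared overlap against the candidate basis
    (carbon Zeeman state) x (proton manifold state).  Within numerically
    degenerate eigenvalue clusters the eigenvectors are rotated onto the
    candidates lying in the cluster, so that e.g. the conjugate Ea/Eb methyl
    manifolds come out cleanly instead of as arbitrary real mixtures.  Levels
    whose best squared overlap stays below 0.8 are reported as ambiguous.
    """
    H = coherent_hamiltonian(system, B0, frame="lab")
    E, V = np.linalg.eigh(H)

    md = proton_manifolds(system)
    c_idx = system.indices("13C")
    candidates, cand_labels = _candidate_basis(system, md, c_idx)

    # degenerate clusters (absolute tolerance in rad/s)
    clusters, start = [], 0
    for k in range(1, len(E) + 1):
        if k == len(E) or E[k] - E[k - 1] > cluster_tol:
            clusters.append(list(range(start, k)))
            start = k
    Vad = V.astype(complex).copy()
    forced_ambiguous: set = set()
    for cl in clusters:
        if len(cl) == 1 or candidates is None:
            continue
        P = V[:, cl] @ V[:, cl].conj().T
        proj = P @ candidates                      # candidates projected into cluster
        w = np.einsum("ij,ij->j", proj.conj(), proj).real
        sel = np.where(w > 0.99)[0]
        if len(sel) == len(cl):
            # a degenerate cluster spanning both 13C Zeeman states has no
            # physical alpha/beta distinction: report ambiguity instead
            carbons = {cand_labels[j][1] for j in sel}
            if len(carbons) > 1:
                forced_ambiguous.update(cl)
                continue
            Q, _ = np.linalg.qr(proj[:, sel])      # orthonormalize (Loewdin-like)
            Vad[:, cl] = Q

    labels, ambiguous = [], []
    if candidates is None:
        labels = [None] * len(E)
        ambiguous = list(range(len(E)))
    else:
        ov = np.abs(candidates.conj().T @ Vad) ** 2   # (n_cand, d)
        for i in range(len(E)):
            j = int(np.argmax(ov[:, i]))
            if i not in forced_ambiguous and ov[j, i] >= _OVERLAP_THRESHOLD:
                labels.append(cand_labels[j])
            else:
                labels.append(None)
                ambiguous.append(i)
    return EnergyLevelDiagram(E, Vad, labels, ambiguous, B0=B0)


def _candidate_basis(system, md, c_idx):
    """(carbon Zeeman) x (manifold) candidate vectors in the full product space."""
    if md is None:
        return None, None
    nh = len(system.indices("1H"))
    if system.nspins == nh:                      # proton-only system
        return md.basis, [(lab, "") for lab in md.labels]
    if len(c_idx) != 1 or c_idx[0] != 0 or system.nspins != nh + 1:
        return None, None
    cands, labels = [], []
    for ci, cl in ((0, "a"), (1, "b")):          # carbon alpha / beta
        cvec = np.zeros(2, dtype=complex)
        cvec[ci] = 1.0
        for k, lab in enumerate(md.labels):
            cands.append(np.kron(cvec, md.basis[:, k]))
            labels.append((lab, cl))
    return np.column_stack(cands), labels
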