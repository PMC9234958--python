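import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ccrelax as cx
from ccrelax.relaxation import MECHANISMS
from ccrelax.spinsys import ch2_system, ch3_system

from _oracles import solomon_rates


def _pop_observable(system, R, op):
    """Project an operator onto the eigenstate-population vector."""
    V = R.diagram.vectors
    return np.real(np.diag(V.conj().T @ op @ V))


def _solomon_block(system, R):
    pop = cx.population_relaxation_matrix(R)
    cz = _pop_observable(system, R, 2.0 * system.op(0, "z"))
    hz = _pop_observable(system, R, 2.0 * system.op(1, "z"))
    M = pop.matrix
    return (cz @ M @ cz / (cz @ cz), hz @ M @ hz / (hz @ hz), hz @ M @ cz / (cz @ cz))


class TestSpectralDensity:
    def test_closed_form_at_zero(self):
        assert cx.spectral_density(1e-9, 0.0) == pytest.approx(0.4e-9)

    def test_even_and_monotone_tail(self):
        w = np.geomspace(1e6, 1e12, 50)
        tau = 1e-9
        assert np.allclose(cx.spectral_density(tau, w), cx.spectral_density(tau, -w))
        assert np.all(np.diff(cx.spectral_density(tau, w)) < 0)
        # omega tau >> 1 asymptote: J -> 2/(5 omega^2 tau)
        assert cx.spectral_density(tau, 1e13) == pytest.approx(2 / (5 * 1e26 * tau), rel=1e-4)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            cx.spectral_density(0.0, 1.0)


class TestSolomonOracle:
    @pytest.mark.parametrize("tau", [1e-12, 1e-10, 1e-8])
    @pytest.mark.parametrize("B0", [0.001, 1.0, 11.7])
    def test_two_spin_block_matches_closed_form(self, ch_pair, tau, B0):
        s = ch_pair(tau)
        R = cx.assemble_relaxation(s, B0, include=("DD_CH-CH",))
        rho_c, rho_h, sigma = _solomon_block(s, R)
        rho_i0, rho_s0, sig0 = solomon_rates(s.dipolar_constant(0, 1), tau, B0)
        assert rho_c == pytest.approx(rho_s0, rel=1e-8)
        assert rho_h == pytest.approx(rho_i0, rel=1e-8)
        assert sigma == pytest.approx(sig0, rel=1e-8)

    def test_extreme_narrowing_sigma_over_rho_is_half(self, ch_pair):
        s = ch_pair(1e-12)
        R = cx.assemble_relaxation(s, 0.001, include=("DD_CH-CH",))
        rho_c, _, sigma = _solomon_block(s, R)
        assert sigma / rho_c == pytest.approx(0.5, rel=1e-5)


class TestDipolar:
    def test_two_proton_pair_has_no_singlet_triplet_flow(self):
        s = ch2_system(carbon=False, random_field=0.05)
        R = cx.assemble_relaxation(s, 11.7, include=("DD_HH-HH", "rnd"))
        pop = cx.population_relaxation_matrix(R)
        s_idx = [i for i, l in enumerate(pop.labels) if l.startswith("S")]
        t_idx = [i for i, l in enumerate(pop.labels) if l.startswith("T")]
        flow = max(abs(pop.matrix[i, j]) for i in s_idx for j in t_idx)
        assert flow < 1e-14 * np.max(np.abs(pop.matrix))

    def test_collinear_cross_equals_auto_perpendicular_is_minus_half(self):
        # three collinear spins: pair (0,1) and (1,2) axes parallel -> P2 = 1
        coords = np.array([[0, 0, 0], [0, 0, 1.5], [0, 0, 3.0]])
        s = cx.SpinSystem([("H1", "1H"), ("H2", "1H"), ("H3", "1H")],
                          [0.0] * 3, np.zeros((3, 3)), coords, tau_c=1e-11)
        auto = cx.dipolar_superoperator(s, (0, 1), (0, 1), 11.7)
        cross = cx.dipolar_superoperator(s, (0, 1), (0, 1), 11.7)
        assert np.allclose(auto, cross)
        # perpendicular geometry: P2(0) = -1/2 scales the cross term
        coords_p = np.array([[0, 0, 0], [0, 0, 1.5], [1.5, 0, 1.5]])
        sp = cx.SpinSystem([("H1", "1H"), ("H2", "1H"), ("H3", "1H")],
                           [0.0] * 3, np.zeros((3, 3)), coords_p, tau_c=1e-11)
        from ccrelax.relaxation import _correlation_terms
        (w_perp, _), = _correlation_terms(sp, sp.pair_axis(1, 0), sp.pair_axis(2, 1))
        assert w_perp == pytest.approx(-0.5)

    def test_unknown_pair_geometry_rejected(self, methanol):
        with pytest.raises((ValueError, IndexError)):
            cx.dipolar_superoperator(methanol, (0, 9), (0, 1), 11.7)


class TestCSA:
    def test_zero_field_gives_zero_csa_terms(self, methanol):
        assert np.max(np.abs(cx.csa_superoperator(methanol, 0, 0.0))) == 0.0
        assert np.max(np.abs(cx.csa_dd_cross_superoperator(methanol, 0, (0, 1), 0.0))) == 0.0

    def test_field_scaling_quadratic_auto_linear_cross(self, eg):
        # exact in the extreme-narrowing limit; at picosecond tau_c the
        # spectral densities deviate from J(0) by ~(omega tau)^2 ~ 1e-5
        r1 = cx.csa_superoperator(eg, 0, 5.85)
        r2 = cx.csa_superoperator(eg, 0, 11.7)
        assert np.max(np.abs(r2 - 4.0 * r1)) < 1e-4 * np.max(np.abs(r2))
        c1 = cx.csa_dd_cross_superoperator(eg, 0, (0, 1), 5.85)
        c2 = cx.csa_dd_cross_superoperator(eg, 0, (0, 1), 11.7)
        assert np.max(np.abs(c2 - 2.0 * c1)) < 1e-4 * np.max(np.abs(c2))

    def test_single_spin_csa_r1_closed_form(self):
        # R1 = (2/15) (delta_sigma w0)^2 tau in extreme narrowing
        from ccrelax.spinsys import CSA
        s = cx.SpinSystem([("C", "13C")], [0.0], np.zeros((1, 1)), np.zeros((1, 3)),
                          csa={0: CSA(100.0, np.array([0.0, 0.0, 1.0]))},
                          tau_c=1e-12)
        B0 = 11.7
        R = cx.assemble_relaxation(s, B0, include=("CSA",))
        pop = cx.population_relaxation_matrix(R)
        cz = _pop_observable(s, R, 2.0 * s.op(0, "z"))
        r1 = cz @ pop.matrix @ cz / (cz @ cz)
        w0 = s.spins[0].gamma * B0
        expected = (2.0 / 15.0) * (100e-6 * w0) ** 2 * s.tau_c
        assert r1 == pytest.approx(expected, rel=1e-4)

    def test_missing_csa_rejected(self, ch_pair):
        s = ch_pair(1e-11)
        with pytest.raises(ValueError, match="CSA"):
            cx.csa_superoperator(s, 0, 11.7)


class TestRandomField:
    def test_zero_amplitude_gives_zero_superoperator(self, methanol):
        r = cx.random_field_superoperator(methanol, amplitudes=0.0, B0=11.7)
        assert np.max(np.abs(r)) == 0.0

    def test_no_population_coupling_between_double_flips(self, eg):
        s = ch2_system(random_field=0.1)
        R = cx.assemble_relaxation(s, 11.7, include=("rnd",))
        pop = cx.population_relaxation_matrix(R)
        # level pairs differing in both the 1H and the 13C state stay unconnected
        diag = R.diagram
        for i in range(pop.dim):
            for j in range(pop.dim):
                li, lj = diag.labels[i], diag.labels[j]
                if li and lj and li[0] != lj[0] and li[1] != lj[1]:
                    assert abs(pop.matrix[i, j]) < 1e-12 * np.max(np.abs(pop.matrix))

    def test_mirror_symmetric_rates_across_carbon_states(self):
        s = ch2_system(random_field=0.1)
        R = cx.assemble_relaxation(s, 11.7, include=("rnd",))
        pop = cx.population_relaxation_matrix(R)
        lab_to_idx = {l: i for i, l in enumerate(pop.labels)}
        # rate between (m1|a, m2|a) equals the mirrored (m1|b, m2|b)
        for m1 in ("T+1", "T0", "T-1", "S"):
            for m2 in ("T+1", "T0", "T-1", "S"):
                if m1 == m2:
                    continue
                left = pop.matrix[lab_to_idx[f"{m1}|a"], lab_to_idx[f"{m2}|a"]]
                right = pop.matrix[lab_to_idx[f"{m1}|b"], lab_to_idx[f"{m2}|b"]]
                assert left == pytest.approx(right, abs=1e-9 * max(np.max(np.abs(pop.matrix)), 1))

    def test_independent_mode_relaxes_singlet(self):
        s = ch2_system(carbon=False, random_field=0.05)
        r = cx.random_field_superoperator(s, B0=11.7, correlation="independent")
        diag = cx.eigenstate_labels(s, 11.7)
        V = diag.vectors
        W = np.kron(V.conj(), V)
        pop_idx = np.arange(4) * 4 + np.arange(4)
        M = (W.conj().T @ r @ W)[np.ix_(pop_idx, pop_idx)].real
        s_idx = [i for i, l in enumerate(diag.labels) if l[0] == "S"]
        t_idx = [i for i, l in enumerate(diag.labels) if l[0].startswith("T")]
        assert max(abs(M[i, j]) for i in s_idx for j in t_idx) > 1e-3


class TestAssembly:
    def test_total_is_sum_of_named_components(self, methanol):
        R = cx.assemble_relaxation(methanol, 11.7, secular=False)
        total = sum(R.mechanism_terms[m] for m in MECHANISMS)
        assert np.max(np.abs(R.matrix - total)) < 1e-10 * np.max(np.abs(R.matrix))

    def test_empty_and_unknown_mechanism_sets_rejected(self, methanol):
        with pytest.raises(ValueError):
            cx.assemble_relaxation(methanol, 11.7, include=())
        with pytest.raises(ValueError, match="unknown"):
            cx.assemble_relaxation(methanol, 11.7, include=("DD",))

    def test_population_conservation_per_mechanism(self, methanol_R):
        pop = cx.population_relaxation_matrix(methanol_R)
        scale = np.max(np.abs(pop.matrix))
        for name, M in pop.mechanism_variants.items():
            assert np.max(np.abs(M.sum(axis=0))) < 1e-10 * max(scale, 1e-30), name

    def test_population_matrix_symmetric(self, methanol_R):
        pop = cx.population_relaxation_matrix(methanol_R)
        assert np.max(np.abs(pop.matrix - pop.matrix.T)) < 1e-9 * np.max(np.abs(pop.matrix))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_hermiticity_preserved_on_random_states(self, seed):
        rng = np.random.default_rng(seed)
        s = ch2_system(random_field=0.05)
        R = cx.assemble_relaxation(s, 11.7)
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        rho = 0.5 * (x + x.conj().T)
        out = R(rho)
        assert np.max(np.abs(out - out.conj().T)) < 1e-10 * np.max(np.abs(out))
        assert abs(np.trace(out)) < 1e-10 * np.max(np.abs(out))

    def test_intra_manifold_flow_faster_than_inter(self, eg_R):
        pop = cx.population_relaxation_matrix(eg_R)
        lab = pop.labels
        M = np.abs(pop.matrix)
        intra_t = max(M[i, j] for i in range(8) for j in range(8) if i != j
                      and lab[i].startswith("T") and lab[j].startswith("T")
                      and lab[i][-1] == lab[j][-1])
        inter = max(M[i, j] for i in range(8) for j in range(8)
                    if lab[i].startswith("S") != lab[j].startswith("S"))
        assert intra_t > 1.5 * inter

    def test_hh_dd_connects_ae_but_not_ts(self, methanol, eg):
        p3 = cx.population_relaxation_matrix(
            cx.assemble_relaxation(methanol, 11.7, include=("DD_HH-HH",)))
        a_idx = [i for i, l in enumerate(p3.labels) if l.startswith("A")]
        e_idx = [i for i, l in enumerate(p3.labels) if l.startswith("E")]
        assert max(abs(p3.matrix[i, j]) for i in a_idx for j in e_idx) > 1e-6
        p2 = cx.population_relaxation_matrix(
            cx.assemble_relaxation(eg, 11.7, include=("DD_HH-HH",)))
        s_idx = [i for i, l in enumerate(p2.labels) if l.startswith("S")]
        t_idx = [i for i, l in enumerate(p2.labels) if l.startswith("T")]
        assert max(abs(p2.matrix[i, j]) for i in s_idx for j in t_idx) \
            < 1e-12 * np.max(np.abs(p2.matrix))

    def test_ch_hh_cross_also_connects_ae(self, methanol):
        p = cx.population_relaxation_matrix(
            cx.assemble_relaxation(methanol, 11.7, include=("DD_CH-HH",)))
        a_idx = [i for i, l in enumerate(p.labels) if l.startswith("A")]
        e_idx = [i for i, l in enumerate(p.labels) if l.startswith("E")]
        assert max(abs(p.matrix[i, j]) for i in a_idx for j in e_idx) > 1e-6


class TestPathwayGraph:
    def test_threshold_one_keeps_single_strongest_edge(self, eg_R):
        pop = cx.population_relaxation_matrix(eg_R)
        g = cx.pathway_graph(pop, threshold=1.0)
        assert g.number_of_edges() == 1

    def test_threshold_zero_keeps_all_nonzero_edges(self, eg_R):
        pop = cx.population_relaxation_matrix(eg_R)
        g0 = cx.pathway_graph(pop, threshold=0.0)
        g1 = cx.pathway_graph(pop, threshold=0.01)
        assert g0.number_of_edges() >= g1.number_of_edges() > 0
        assert all(not g0.has_edge(n, n) for n in g0.nodes)

    def test_dd_graph_contains_diagonal_proton_carbon_pathway(self, methanol):
        R = cx.assemble_relaxation(methanol, 11.7, include=("DD_CH-CH",))
        pop = cx.population_relaxation_matrix(R)
        g = cx.pathway_graph(pop, threshold=0.01)
        diag = R.diagram

        def differs_in_both(i, j):
            li, lj = diag.labels[i], diag.labels[j]
            return li and lj and li[0] != lj[0] and li[1] != lj[1]

        assert any(differs_in_both(i, j) for i, j in g.edges)

    def test_edge_sign_attribute_records_negative_rates(self, methanol_R):
        pop = cx.population_relaxation_matrix(methanol_R)
        g = cx.pathway_graph(pop, threshold=0.0)
        signs = {d["sign"] for _, _, d in g.edges(data=True)}
        assert signs <= {-1, 1}
        assert -1 in signs  # cross-correlated pathways carry negative rates

    def test_graphml_round_trip(self, eg_R, tmp_path):
        import networkx as nx
        pop = cx.population_relaxation_matrix(eg_R)
        g = cx.pathway_graph(pop)
        p = tmp_path / "g.graphml"
        nx.write_graphml(g, p)
        g2 = nx.read_graphml(p)
        assert g2.number_of_nodes() == g.number_of_nodes()
        assert g2.number_of_edges() == g.number_of_edges()
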