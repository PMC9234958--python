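import numpy as np
import pytest

import ccrelax as cx
from ccrelax.spinsys import ch3_system, exchange_operator

from _oracles import boltzmann_populations, geometric_depletion


class TestImbalanceOperator:
    def test_traceless_and_sign_convention(self, methanol, eg):
        q_ae = cx.imbalance_operator(methanol, "AE")
        q_ts = cx.imbalance_operator(eg, "TS")
        assert abs(np.trace(q_ae)) < 1e-12
        assert abs(np.trace(q_ts)) < 1e-12
        # positive coefficient overpopulates E / S
        from ccrelax.spinsys import methyl_symmetry_states, singlet_triplet_states
        md = methyl_symmetry_states()
        pe = np.kron(np.eye(2), md.projector("Ea") + md.projector("Eb"))
        assert np.real(np.trace(q_ae @ pe)) > 0
        ps = np.kron(np.eye(2), singlet_triplet_states().projector("S"))
        assert np.real(np.trace(q_ts @ ps)) > 0

    def test_ae_commutes_with_all_proton_permutations(self, methanol):
        q = cx.imbalance_operator(methanol, "AE")
        perms = [{1: 2, 2: 1}, {1: 2, 2: 3, 3: 1}, {2: 3, 3: 2}]
        for perm in perms:
            U = exchange_operator(methanol, perm)
            assert np.max(np.abs(U @ q - q @ U)) < 1e-12

    def test_thermal_expectation_vanishes(self, methanol):
        """Boltzmann oracle: at 298 K / 11.7 T the manifold imbalance is ~0."""
        H = cx.coherent_hamiltonian(methanol, 11.7, frame="lab")
        e, v = np.linalg.eigh(H)
        pops = boltzmann_populations(e)
        q = cx.imbalance_operator(methanol, "AE")
        q_eig = np.real(np.diag(v.conj().T @ q @ v))
        expect = float(pops @ q_eig)
        assert abs(expect) < 1e-6 * np.max(np.abs(np.linalg.eigvalsh(q)))

    def test_incompatible_kind_rejected(self, methanol, eg):
        with pytest.raises(ValueError):
            cx.imbalance_operator(methanol, "TS")
        with pytest.raises(ValueError):
            cx.imbalance_operator(eg, "AE")


class TestInitialState:
    def test_empty_combination_gives_infinite_temperature_state(self, methanol):
        rho = cx.initial_state(methanol, {})
        assert np.allclose(rho.operator, np.eye(16) / 16)

    def test_hz_coefficient_sets_proton_polarization(self, methanol):
        rho = cx.initial_state(methanol, {"Hz": -1.0}, reference_polarization=0.25)
        for i in methanol.indices("1H"):
            assert rho.expect(2.0 * methanol.op(i, "z")) == pytest.approx(-0.25)
        assert rho.expect(2.0 * methanol.op(0, "z")) == pytest.approx(0.0, abs=1e-14)

    def test_negative_populations_rejected_with_level_report(self, methanol):
        with pytest.raises(ValueError, match="negative population"):
            cx.initial_state(methanol, {"Hz": -1.0, "Cz": -0.01, "AE": 3.0},
                             reference_polarization=1.0)

    def test_paper_combination_physical_at_reduced_scale(self, methanol):
        rho = cx.initial_state(methanol, {"Hz": -1.0, "Cz": -0.01, "AE": 3.0},
                               reference_polarization=0.1)
        evals = np.linalg.eigvalsh(rho.operator)
        assert evals.min() >= -1e-14
        # E manifold overpopulated, 1H and 13C polarizations negative
        q = cx.imbalance_operator(methanol, "AE")
        assert rho.expect(q) > 0
        assert rho.expect(2 * methanol.op(1, "z")) < 0
        assert rho.expect(2 * methanol.op(0, "z")) < 0

    def test_cz_without_carbon_rejected(self):
        s = ch3_system(carbon=False)
        with pytest.raises(ValueError, match="13C"):
            cx.initial_state(s, {"Cz": 0.5})


class TestPropagate:
    def test_thermal_state_is_stationary(self, methanol, methanol_R):
        rho_eq = cx.thermal_state(methanol, 11.7)
        tr = cx.propagate(rho_eq, methanol, 11.7, methanol_R, [0.0, 5.0, 10.0])
        for name, vals in tr.observables.items():
            assert vals == pytest.approx(np.full_like(vals, vals[0]), abs=1e-10)

    def test_long_time_limit_reaches_equilibrium(self, methanol, methanol_R):
        rho0 = cx.initial_state(methanol, {"Hz": 0.3}, 1.0)
        tr = cx.propagate(rho0, methanol, 11.7, methanol_R, [0.0, 200.0])
        rho_eq = cx.thermal_state(methanol, 11.7).operator
        assert np.linalg.norm(tr.states[-1].operator - rho_eq) < 1e-6

    def test_semigroup_property(self, eg, eg_R):
        rho0 = cx.initial_state(eg, {"Hz": 0.4, "TS": 0.2}, 0.5)
        one = cx.propagate(rho0, eg, 11.7, eg_R, [0.0, 7.0]).states[-1]
        two = cx.propagate(rho0, eg, 11.7, eg_R, [0.0, 3.0, 7.0]).states[-1]
        assert np.max(np.abs(one.operator - two.operator)) < 1e-9

    def test_trace_and_hermiticity_along_trajectory(self, methanol, methanol_R):
        rho0 = cx.initial_state(methanol, {"Hz": -0.5, "AE": 1.0}, 0.2)
        tr = cx.propagate(rho0, methanol, 11.7, methanol_R, np.linspace(0, 20, 9))
        for st in tr.states:
            assert abs(np.trace(st.operator).real - 1.0) < 1e-10
            assert np.max(np.abs(st.operator - st.operator.conj().T)) < 1e-10

    def test_zero_relaxation_keeps_observables_constant(self, methanol):
        rho0 = cx.initial_state(methanol, {"Hz": 0.3}, 1.0)
        tr = cx.propagate(rho0, methanol, 11.7, None, [0.0, 1.0, 2.0])
        hz = tr.observables["Hz_total"]
        assert hz == pytest.approx(np.full_like(hz, hz[0]), rel=1e-9)

    def test_field_mismatch_rejected(self, methanol, methanol_R):
        rho0 = cx.initial_state(methanol, {}, 1.0)
        with pytest.raises(ValueError, match="different field"):
            cx.propagate(rho0, methanol, 9.4, methanol_R, [0.0, 1.0])


class TestDetectionTrain:
    def test_90_degree_pulse_exhausts_longitudinal_order(self, methanol):
        rho0 = cx.initial_state(methanol, {"Cz": 0.5}, 1.0)
        times, recs = cx.detection_train(rho0, methanol, 11.7, None,
                                         {"13C": 90.0}, 1.0, 2, rho_eq="unit")
        total0 = sum(recs[0][f"line{k}"] for k in range(1, 5))
        total1 = sum(recs[1][f"line{k}"] for k in range(1, 5))
        assert abs(total1) < 1e-10 * abs(total0)

    def test_small_angle_limit_depletes_nothing(self, methanol):
        rho0 = cx.initial_state(methanol, {"Cz": 0.5}, 1.0)
        _, recs = cx.detection_train(rho0, methanol, 11.7, None,
                                     {"13C": 0.01}, 1.0, 3, rho_eq="unit")
        t0 = sum(recs[0][f"line{k}"] for k in range(1, 5))
        t2 = sum(recs[2][f"line{k}"] for k in range(1, 5))
        assert t2 == pytest.approx(t0, rel=1e-7)

    def test_pulse_train_envelope_matches_geometric_oracle(self, methanol):
        """cos(theta)^(scan-1) depletion with relaxation switched off."""
        rho0 = cx.initial_state(methanol, {"Cz": 0.5}, 1.0)
        _, recs = cx.detection_train(rho0, methanol, 11.7, None,
                                     {"13C": 30.0}, 1.0, 8, rho_eq="unit")
        totals = np.array([sum(r[f"line{k}"] for k in range(1, 5)) for r in recs])
        expected = geometric_depletion(1.0, 30.0, 8)
        assert totals / totals[0] == pytest.approx(expected / expected[0], rel=1e-9)

    def test_invalid_angles_and_interval_rejected(self, methanol):
        rho0 = cx.initial_state(methanol, {}, 1.0)
        with pytest.raises(ValueError):
            cx.detection_train(rho0, methanol, 11.7, None, {"13C": 120.0}, 1.0, 1)
        with pytest.raises(ValueError):
            cx.detection_train(rho0, methanol, 11.7, None, {"13C": 30.0}, 0.0, 1)


class TestBackpropagation:
    def test_zero_pre_delay_matches_plain_propagation(self, eg, eg_R):
        out = cx.backpropagate_window(eg, {"Hz": 0.5}, 0.0, 11.7, R=eg_R,
                                      reference_polarization=0.2)
        rho_direct = cx.initial_state(eg, {"Hz": 0.5}, 0.2)
        assert np.max(np.abs(out["state_t0"].operator - rho_direct.operator)) < 1e-12

    def test_time_origin_at_detection_start(self, eg, eg_R):
        out = cx.backpropagate_window(eg, {"Hz": 1.0, "Cz": 0.01, "TS": 0.5},
                                      34.0, 11.7, R=eg_R, reference_polarization=0.1)
        assert out["pre_trajectory"].times[0] == pytest.approx(-34.0)
        assert out["pre_trajectory"].times[-1] == pytest.approx(0.0)

    def test_methylene_triplet_inverted_relative_to_cz_control(self, eg, eg_R):
        kw = dict(flip_angles={"13C": 10.0}, n_scans=1, rho_eq="unit",
                  reference_polarization=0.1)
        full = cx.backpropagate_window(eg, {"Hz": 1.0, "Cz": 0.01, "TS": 0.5},
                                       34.0, 11.7, R=eg_R, **kw)
        ctrl = cx.backpropagate_window(eg, {"Cz": 0.01}, 34.0, 11.7, R=eg_R, **kw)
        tri = np.array([full["scans"][0][f"line{k}"] for k in (1, 2, 3)])
        tri_c = np.array([ctrl["scans"][0][f"line{k}"] for k in (1, 2, 3)])
        assert np.all(tri_c > 0)
        assert np.all(tri < 0)


class TestTransferScaling:
    def test_zero_concentration_gives_unit_multipliers(self, methanol):
        prof = cx.fixture_field_profile("vienna")
        rep = cx.transfer_scaling(prof, cx.tempol_water(0.0), methanol)
        assert all(seg["rnd_multiplier"] == pytest.approx(1.0)
                   for seg in rep["segments"])

    def test_low_field_segment_relaxes_faster_than_high_field(self, methanol):
        prof = cx.FieldProfile([(1.0, 0.001), (1.0, 11.7)])
        rep = cx.transfer_scaling(prof, cx.tempol_water(0.36), methanol)
        low, high = rep["segments"]
        assert low["rnd_multiplier"] > high["rnd_multiplier"]
        assert high["rnd_multiplier"] == pytest.approx(1.0)

    def test_short_low_field_transfer_equivalent_to_longer_high_field_window(self, methanol):
        """A 5 s profile with a strong low-field gap is 'worth' much more than
        5 s at the detection field, reconciling short transfers with the long
        constant-field windows used in the simulations."""
        gap = cx.FieldProfile([(4.0, 0.57), (1.0, 0.001)])
        model = cx.tempol_water(0.36)
        rep = cx.transfer_scaling(gap, model, methanol)
        assert rep["equivalent_time_s"] > gap.duration

    def test_field_profile_mode_runs_segments(self, methanol):
        prof = cx.fixture_field_profile("custom", segments=[(1.0, 11.7)])
        out = cx.backpropagate_window(methanol, {"Hz": -0.5}, 1.0, 11.7,
                                      reference_polarization=0.2,
                                      field_profile=prof, spre_model=None)
        assert out["pre_trajectory"].times[-1] == pytest.approx(0.0)


class TestMechanismTheorems:
    def test_removing_dd_abolishes_sign_inversion(self, methanol):
        """With all DD terms excluded the 13Cz order never crosses zero on
        [-12 s, 60 s]; the full superoperator drives it positive."""
        rho0 = cx.initial_state(methanol, {"Hz": -1.0, "Cz": -0.01, "AE": 3.0}, 0.1)
        ts = np.linspace(0.0, 72.0, 73)
        r_full = cx.assemble_relaxation(methanol, 11.7)
        r_nodd = cx.assemble_relaxation(methanol, 11.7, include=("CSA", "rnd"))
        cz_full = cx.propagate(rho0, methanol, 11.7, r_full, ts, rho_eq="unit",
                               store_states=False).observables["Cz"]
        cz_nodd = cx.propagate(rho0, methanol, 11.7, r_nodd, ts, rho_eq="unit",
                               store_states=False).observables["Cz"]
        assert cz_full.max() > 0 and cz_full.min() < 0
        assert cz_nodd.max() < 0

    def test_pure_proton_polarization_drives_carbon_negative(self, methanol, methanol_R):
        rho0 = cx.initial_state(methanol, {"Hz": 1.0}, 1.0 / 3.0)
        ts = np.linspace(0.0, 60.0, 61)
        cz = cx.propagate(rho0, methanol, 11.7, methanol_R, ts, rho_eq="unit",
                          store_states=False).observables["Cz"]
        assert cz.min() < 0

    def test_proton_only_methyl_decay_is_monoexponential(self):
        from scipy.optimize import curve_fit
        s = ch3_system(tau_c=5e-12, tau_rotation=5e-13,
                       random_field=0.0663402669, carbon=False)
        R = cx.assemble_relaxation(s, 11.7)
        rho0 = cx.initial_state(s, {"Hz": 1.0}, 1.0 / 3.0)
        ts = np.arange(0.0, 61.0)
        h = cx.propagate(rho0, s, 11.7, R, ts, rho_eq="unit",
                         store_states=False).observables["Hz_total"]
        p, _ = curve_fit(lambda t, a, r: a * np.exp(-r * t), ts, h, p0=[h[0], 0.2])
        resid = h - p[0] * np.exp(-p[1] * ts)
        r2 = 1.0 - np.sum(resid**2) / np.sum((h - h.mean()) ** 2)
        assert r2 > 0.999
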