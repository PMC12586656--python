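"""Quantum-core correctness: gates, embedding, layers, readout, gradients."""

import numpy as np
import pytest
from _oracles import dense_circuit_features, dense_layer_unitary, rot
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaqnet.circuits import (
    CircuitError,
    CircuitParams,
    CircuitSpec,
    QuantumState,
    angle_embed,
    apply_cnot,
    circuit_gradient,
    entangling_layer,
    expectation_z,
    input_gradient,
    rotation_matrix,
    run_circuit,
)


class TestRotationMatrix:
    def test_zero_angle_is_identity(self):
        for axis in "XYZ":
            np.testing.assert_allclose(
                rotation_matrix(axis, 0.0), np.eye(2), atol=1e-15
            )

    def test_y_half_turn_flips_ground_state(self):
        state = rotation_matrix("Y", np.pi) @ np.array([1.0, 0.0])
        np.testing.assert_allclose(state, [0.0, 1.0], atol=1e-15)

    def test_y_matrix_closed_form(self):
        rng = np.random.default_rng(0)
        for theta in rng.uniform(-6, 6, 10):
            c, s = np.cos(theta / 2), np.sin(theta / 2)
            np.testing.assert_allclose(
                rotation_matrix("Y", theta), [[c, -s], [s, c]], atol=1e-12
            )

    @pytest.mark.parametrize("axis", ["X", "Y", "Z"])
    def test_unitarity(self, axis):
        rng = np.random.default_rng(1)
        for theta in rng.uniform(-10, 10, 5):
            u = rotation_matrix(axis, theta)
            np.testing.assert_allclose(u.conj().T @ u, np.eye(2), atol=1e-12)

    def test_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(2)
        for axis in "XYZ":
            theta = rng.uniform(-4, 4)
            np.testing.assert_allclose(
                rotation_matrix(axis, theta), rot(axis, theta), atol=1e-12
            )

    def test_unknown_axis_rejected(self):
        with pytest.raises(CircuitError):
            rotation_matrix("W", 0.3)


class TestQuantumState:
    def test_zero_state(self):
        s = QuantumState.zero(3)
        assert s.amplitudes[0] == 1.0 and np.all(s.amplitudes[1:] == 0)

    def test_unnormalized_rejected(self):
        with pytest.raises(CircuitError):
            QuantumState(1, np.array([1.0, 1.0]))

    def test_wrong_length_rejected(self):
        with pytest.raises(CircuitError):
            QuantumState(2, np.array([1.0, 0.0]))


class TestCircuitParams:
    def test_trainable_count_is_3nl(self):
        assert CircuitParams(2, 4).n_trainable == 24
        assert CircuitParams(3, 5).n_trainable == 45

    def test_nonfinite_rejected(self):
        theta = np.zeros((1, 2, 3))
        theta[0, 0, 0] = np.nan
        with pytest.raises(CircuitError):
            CircuitParams(1, 2, theta)

    def test_bad_spec_options_rejected(self):
        with pytest.raises(CircuitError):
            CircuitSpec(topology="star")
        with pytest.raises(CircuitError):
            CircuitSpec(rotation_order="zzz")


class TestAngleEmbed:
    def test_all_zero_angles_give_ground_state(self):
        amps = angle_embed(np.zeros(4))
        assert amps[0] == 1.0 and np.all(amps[1:] == 0)

    def test_single_qubit_pi_gives_excited_state(self):
        np.testing.assert_allclose(angle_embed(np.array([np.pi])), [0, 1], atol=1e-15)

    def test_z_marginal_is_cosine(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(-3, 3, 5)
        z = expectation_z(angle_embed(m), 5)
        np.testing.assert_allclose(z, np.cos(m), atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(CircuitError):
            angle_embed(np.zeros(3), n_qubits=4)


class TestCnot:
    def test_truth_table(self):
        ten = np.array([0, 0, 1, 0], dtype=complex)  # |10>
        out = apply_cnot(ten, 0, 1, 2)
        np.testing.assert_array_equal(out, [0, 0, 0, 1])  # |11>
        zero = np.array([1, 0, 0, 0], dtype=complex)
        np.testing.assert_array_equal(apply_cnot(zero, 0, 1, 2), zero)

    def test_involution(self):
        rng = np.random.default_rng(4)
        amps = rng.normal(size=8) + 1j * rng.normal(size=8)
        amps /= np.linalg.norm(amps)
        twice = apply_cnot(apply_cnot(amps, 2, 0, 3), 2, 0, 3)
        np.testing.assert_array_equal(twice, amps)

    def test_invalid_indices_rejected(self):
        amps = np.array([1, 0, 0, 0], dtype=complex)
        with pytest.raises(CircuitError):
            apply_cnot(amps, 1, 1, 2)
        with pytest.raises(CircuitError):
            apply_cnot(amps, 0, 2, 2)


class TestEntanglingLayer:
    def test_zero_angles_fix_ground_state(self):
        amps = angle_embed(np.zeros(4))
        out = entangling_layer(amps, np.zeros((4, 3)), 4, "ring")
        np.testing.assert_allclose(out, amps, atol=1e-15)

    @pytest.mark.parametrize("topology", ["ring", "ladder"])
    @pytest.mark.parametrize("order", ["zyz", "xyz"])
    def test_matches_dense_unitary_oracle(self, topology, order):
        rng = np.random.default_rng(5)
        n = 3
        theta_l = rng.uniform(0, 2 * np.pi, size=(n, 3))
        amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
        amps /= np.linalg.norm(amps)
        got = entangling_layer(amps, theta_l, n, topology, order)
        want = dense_layer_unitary(theta_l, n, topology, order) @ amps
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CircuitError):
            entangling_layer(angle_embed(np.zeros(4)), np.zeros((3, 3)), 4)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_norm_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
        amps /= np.linalg.norm(amps)
        out = entangling_layer(
            amps, rng.uniform(0, 2 * np.pi, size=(n, 3)), n,
            topology=rng.choice(["ring", "ladder"]),
        )
        assert abs(np.sum(np.abs(out) ** 2) - 1.0) < 1e-9


class TestRunCircuit:
    def test_trivial_circuit_gives_unit_expectations(self):
        q = run_circuit(np.zeros(4), CircuitParams(2, 4))
        np.testing.assert_allclose(q, np.ones(4), atol=1e-15)

    def test_single_qubit_matrix_chain_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            m = rng.uniform(-3, 3, 1)
            theta = rng.uniform(0, 2 * np.pi, size=(1, 1, 3))
            # independent 2x2 matrix-chain evaluation (zyz order)
            state = rot("Y", m[0]) @ np.array([1.0, 0.0])
            for axis, ang in zip("ZYZ", theta[0, 0]):
                state = rot(axis, ang) @ state
            want = abs(state[0]) ** 2 - abs(state[1]) ** 2
            got = run_circuit(m, CircuitParams(1, 1, theta))
            np.testing.assert_allclose(got, [want], atol=1e-12)

    def test_dense_oracle_n4_l2(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(-np.pi, np.pi, 4)
        theta = rng.uniform(0, 2 * np.pi, size=(2, 4, 3))
        got = run_circuit(m, CircuitParams(2, 4, theta))
        np.testing.assert_allclose(got, dense_circuit_features(m, theta), atol=1e-9)

    def test_outputs_bounded(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(-4, 4, size=(20, 4))
        q = run_circuit(m, CircuitParams.random(2, 4, rng))
        assert np.all(q <= 1 + 1e-9) and np.all(q >= -1 - 1e-9)

    def test_batch_matches_per_sample(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(-2, 2, size=(6, 4))
        cp = CircuitParams.random(2, 4, rng)
        batched = run_circuit(m, cp)
        singles = np.stack([run_circuit(row, cp) for row in m])
        np.testing.assert_array_equal(batched, singles)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(CircuitError):
            run_circuit(np.zeros(3), CircuitParams(1, 4))


class TestGradients:
    def test_single_ry_gradient_closed_form(self):
        # one qubit, zyz triple (0, theta, 0): q = cos(theta), dq/dtheta = -sin
        rng = np.random.default_rng(10)
        for theta_y in rng.uniform(-3, 3, 5):
            theta = np.zeros((1, 1, 3))
            theta[0, 0, 1] = theta_y
            g = circuit_gradient(np.zeros(1), CircuitParams(1, 1, theta))
            np.testing.assert_allclose(g[0, 0, 0, 1], -np.sin(theta_y), atol=1e-12)

    def test_phase_gate_on_ground_state_has_zero_gradient(self):
        g = circuit_gradient(np.zeros(4), CircuitParams(2, 4))
        # first R_z angle of each qubit acts on |0>: pure phase, no effect
        np.testing.assert_allclose(g[:, 0, :, 0], 0.0, atol=1e-12)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(-1, 1, 4)
        cp = CircuitParams.random(2, 4, rng)
        g = circuit_gradient(m, cp)
        h = 1e-5
        for layer in range(2):
            for i in range(4):
                for k in range(3):
                    tp = cp.theta.copy()
                    tp[layer, i, k] += h
                    tm = cp.theta.copy()
                    tm[layer, i, k] -= h
                    fd = (
                        run_circuit(m, CircuitParams(2, 4, tp))
                        - run_circuit(m, CircuitParams(2, 4, tm))
                    ) / (2 * h)
                    np.testing.assert_allclose(g[:, layer, i, k], fd, atol=1e-6)

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(-1, 1, 4)
        cp = CircuitParams.random(2, 4, rng)
        g = input_gradient(m, cp)
        h = 1e-5
        for i in range(4):
            mp, mm = m.copy(), m.copy()
            mp[i] += h
            mm[i] -= h
            fd = (run_circuit(mp, cp) - run_circuit(mm, cp)) / (2 * h)
            np.testing.assert_allclose(g[:, i], fd, atol=1e-6)
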