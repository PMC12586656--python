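"""Independent brute-force oracles used by the test suite.

These build the circuit as one dense 2^n x 2^n unitary by explicit
Kronecker products and matrix multiplication — a deliberately different
route from the layered sparse simulator under test. Qubit 0 is the most
significant bit of the amplitude index, matching the package convention.
"""

import numpy as np


def pauli(axis: str) -> np.ndarray:
    return {
        "X": np.array([[0, 1], [1, 0]], dtype=complex),
        "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
        "Z": np.array([[1, 0], [0, -1]], dtype=complex),
    }[axis]


def rot(axis: str, angle: float) -> np.ndarray:
    """exp(-i angle/2 P) via eigendecomposition (independent of the package)."""
    from scipy.linalg import expm

    return expm(-0.5j * angle * pauli(axis))


def embed_gate(gate: np.ndarray, qubit: int, n: int) -> np.ndarray:
    u = np.eye(2**qubit, dtype=complex)
    u = np.kron(u, gate)
    return np.kron(u, np.eye(2 ** (n - qubit - 1), dtype=complex))


def cnot_matrix(control: int, target: int, n: int) -> np.ndarray:
    dim = 2**n
    m = np.zeros((dim, dim))
    for j in range(dim):
        bits = [(j >> (n - 1 - k)) & 1 for k in range(n)]
        if bits[control]:
            bits[target] ^= 1
        i = sum(b << (n - 1 - k) for k, b in enumerate(bits))
        m[i, j] = 1.0
    return m


def entangler_pairs(n: int, topology: str):
    if topology == "ring":
        return [] if n == 1 else [(i, (i + 1) % n) for i in range(n)]
    return [(i, i + 1) for i in range(n - 1)]


def rotation_axes(order: str):
    return ("Z", "Y", "Z") if order == "zyz" else ("X", "Y", "Z")


def dense_layer_unitary(
    theta_l: np.ndarray, n: int, topology: str = "ring", order: str = "zyz"
) -> np.ndarray:
    u = np.eye(2**n, dtype=complex)
    for i in range(n):
        for k, axis in enumerate(rotation_axes(order)):
            u = embed_gate(rot(axis, theta_l[i, k]), i, n) @ u
    for c, t in entangler_pairs(n, topology):
        u = cnot_matrix(c, t, n) @ u
    return u


def dense_circuit_features(
    m: np.ndarray, theta: np.ndarray, topology: str = "ring", order: str = "zyz"
) -> np.ndarray:
    """q via the full dense unitary acting on the dense embedded state."""
    n = m.size
    state = np.zeros(2**n, dtype=complex)
    state[0] = 1.0
    u_embed = np.eye(2**n, dtype=complex)
    for i in range(n):
        u_embed = embed_gate(rot("Y", m[i]), i, n) @ u_embed
    state = u_embed @ state
    for layer in range(theta.shape[0]):
        state = dense_layer_unitary(theta[layer], n, topology, order) @ state
    q = np.empty(n)
    for j in range(n):
        zj = embed_gate(pauli("Z"), j, n)
        q[j] = np.real(state.conj() @ zj @ state)
    return q


def pairwise_auc(y_binary: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs correctly ordered,
    counting ties as one half."""
    pos = scores[y_binary == 1]
    neg = scores[y_binary == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
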