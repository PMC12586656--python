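"""Exact state-vector simulation of the few-qubit variational feature circuit.

The circuit is the quantum half of the hybrid classifier: a classical
feature vector ``m`` (radians, one angle per qubit) is angle-embedded with
``R_y`` rotations, transformed by ``L`` strongly entangling layers (a
trainable rotation triple per qubit followed by a CNOT entangler over a
fixed topology), and read out as the vector of Pauli-Z expectation values
``q_j = <psi|Z_j|psi>`` in ``[-1, 1]``.

Conventions
-----------
* Qubit 0 is the **most significant bit** of the amplitude index, i.e. for
  two qubits the basis order is ``|00>, |01>, |10>, |11>`` with the first
  bit belonging to qubit 0.
* Rotation triples are applied lowest θ-index first: with the default
  ``zyz`` order the state is hit by ``R_z(θ[0])``, then ``R_y(θ[1])``,
  then ``R_z(θ[2])``.
* All amplitudes are complex128; expectations are exact (no shot noise),
  and gradients use the parameter-shift rule, which is exact for gates
  generated by half Pauli operators.

Every public function accepts either a single amplitude vector of length
``2**n`` or a batch of shape ``(B, 2**n)``; batching is a convenience for
the training loop and never changes per-sample results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantumState",
    "CircuitParams",
    "CircuitSpec",
    "rotation_matrix",
    "angle_embed",
    "apply_cnot",
    "apply_single_qubit_gate",
    "entangling_layer",
    "run_circuit",
    "expectation_z",
    "circuit_gradient",
    "input_gradient",
]

_PAULI = {
    "X": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    "Y": np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
    "Z": np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex),
}

NORM_ATOL = 1e-9  # normalization tolerance for state validation


class CircuitError(ValueError):
    """Raised for malformed circuit inputs (bad axis, shape, index...)."""


@dataclass
class QuantumState:
    """Pure state of ``n_qubits`` qubits as a complex amplitude vector.

    Invariants: ``len(amplitudes) == 2**n_qubits`` and unit norm within
    ``1e-9`` (|alpha|^2 + |beta|^2 = 1 per qubit generalises to the joint
    state).
    """

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.n_qubits < 1:
            raise CircuitError("n_qubits must be >= 1")
        if self.amplitudes.shape != (2**self.n_qubits,):
            raise CircuitError(
                f"amplitude vector has shape {self.amplitudes.shape}, "
                f"expected ({2 ** self.n_qubits},)"
            )
        norm = float(np.sum(np.abs(self.amplitudes) ** 2))
        if abs(norm - 1.0) > NORM_ATOL:
            raise CircuitError(f"state norm^2 = {norm!r} is not 1 within {NORM_ATOL}")

    @classmethod
    def zero(cls, n_qubits: int) -> "QuantumState":
        amps = np.zeros(2**n_qubits, dtype=complex)
        amps[0] = 1.0
        return cls(n_qubits, amps)

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


@dataclass
class CircuitParams:
    """Trainable rotation angles, shape ``[L][n][3]`` (radians).

    The trainable count is ``3 * n * L`` (e.g. 24 for n=4, L=2).
    """

    n_layers: int
    n_qubits: int
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_qubits < 1:
            raise CircuitError("n_layers and n_qubits must be >= 1")
        if self.theta is None:
            self.theta = np.zeros((self.n_layers, self.n_qubits, 3))
        self.theta = np.asarray(self.theta, dtype=float)
        expected = (self.n_layers, self.n_qubits, 3)
        if self.theta.shape != expected:
            raise CircuitError(
                f"theta has shape {self.theta.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(self.theta)):
            raise CircuitError("theta contains non-finite entries")

    @property
    def n_trainable(self) -> int:
        return 3 * self.n_qubits * self.n_layers

    @classmethod
    def random(
        cls, n_layers: int, n_qubits: int, rng: np.random.Generator
    ) -> "CircuitParams":
        """Angles drawn uniformly in (0, 2π); the conventional circuit init."""
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_layers, n_qubits, 3))
        return cls(n_layers, n_qubits, theta)


@dataclass
class CircuitSpec:
    """Serializable circuit description (config-block contract)."""

    n_qubits: int = 4
    n_layers: int = 2
    topology: str = "ring"
    rotation_order: str = "zyz"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("ring", "ladder"):
            raise CircuitError(f"unknown topology {self.topology!r}")
        if self.rotation_order not in ("zyz", "xyz"):
            raise CircuitError(f"unknown rotation_order {self.rotation_order!r}")

    def to_dict(self) -> dict:
        return {
            "n_qubits": self.n_qubits,
            "n_layers": self.n_layers,
            "topology": self.topology,
            "rotation_order": self.rotation_order,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        return cls(**d)


def rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """2x2 unitary ``exp(-i * angle/2 * P_axis)`` for Pauli axis X, Y or Z."""
    if axis not in _PAULI:
        raise CircuitError(f"unknown rotation axis {axis!r}; expected one of X, Y, Z")
    angle = float(angle)
    if not np.isfinite(angle):
        raise CircuitError("rotation angle must be finite")
    c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
    if axis == "X":
        return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)
    if axis == "Y":
        return np.array([[c, -s], [s, c]], dtype=complex)
    return np.array([[c - 1j * s, 0.0], [0.0, c + 1j * s]], dtype=complex)


def _as_batch(amps: np.ndarray) -> tuple[np.ndarray, bool]:
    amps = np.asarray(amps, dtype=complex)
    if amps.ndim == 1:
        return amps[None, :], True
    return amps, False


def apply_single_qubit_gate(
    amps: np.ndarray, gate: np.ndarray, qubit: int, n_qubits: int
) -> np.ndarray:
    """Apply a 2x2 gate to one qubit of a (batched) amplitude vector."""
    batch, squeeze = _as_batch(amps)
    if not (0 <= qubit < n_qubits):
        raise CircuitError(f"qubit index {qubit} out of range for n={n_qubits}")
    b = batch.shape[0]
    left = 2**qubit
    right = 2 ** (n_qubits - qubit - 1)
    v = batch.reshape(b, left, 2, right)
    out = np.einsum("pq,blqr->blpr", gate, v).reshape(b, 2**n_qubits)
    return out[0] if squeeze else out


def apply_cnot(
    amps: np.ndarray, control: int, target: int, n_qubits: int
) -> np.ndarray:
    """CNOT: flip the target bit on amplitudes whose control bit is 1."""
    if control == target:
        raise CircuitError("CNOT control and target must differ")
    for idx in (control, target):
        if not (0 <= idx < n_qubits):
            raise CircuitError(f"qubit index {idx} out of range for n={n_qubits}")
    batch, squeeze = _as_batch(amps)
    b = batch.shape[0]
    v = batch.reshape((b,) + (2,) * n_qubits).copy()
    sel = [slice(None)] * (n_qubits + 1)
    sel[1 + control] = slice(1, 2)
    sel = tuple(sel)
    v[sel] = np.flip(v[sel], axis=1 + target)
    out = v.reshape(b, 2**n_qubits)
    return out[0] if squeeze else out


def angle_embed(m: np.ndarray, n_qubits: int | None = None) -> np.ndarray:
    """Product state ``⊗_i R_y(m_i)|0>`` as a (batched) amplitude vector.

    Each classical feature becomes the Y-rotation angle of its own qubit, so
    the single-qubit marginal satisfies ``<Z_i> = cos(m_i)`` exactly.
    """
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 1
    mb = m[None, :] if squeeze else m
    n = mb.shape[1]
    if n_qubits is not None and n != n_qubits:
        raise CircuitError(
            f"embedding vector length {n} does not match circuit width {n_qubits}"
        )
    if not np.all(np.isfinite(mb)):
        raise CircuitError("embedding angles must be finite")
    # R_y(m)|0> = (cos(m/2), sin(m/2)); take successive Kronecker products.
    amps = np.ones((mb.shape[0], 1), dtype=complex)
    for i in range(n):
        qubit = np.stack([np.cos(mb[:, i] / 2), np.sin(mb[:, i] / 2)], axis=1)
        amps = (amps[:, :, None] * qubit[:, None, :]).reshape(mb.shape[0], -1)
    return amps[0] if squeeze else amps


def _entangler_pairs(n_qubits: int, topology: str) -> list[tuple[int, int]]:
    if topology == "ring":
        if n_qubits == 1:
            return []
        return [(i, (i + 1) % n_qubits) for i in range(n_qubits)]
    if topology == "ladder":
        return [(i, i + 1) for i in range(n_qubits - 1)]
    raise CircuitError(f"unknown topology {topology!r}")


def _rotation_axes(order: str) -> tuple[str, str, str]:
    if order == "zyz":
        return ("Z", "Y", "Z")
    if order == "xyz":
        return ("X", "Y", "Z")
    raise CircuitError(f"unknown rotation_order {order!r}")


def entangling_layer(
    amps: np.ndarray,
    theta_l: np.ndarray,
    n_qubits: int,
    topology: str = "ring",
    rotation_order: str = "zyz",
) -> np.ndarray:
    """One strongly entangling layer: rotation triples, then the entangler."""
    theta_l = np.asarray(theta_l, dtype=float)
    if theta_l.shape != (n_qubits, 3):
        raise CircuitError(
            f"layer parameters have shape {theta_l.shape}, expected ({n_qubits}, 3)"
        )
    axes = _rotation_axes(rotation_order)
    out = amps
    for i in range(n_qubits):
        for k, axis in enumerate(axes):
            out = apply_single_qubit_gate(
                out, rotation_matrix(axis, theta_l[i, k]), i, n_qubits
            )
    for control, target in _entangler_pairs(n_qubits, topology):
        out = apply_cnot(out, control, target, n_qubits)
    return out


def expectation_z(amps: np.ndarray, n_qubits: int) -> np.ndarray:
    """Per-qubit Pauli-Z expectations, shape ``(n,)`` or ``(B, n)``."""
    batch, squeeze = _as_batch(amps)
    probs = np.abs(batch) ** 2
    b = batch.shape[0]
    v = probs.reshape((b,) + (2,) * n_qubits)
    out = np.empty((b, n_qubits))
    for j in range(n_qubits):
        marg = v.sum(axis=tuple(k for k in range(1, n_qubits + 1) if k != j + 1))
        out[:, j] = marg[:, 0] - marg[:, 1]
    return out[0] if squeeze else out


def _final_state(
    m: np.ndarray,
    params: CircuitParams,
    topology: str,
    rotation_order: str,
) -> np.ndarray:
    amps = angle_embed(m, params.n_qubits)
    for layer in range(params.n_layers):
        amps = entangling_layer(
            amps, params.theta[layer], params.n_qubits, topology, rotation_order
        )
    return amps


def run_circuit(
    m: np.ndarray,
    params: CircuitParams,
    topology: str = "ring",
    rotation_order: str = "zyz",
) -> np.ndarray:
    """Quantum feature vector ``q_j = <Z_j>`` of the full circuit.

    ``m`` may be a single length-``n`` angle vector or a ``(B, n)`` batch;
    the result has the matching shape and every entry lies in ``[-1, 1]``.
    """
    m = np.asarray(m, dtype=float)
    width = m.shape[-1]
    if width != params.n_qubits:
        raise CircuitError(
            f"input has {width} features but the circuit has {params.n_qubits} qubits"
        )
    amps = _final_state(m, params, topology, rotation_order)
    return expectation_z(amps, params.n_qubits)


def circuit_gradient(
    m: np.ndarray,
    params: CircuitParams,
    topology: str = "ring",
    rotation_order: str = "zyz",
) -> np.ndarray:
    """Parameter-shift gradient ``∂q_j/∂θ``, shape ``([B,] n, L, n, 3)``.

    Each angle parametrises a gate ``exp(-i θ/2 P)``, so the exact gradient
    is ``[q(θ+π/2) - q(θ-π/2)] / 2``.
    """
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 1
    mb = m[None, :] if squeeze else m
    b = mb.shape[0]
    n, L = params.n_qubits, params.n_layers
    grad = np.empty((b, n, L, n, 3))
    for layer in range(L):
        for i in range(n):
            for k in range(3):
                for sign, half in ((1.0, 0), (-1.0, 1)):
                    shifted = params.theta.copy()
                    shifted[layer, i, k] += sign * np.pi / 2
                    q = run_circuit(
                        mb,
                        CircuitParams(L, n, shifted),
                        topology,
                        rotation_order,
                    )
                    if half == 0:
                        grad[:, :, layer, i, k] = q / 2.0
                    else:
                        grad[:, :, layer, i, k] -= q / 2.0
    return grad[0] if squeeze else grad


def input_gradient(
    m: np.ndarray,
    params: CircuitParams,
    topology: str = "ring",
    rotation_order: str = "zyz",
) -> np.ndarray:
    """Parameter-shift gradient ``∂q_j/∂m_i``, shape ``([B,] n, n)``.

    The embedding gates are ``R_y(m_i)``, which share the half-Pauli
    generator structure, so the same ±π/2 shift rule is exact.
    """
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 1
    mb = m[None, :] if squeeze else m
    b, n = mb.shape
    grad = np.empty((b, n, n))
    for i in range(n):
        plus = mb.copy()
        plus[:, i] += np.pi / 2
        minus = mb.copy()
        minus[:, i] -= np.pi / 2
        q_plus = run_circuit(plus, params, topology, rotation_order)
        q_minus = run_circuit(minus, params, topology, rotation_order)
        grad[:, :, i] = (q_plus - q_minus) / 2.0
    return grad[0] if squeeze else grad
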