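"""Per-layer parameter counting and the FLOPs heuristic.

The hybrid architecture is deliberately tiny on the trainable side: a frozen
backbone feeds a global-average-pooled d-vector into a dense projection to
n_qubits features, the variational circuit contributes ``3 * n * L`` angles,
and a small dense/batch-norm head maps the fused 2*n_qubits vector to the
class logits. The ledger reproduces that walkthrough layer by layer so the
counts can be cross-checked against an instantiated model tensor-for-tensor.

Counting conventions: batch-norm contributes two trainable parameters per
feature (scale and shift); its running mean/variance are non-trainable state
and are excluded from both columns. FLOPs use the coarse estimate
``2 x trainable parameters`` (one multiply and one add per weight), which is
the convention the rest of the toolkit's comparisons assume; an exact
MAC count for convolutional backbones is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .model import ModelSpec

__all__ = [
    "LayerDescriptor",
    "ParamLedger",
    "conv_params",
    "dense_params",
    "bn_params",
    "quantum_params",
    "flops_estimate",
    "build_ledger",
]


class AccountingError(ValueError):
    pass


def conv_params(k_h: int, k_w: int, c_in: int, c_out: int) -> int:
    """Trainable parameters of a 2-D convolution: K_H*K_W*C_in*C_out + C_out."""
    for v in (k_h, k_w, c_in, c_out):
        if int(v) != v or v <= 0:
            raise AccountingError("conv dimensions must be positive integers")
    return int(k_h) * int(k_w) * int(c_in) * int(c_out) + int(c_out)


def dense_params(n_i: int, n_o: int) -> int:
    """Trainable parameters of a dense layer: n_i*n_o weights + n_o biases."""
    for v in (n_i, n_o):
        if int(v) != v or v <= 0:
            raise AccountingError("dense dimensions must be positive integers")
    return int(n_i) * int(n_o) + int(n_o)


def bn_params(n_features: int) -> int:
    """Trainable batch-norm parameters: scale + shift per feature (2F)."""
    if int(n_features) != n_features or n_features < 0:
        raise AccountingError("feature count must be a nonnegative integer")
    return 2 * int(n_features)


def quantum_params(n_qubits: int, n_layers: int) -> int:
    """Variational circuit angles: 3 per qubit per entangling layer."""
    for v in (n_qubits, n_layers):
        if int(v) != v or v <= 0:
            raise AccountingError("qubit and layer counts must be positive integers")
    return 3 * int(n_qubits) * int(n_layers)


def flops_estimate(trainable: int) -> int:
    """Coarse FLOPs heuristic: 2 x trainable parameter count."""
    if int(trainable) != trainable or trainable < 0:
        raise AccountingError("trainable count must be a nonnegative integer")
    return 2 * int(trainable)


@dataclass
class LayerDescriptor:
    name: str
    kind: str  # conv | dense | batchnorm | quantum | pooling | dropout | concat | backbone
    trainable: int
    non_trainable: int = 0

    def __post_init__(self) -> None:
        if self.trainable < 0 or self.non_trainable < 0:
            raise AccountingError("parameter counts must be nonnegative")


@dataclass
class ParamLedger:
    """Ordered per-layer parameter accounting with column totals."""

    entries: list[LayerDescriptor] = field(default_factory=list)

    @property
    def trainable_total(self) -> int:
        return sum(e.trainable for e in self.entries)

    @property
    def non_trainable_total(self) -> int:
        return sum(e.non_trainable for e in self.entries)

    @property
    def grand_total(self) -> int:
        return self.trainable_total + self.non_trainable_total

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "layer": e.name,
                    "kind": e.kind,
                    "trainable": e.trainable,
                    "non_trainable": e.non_trainable,
                }
                for e in self.entries
            ]
        )
        total = pd.DataFrame(
            [
                {
                    "layer": "TOTAL",
                    "kind": "",
                    "trainable": self.trainable_total,
                    "non_trainable": self.non_trainable_total,
                }
            ]
        )
        return pd.concat([df, total], ignore_index=True)


def build_ledger(spec: "ModelSpec") -> ParamLedger:
    """Walk the architecture in order and account for every layer.

    Layout: backbone (frozen) -> GAP -> dense d->n_qubits projection ->
    quantum circuit -> concat -> dense->BN->dropout blocks -> output dense.
    """
    required = ("feature_dim", "n_qubits", "n_layers", "head_widths", "n_classes")
    for attr in required:
        if getattr(spec, attr, None) in (None, 0, ()):
            raise AccountingError(f"model spec is missing {attr!r}")

    ledger = ParamLedger()
    ledger.entries.append(
        LayerDescriptor(
            f"backbone[{spec.backbone_id}]",
            "backbone",
            0,
            int(spec.backbone_nontrainable),
        )
    )
    ledger.entries.append(LayerDescriptor("global_average_pooling", "pooling", 0))
    ledger.entries.append(
        LayerDescriptor(
            f"projection_dense_{spec.feature_dim}x{spec.n_qubits}",
            "dense",
            dense_params(spec.feature_dim, spec.n_qubits),
        )
    )
    ledger.entries.append(
        LayerDescriptor(
            f"quantum_circuit_{spec.n_qubits}q_{spec.n_layers}L",
            "quantum",
            quantum_params(spec.n_qubits, spec.n_layers),
        )
    )
    ledger.entries.append(LayerDescriptor("fusion_concat", "concat", 0))

    width = 2 * spec.n_qubits  # fused [c; q] vector
    for hidden in spec.head_widths:
        ledger.entries.append(
            LayerDescriptor(
                f"head_dense_{width}x{hidden}", "dense", dense_params(width, hidden)
            )
        )
        ledger.entries.append(
            LayerDescriptor(f"head_batchnorm_{hidden}", "batchnorm", bn_params(hidden))
        )
        ledger.entries.append(LayerDescriptor(f"head_dropout_{hidden}", "dropout", 0))
        width = hidden
    ledger.entries.append(
        LayerDescriptor(
            f"output_dense_{width}x{spec.n_classes}",
            "dense",
            dense_params(width, spec.n_classes),
        )
    )
    return ledger
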