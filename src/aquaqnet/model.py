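"""The hybrid quantum-classical classifier and its training loop.

Architecture: frozen backbone features -> global average pooling (inside
the backbone adapter) -> dense projection ``c = tanh(Wz + b)`` to one angle
per qubit -> variational quantum circuit producing Pauli-Z features ``q``
-> fusion ``u = [c; q]`` -> a small dense / batch-norm / dropout head ->
softmax over classes. Only the projection, the circuit angles Θ and the
head are trainable; the backbone never updates.

Training minimises categorical cross-entropy with Adam (pluggable optimizer
contract), global-norm gradient clipping, reduce-on-plateau learning-rate
decay and early stopping on validation loss with best-weight restoration.
Classical gradients are exact backpropagation; the circuit's gradients
(w.r.t. Θ and w.r.t. its angle inputs) use the parameter-shift rule, so
the whole end-to-end gradient is exact up to floating point.

Usage follows the model/results idiom::

    model = HybridQuantumClassifier(z_train, y_train, z_val, y_val, spec=spec)
    res = model.fit(TrainConfig(seed=0, max_epochs=20))
    print(res.summary())
    report = res.evaluate(z_test, y_test)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import circuits
from .accounting import build_ledger
from .metrics import MetricsReport, classification_report, confusion_matrix, roc_auc_ovr

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainingTrace",
    "HybridQuantumClassifier",
    "HybridFitResults",
    "Adam",
    "extract_features",
    "project",
    "fuse",
    "classify",
    "TrainingError",
]

CHECKPOINT_SCHEMA = 1


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Architecture description; defaults match the reference configuration."""

    backbone_id: str = "resnet50"
    feature_dim: int = 2048
    backbone_nontrainable: int = 23_588_096
    n_qubits: int = 4
    n_layers: int = 2
    head_widths: tuple[int, ...] = (128, 64)
    n_classes: int = 5
    dropout_rate: float = 0.5
    bn_momentum: float = 0.99
    bn_epsilon: float = 1e-3
    input_size: tuple[int, int, int] = (224, 224, 3)
    topology: str = "ring"
    rotation_order: str = "zyz"
    head_activation: str = "relu"
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if self.head_activation not in ("relu", "linear"):
            raise ValueError(f"unknown head activation {self.head_activation!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def fused_width(self) -> int:
        """Width of u = [c; q]: projection width + n_qubits (8 by default)."""
        return 2 * self.n_qubits

    @classmethod
    def toy(cls, backbone, n_classes: int = 5, **kw) -> "ModelSpec":
        """Spec wired to a functional (toy) backbone adapter."""
        return cls(
            backbone_id=backbone.backbone_id,
            feature_dim=backbone.feature_dim,
            backbone_nontrainable=backbone.non_trainable,
            n_classes=n_classes,
            input_size=tuple(backbone.input_size),
            **kw,
        )


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    batch_size: int = 32
    max_epochs: int = 10
    early_stop_patience: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    grad_clip_norm: float | None = 1.0
    seed: int = 0
    record_quantum_diagnostics: bool = False
    probe_every: int = 10  # iterations between <Z> probe evaluations

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch training record plus optional quantum diagnostics."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    costs: list[float] = field(default_factory=list)  # per-iteration batch loss
    probe_z: list[list[float]] = field(default_factory=list)  # <Z> on probe input
    theta_path: list[list[float]] = field(default_factory=list)  # flattened Θ

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingTrace":
        df = pd.read_csv(path)
        trace = cls()
        trace.epoch = [int(e) for e in df["epoch"]]
        trace.train_loss = [float(v) for v in df["train_loss"]]
        trace.train_acc = [float(v) for v in df["train_acc"]]
        trace.val_loss = [float(v) for v in df["val_loss"]]
        trace.val_acc = [float(v) for v in df["val_acc"]]
        trace.stopped_epoch = trace.epoch[-1] if trace.epoch else 0
        trace.best_epoch = (
            int(df.loc[df["val_loss"].idxmin(), "epoch"]) if len(df) else 0
        )
        return trace


# ---------------------------------------------------------------------------
# functional pieces (spec-level operations)


def extract_features(images: np.ndarray, backbone) -> np.ndarray:
    """Pooled feature vectors from a frozen backbone adapter."""
    if not getattr(backbone, "functional", False):
        raise TrainingError(
            f"backbone {backbone.backbone_id!r} is a metadata profile and "
            "cannot extract features; use a functional adapter"
        )
    return backbone.extract_features(images)


def project(z: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Classical projection ``c = tanh(Wz + b)``; entries strictly in (-1, 1)."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    b = np.asarray(b, dtype=float)
    if z.shape[-1] != w.shape[1] or w.shape[0] != b.shape[0]:
        raise ValueError(
            f"shape mismatch: z{z.shape}, W{w.shape}, b{b.shape}"
        )
    return np.tanh(z @ w.T + b)


def fuse(c: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Concatenate classical and quantum features: ``u = [c; q]``."""
    c = np.asarray(c, dtype=float)
    q = np.asarray(q, dtype=float)
    if c.shape != q.shape:
        raise ValueError(f"fusion inputs differ in shape: {c.shape} vs {q.shape}")
    return np.concatenate([c, q], axis=-1)


def split_fused(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`fuse`."""
    half = u.shape[-1] // 2
    return u[..., :half], u[..., half:]


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_out, n_in))


def init_params(spec: ModelSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform dense weights, unit/zero batch-norm, Θ ~ U(0, 2π)."""
    p: dict[str, np.ndarray] = {
        "proj_W": _glorot(rng, spec.n_qubits, spec.feature_dim),
        "proj_b": np.zeros(spec.n_qubits),
        "theta": rng.uniform(0, 2 * np.pi, size=(spec.n_layers, spec.n_qubits, 3)),
    }
    width = spec.fused_width
    for i, hidden in enumerate(spec.head_widths):
        p[f"h{i}_W"] = _glorot(rng, hidden, width)
        p[f"h{i}_b"] = np.zeros(hidden)
        p[f"h{i}_gamma"] = np.ones(hidden)
        p[f"h{i}_beta"] = np.zeros(hidden)
        width = hidden
    p["out_W"] = _glorot(rng, spec.n_classes, width)
    p["out_b"] = np.zeros(spec.n_classes)
    return p


def init_state(spec: ModelSpec) -> dict[str, np.ndarray]:
    """Batch-norm running statistics (non-trainable state)."""
    s: dict[str, np.ndarray] = {}
    for i, hidden in enumerate(spec.head_widths):
        s[f"h{i}_mean"] = np.zeros(hidden)
        s[f"h{i}_var"] = np.ones(hidden)
    return s


def _head_forward(
    u: np.ndarray,
    params: dict,
    state: dict,
    spec: ModelSpec,
    mode: str,
    dropout_rng: np.random.Generator | None = None,
    update_state: bool = False,
    cache: dict | None = None,
) -> np.ndarray:
    """Dense->BN->(act)->dropout blocks then the softmax output layer."""
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    h = u
    for i in range(len(spec.head_widths)):
        a = h @ params[f"h{i}_W"].T + params[f"h{i}_b"]
        if mode == "train":
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            if update_state:
                mom = spec.bn_momentum
                state[f"h{i}_mean"] = mom * state[f"h{i}_mean"] + (1 - mom) * mu
                state[f"h{i}_var"] = mom * state[f"h{i}_var"] + (1 - mom) * var
        else:
            mu = state[f"h{i}_mean"]
            var = state[f"h{i}_var"]
        inv_std = 1.0 / np.sqrt(var + spec.bn_epsilon)
        xhat = (a - mu) * inv_std
        y = params[f"h{i}_gamma"] * xhat + params[f"h{i}_beta"]
        if spec.head_activation == "relu":
            act = np.maximum(y, 0.0)
        else:
            act = y
        if mode == "train" and spec.dropout_rate > 0.0:
            if dropout_rng is None:
                raise TrainingError("dropout in train mode requires an RNG")
            keep = 1.0 - spec.dropout_rate
            mask = (dropout_rng.random(act.shape) < keep) / keep  # inverted dropout
            dropped = act * mask
        else:
            mask = None
            dropped = act
        if cache is not None:
            cache[f"h{i}"] = {
                "input": h, "a": a, "mu": mu, "var": var, "inv_std": inv_std,
                "xhat": xhat, "y": y, "act": act, "mask": mask,
            }
        h = dropped
    logits = h @ params["out_W"].T + params["out_b"]
    if cache is not None:
        cache["out_input"] = h
        cache["logits"] = logits
    return _softmax(logits)


def classify(
    u: np.ndarray,
    params: dict,
    spec: ModelSpec,
    mode: str = "infer",
    state: dict | None = None,
    dropout_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probability vector(s) from fused features ``u``."""
    u = np.asarray(u, dtype=float)
    squeeze = u.ndim == 1
    ub = u[None, :] if squeeze else u
    if state is None:
        state = init_state(spec)
    probs = _head_forward(ub, params, state, spec, mode, dropout_rng)
    return probs[0] if squeeze else probs


# ---------------------------------------------------------------------------
# optimizer contract


class Adam:
    """Adam with bias correction; satisfies the ``step(params, grads)`` contract."""

    def __init__(
        self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for key, p in params.items():
            g = grads[key]
            m = self.m.get(key, np.zeros_like(p))
            v = self.v.get(key, np.zeros_like(p))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g**2
            self.m[key] = m
            self.v[key] = v
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            out[key] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


_OPTIMIZERS: dict[str, Callable[..., object]] = {"adam": Adam}


def register_optimizer(name: str, factory: Callable[..., object]) -> None:
    """Register a third-party optimizer implementing ``step(params, grads)``."""
    _OPTIMIZERS[name] = factory


# ---------------------------------------------------------------------------
# forward/backward through the full trainable stack


def _forward(
    z: np.ndarray,
    params: dict,
    state: dict,
    spec: ModelSpec,
    mode: str,
    dropout_rng=None,
    update_state: bool = False,
    cache: dict | None = None,
) -> np.ndarray:
    c = project(z, params["proj_W"], params["proj_b"])
    cp = circuits.CircuitParams(spec.n_layers, spec.n_qubits, params["theta"])
    q = circuits.run_circuit(c, cp, spec.topology, spec.rotation_order)
    u = fuse(c, q)
    if cache is not None:
        cache["z"], cache["c"], cache["q"], cache["u"] = z, c, q, u
    return _head_forward(
        u, params, state, spec, mode, dropout_rng, update_state, cache
    )


def _loss_and_grads(
    z: np.ndarray,
    y: np.ndarray,
    params: dict,
    state: dict,
    spec: ModelSpec,
    dropout_rng,
    update_state: bool = True,
) -> tuple[float, float, dict]:
    """Mean cross-entropy, batch accuracy and gradients for one batch."""
    cache: dict = {}
    probs = _forward(
        z, params, state, spec, "train", dropout_rng, update_state, cache
    )
    b = z.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(b), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))

    grads = {}
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits /= b
    grads["out_W"] = dlogits.T @ cache["out_input"]
    grads["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ params["out_W"]

    for i in reversed(range(len(spec.head_widths))):
        blk = cache[f"h{i}"]
        if blk["mask"] is not None:
            dact = dh * blk["mask"]
        else:
            dact = dh
        if spec.head_activation == "relu":
            dy = dact * (blk["y"] > 0)
        else:
            dy = dact
        grads[f"h{i}_gamma"] = (dy * blk["xhat"]).sum(axis=0)
        grads[f"h{i}_beta"] = dy.sum(axis=0)
        dxhat = dy * params[f"h{i}_gamma"]
        a, mu, inv_std = blk["a"], blk["mu"], blk["inv_std"]
        centered = a - mu
        dvar = np.sum(dxhat * centered, axis=0) * (-0.5) * inv_std**3
        dmu = -np.sum(dxhat, axis=0) * inv_std + dvar * np.mean(-2.0 * centered, axis=0)
        da = dxhat * inv_std + dvar * 2.0 * centered / b + dmu / b
        grads[f"h{i}_W"] = da.T @ blk["input"]
        grads[f"h{i}_b"] = da.sum(axis=0)
        dh = da @ params[f"h{i}_W"]

    dc_direct, dq = split_fused(dh)
    cp = circuits.CircuitParams(spec.n_layers, spec.n_qubits, params["theta"])
    c = cache["c"]
    dq_dtheta = circuits.circuit_gradient(c, cp, spec.topology, spec.rotation_order)
    dq_dc = circuits.input_gradient(c, cp, spec.topology, spec.rotation_order)
    grads["theta"] = np.einsum("bj,bjlik->lik", dq, dq_dtheta)
    dc = dc_direct + np.einsum("bj,bji->bi", dq, dq_dc)
    dc_pre = dc * (1.0 - c**2)  # tanh backward
    grads["proj_W"] = dc_pre.T @ cache["z"]
    grads["proj_b"] = dc_pre.sum(axis=0)
    return loss, acc, grads


def _clip_global_norm(grads: dict, max_norm: float | None) -> dict:
    if max_norm is None:
        return grads
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return {k: g * scale for k, g in grads.items()}


# ---------------------------------------------------------------------------
# model / results


class HybridQuantumClassifier:
    """Hybrid variational-quantum transfer-learning classifier.

    Built from pre-extracted (frozen-backbone) feature vectors and integer
    labels; ``fit`` trains the projection, circuit and head and returns a
    :class:`HybridFitResults`.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        val_features: np.ndarray,
        val_labels: np.ndarray,
        spec: ModelSpec | None = None,
    ) -> None:
        self.z_train = np.asarray(features, dtype=float)
        self.y_train = np.asarray(labels, dtype=int)
        self.z_val = np.asarray(val_features, dtype=float)
        self.y_val = np.asarray(val_labels, dtype=int)
        if self.z_train.ndim != 2:
            raise TrainingError("features must be a (samples, d) matrix")
        if self.z_train.shape[0] == 0 or self.z_val.shape[0] == 0:
            raise TrainingError("training and validation splits must be non-empty")
        if self.z_train.shape[0] != self.y_train.shape[0]:
            raise TrainingError("feature/label counts differ")
        if np.unique(self.y_train).size < 2:
            raise TrainingError("training set contains a single class")
        self.spec = spec or ModelSpec(feature_dim=self.z_train.shape[1])
        if self.spec.feature_dim != self.z_train.shape[1]:
            raise TrainingError(
                f"spec declares d={self.spec.feature_dim} but features have "
                f"width {self.z_train.shape[1]}"
            )
        n_classes = self.spec.n_classes
        if self.y_train.min() < 0 or self.y_train.max() >= n_classes:
            raise TrainingError(f"labels must lie in [0, {n_classes})")
        # per-feature z-scoring fitted on the training split only; pooled
        # backbone features are all-positive with wildly uneven scales, and
        # the projection layer assumes roughly centred, unit-scale inputs
        if self.spec.standardize_features:
            self.feat_mean = self.z_train.mean(axis=0)
            sd = self.z_train.std(axis=0)
            self.feat_std = np.where(sd < 1e-8, 1.0, sd)
        else:
            self.feat_mean = np.zeros(self.z_train.shape[1])
            self.feat_std = np.ones(self.z_train.shape[1])
        self.z_train = (self.z_train - self.feat_mean) / self.feat_std
        self.z_val = (self.z_val - self.feat_mean) / self.feat_std

    @classmethod
    def from_images(
        cls,
        images: np.ndarray,
        labels: np.ndarray,
        val_images: np.ndarray,
        val_labels: np.ndarray,
        backbone,
        **spec_kw,
    ) -> "HybridQuantumClassifier":
        spec = ModelSpec.toy(backbone, **spec_kw)
        return cls(
            extract_features(images, backbone),
            labels,
            extract_features(val_images, backbone),
            val_labels,
            spec=spec,
        )

    # -- training ----------------------------------------------------------

    def fit(
        self,
        cfg: TrainConfig | None = None,
        _val_evaluator: Callable[[dict, dict], tuple[float, float]] | None = None,
    ) -> "HybridFitResults":
        """Train with the configured optimizer; reproducible under the seed.

        ``_val_evaluator`` is a test hook replacing the validation pass;
        it receives (params, state) and returns (val_loss, val_acc).
        """
        cfg = cfg or TrainConfig()
        spec = self.spec
        rng = np.random.default_rng(cfg.seed)
        params = init_params(spec, rng)
        state = init_state(spec)
        try:
            opt = _OPTIMIZERS[cfg.optimizer](
                lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps
            )
        except KeyError:
            raise TrainingError(f"unknown optimizer {cfg.optimizer!r}") from None

        trace = TrainingTrace()
        best_loss = np.inf
        best_epoch = 0
        best_params: dict | None = None
        best_state: dict | None = None
        plateau_wait = 0
        n = self.z_train.shape[0]
        probe = np.full(spec.n_qubits, 0.5)  # fixed diagnostic embedding
        iteration = 0

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            batch_losses, batch_accs = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, acc, grads = _loss_and_grads(
                    self.z_train[idx], self.y_train[idx], params, state, spec, rng
                )
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                grads = _clip_global_norm(grads, cfg.grad_clip_norm)
                params = opt.step(params, grads)
                batch_losses.append(loss)
                batch_accs.append(acc)
                if cfg.record_quantum_diagnostics:
                    trace.costs.append(loss)
                    if iteration % cfg.probe_every == 0:
                        cp = circuits.CircuitParams(
                            spec.n_layers, spec.n_qubits, params["theta"]
                        )
                        z_probe = circuits.run_circuit(
                            probe, cp, spec.topology, spec.rotation_order
                        )
                        trace.probe_z.append([float(v) for v in z_probe])
                        trace.theta_path.append(
                            [float(v) for v in params["theta"].ravel()]
                        )
                iteration += 1

            if _val_evaluator is not None:
                val_loss, val_acc = _val_evaluator(params, state)
            else:
                val_loss, val_acc = self._evaluate_split(params, state)

            trace.epoch.append(epoch)
            trace.train_loss.append(float(np.mean(batch_losses)))
            trace.train_acc.append(float(np.mean(batch_accs)))
            trace.val_loss.append(float(val_loss))
            trace.val_acc.append(float(val_acc))

            if val_loss < best_loss:
                best_loss = val_loss
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in params.items()}
                best_state = {k: v.copy() for k, v in state.items()}
                plateau_wait = 0
            else:
                plateau_wait += 1
                if plateau_wait >= cfg.plateau_patience:
                    opt.lr *= cfg.plateau_factor
                    plateau_wait = 0
            if epoch - best_epoch >= cfg.early_stop_patience:
                break

        trace.best_epoch = best_epoch
        trace.stopped_epoch = trace.epoch[-1]
        final_params = best_params if best_params is not None else params
        final_state = best_state if best_state is not None else state
        return HybridFitResults(self, final_params, final_state, trace, cfg)

    def _evaluate_split(self, params: dict, state: dict) -> tuple[float, float]:
        probs = _forward(self.z_val, params, state, self.spec, "infer")
        b = self.z_val.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(b), self.y_val] + 1e-12)))
        acc = float(np.mean(probs.argmax(axis=1) == self.y_val))
        return loss, acc


class HybridFitResults:
    """Fitted parameters, the training trace, and evaluation helpers."""

    def __init__(
        self,
        model: HybridQuantumClassifier,
        params: dict,
        state: dict,
        trace: TrainingTrace,
        cfg: TrainConfig,
    ) -> None:
        self.model = model
        self.spec = model.spec
        self.params = params
        self.state = state
        self.trace = trace
        self.cfg = cfg
        self.feat_mean = getattr(model, "feat_mean", None)
        self.feat_std = getattr(model, "feat_std", None)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = np.asarray(features, dtype=float)
        if self.feat_mean is not None:
            z = (z - self.feat_mean) / self.feat_std
        return _forward(z, self.params, self.state, self.spec, "infer")

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=-1)

    def evaluate(self, features: np.ndarray, labels: np.ndarray) -> MetricsReport:
        probs = self.predict_proba(features)
        preds = probs.argmax(axis=-1)
        cm = confusion_matrix(labels, preds, self.spec.n_classes)
        report = classification_report(cm)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            report.auc, report.macro_auc = roc_auc_ovr(labels, probs)
        return report

    # -- accounting / reporting -------------------------------------------

    @property
    def ledger(self):
        return build_ledger(self.spec)

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def summary(self) -> str:
        led = self.ledger
        lines = [
            "Hybrid variational-quantum classifier",
            "=" * 54,
            f"backbone           {self.spec.backbone_id} (frozen, "
            f"{self.spec.backbone_nontrainable:,} params)",
            f"circuit            {self.spec.n_qubits} qubits x "
            f"{self.spec.n_layers} entangling layers ({self.spec.topology})",
            f"trainable params   {led.trainable_total:,} "
            f"(tensor count {self.n_trainable():,})",
            f"FLOPs (2P)         {2 * led.trainable_total:,}",
            f"epochs run         {self.trace.stopped_epoch} "
            f"(best: {self.trace.best_epoch})",
        ]
        if self.trace.val_acc:
            i = self.trace.best_epoch - self.trace.epoch[0]
            lines += [
                f"final train acc    {self.trace.train_acc[-1]:.4f}",
                f"final val acc      {self.trace.val_acc[-1]:.4f}",
                f"best val loss      {min(self.trace.val_loss):.4f} "
                f"(val acc {self.trace.val_acc[i]:.4f})",
            ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "schema": CHECKPOINT_SCHEMA,
            "spec": asdict(self.spec),
            "cfg": asdict(self.cfg),
            "seed": self.cfg.seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "state": {k: v.tolist() for k, v in self.state.items()},
            "feat_mean": None if self.feat_mean is None else self.feat_mean.tolist(),
            "feat_std": None if self.feat_std is None else self.feat_std.tolist(),
            "trace": {
                "epoch": self.trace.epoch,
                "train_loss": self.trace.train_loss,
                "train_acc": self.trace.train_acc,
                "val_loss": self.trace.val_loss,
                "val_acc": self.trace.val_acc,
                "best_epoch": self.trace.best_epoch,
                "stopped_epoch": self.trace.stopped_epoch,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HybridFitResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != CHECKPOINT_SCHEMA:
            raise TrainingError(
                f"unsupported checkpoint schema {payload.get('schema')!r}"
            )
        spec_d = payload["spec"]
        for key in ("head_widths", "input_size"):
            spec_d[key] = tuple(spec_d[key])
        spec = ModelSpec(**spec_d)
        cfg = TrainConfig(**payload["cfg"])
        params = {k: np.array(v) for k, v in payload["params"].items()}
        state = {k: np.array(v) for k, v in payload["state"].items()}
        trace = TrainingTrace()
        for key, value in payload["trace"].items():
            setattr(trace, key, value)
        shell = HybridQuantumClassifier.__new__(HybridQuantumClassifier)
        shell.spec = spec
        if payload.get("feat_mean") is not None:
            shell.feat_mean = np.array(payload["feat_mean"])
            shell.feat_std = np.array(payload["feat_std"])
        return cls(shell, params, state, trace, cfg)
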