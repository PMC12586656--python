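"""Frozen feature-extraction backbones.

The hybrid classifier never updates its backbone: it is a fixed map from a
preprocessed image to a pooled d-dimensional feature vector. Two kinds of
adapter exist here:

* ``ToyConvBackbone`` — a seeded random convolution stack with global
  average pooling. Its weights are drawn once from the seed and never
  change, which makes it a deterministic stand-in extractor for tests and
  desk-scale experiments (random convolutional features are a standard
  frozen-feature baseline).
* Named profiles of the four pretrained networks the accounting ledger
  covers (ResNet50, MobileNetV2, InceptionResNetV2, DenseNet201). These
  are metadata adapters: they declare the published pooled feature width
  and frozen parameter count so ledgers and configs can be built without
  instantiating the networks; they do not ship weights and cannot extract
  features themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BackboneProfile", "ToyConvBackbone", "get_profile", "PROFILES"]


class BackboneError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneProfile:
    """Declared metadata of a (pretrained) backbone."""

    backbone_id: str
    feature_dim: int
    non_trainable: int
    input_size: tuple[int, int, int] = (224, 224, 3)
    preprocessing: str = "backbone_declared"
    functional: bool = False  # can extract_features be called?


#: Published pooled-feature widths and the frozen-parameter counts used by
#: the parameter ledger for each supported pretrained profile.
PROFILES: dict[str, BackboneProfile] = {
    "resnet50": BackboneProfile("resnet50", 2048, 23_588_096),
    "mobilenetv2": BackboneProfile("mobilenetv2", 1280, 2_258_368),
    "inceptionresnetv2": BackboneProfile("inceptionresnetv2", 1536, 54_337_120),
    "densenet201": BackboneProfile("densenet201", 1920, 18_322_368),
}


def get_profile(name: str) -> BackboneProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise BackboneError(
            f"unknown backbone profile {name!r}; known: {sorted(PROFILES)} or 'toy'"
        ) from None


class ToyConvBackbone:
    """Seeded random two-layer convolution stack with GAP readout.

    conv(3 -> d/2, 3x3, stride 2, ReLU) -> conv(d/2 -> d, 3x3, stride 2,
    ReLU) -> global average pooling. Weights are fixed at construction from
    the seed; repeated calls on identical input are bit-identical, and the
    parameters are exposed read-only so the frozen contract is checkable.
    """

    def __init__(
        self,
        feature_dim: int = 16,
        input_size: tuple[int, int, int] = (32, 32, 3),
        seed: int = 0,
    ) -> None:
        if feature_dim < 2 or feature_dim % 2:
            raise BackboneError("feature_dim must be an even integer >= 2")
        self.backbone_id = f"toy{feature_dim}"
        self.feature_dim = int(feature_dim)
        self.input_size = tuple(input_size)
        self.preprocessing = "scale01"
        self.functional = True
        rng = np.random.default_rng(seed)
        c_mid = feature_dim // 2
        # He-style scaling keeps activations in a usable range after ReLU.
        self._w1 = rng.normal(0.0, np.sqrt(2.0 / (3 * 9)), size=(c_mid, 3, 3, 3))
        self._b1 = rng.normal(0.0, 0.1, size=c_mid)
        self._w2 = rng.normal(
            0.0, np.sqrt(2.0 / (c_mid * 9)), size=(feature_dim, c_mid, 3, 3)
        )
        self._b2 = rng.normal(0.0, 0.1, size=feature_dim)

    @property
    def non_trainable(self) -> int:
        return self._w1.size + self._b1.size + self._w2.size + self._b2.size

    def parameter_bytes(self) -> bytes:
        """Byte snapshot of the frozen weights (for frozen-contract checks)."""
        return b"".join(
            np.ascontiguousarray(a).tobytes()
            for a in (self._w1, self._b1, self._w2, self._b2)
        )

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
        """Valid-padding strided convolution, x: (B, H, W, C) -> (B, H', W', F)."""
        kb, kc, kh, kw = w.shape
        windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        windows = windows[:, ::stride, ::stride]  # (B, H', W', C, kh, kw)
        out = np.einsum("bhwckl,fckl->bhwf", windows, w) + b
        return np.maximum(out, 0.0)

    def extract_features(self, images: np.ndarray) -> np.ndarray:
        """Pooled feature vectors, shape (B, d), from (B, H, W, 3) images.

        Images must already be preprocessed to the declared input size and
        [0, 1] range.
        """
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[None]
        expected = (self.input_size[0], self.input_size[1], self.input_size[2])
        if x.shape[1:] != expected:
            raise BackboneError(
                f"image batch has shape {x.shape[1:]}, backbone expects {expected}"
            )
        h = self._conv(x, self._w1, self._b1, stride=2)
        h = self._conv(h, self._w2, self._b2, stride=2)
        return h.mean(axis=(1, 2))
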