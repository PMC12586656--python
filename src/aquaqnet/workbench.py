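"""Reproducible experiment runs: folder I/O, configuration, pipeline.

An experiment is described by a nested config (YAML on disk, a plain dict
in memory) whose blocks map onto the module dataclasses: ``synthetic``,
``model``, ``train``, ``augment``, ``split``. Every block is validated by
constructing the corresponding dataclass before any computation starts,
and a single global seed drives synthesis, splitting, augmentation and
training, so a manifest (resolved config + seed + artifact hashes) is
sufficient to re-create every reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from . import metrics as metrics_mod
from . import pqsfp as pqsfp_mod
from .backbones import ToyConvBackbone
from .datasets import (
    AugmentConfig,
    SyntheticDatasetConfig,
    augment,
    generate_dataset,
    preprocess,
    stratified_split,
)
from .model import (
    HybridQuantumClassifier,
    ModelSpec,
    TrainConfig,
    extract_features,
)

__all__ = ["load_image_folder", "save_image_folder", "resolve_config", "run_experiment"]

log = logging.getLogger("aquaqnet")


class WorkbenchError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# image-folder I/O (class-per-subdirectory convention)


def load_image_folder(path) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Read a class-per-subdirectory image corpus.

    Class names are the subdirectory names in alphabetical order; labels are
    indices into that ordering. Corrupt or undecodable files are skipped
    with a warning and reflected in the final count report.
    """
    root = Path(path)
    if not root.is_dir():
        raise WorkbenchError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise WorkbenchError(
            f"no class subdirectories found under {root}; expected one "
            "directory per class containing PNG/JPEG images"
        )
    images: list[np.ndarray] = []
    labels: list[int] = []
    skipped = 0
    total = 0
    for label, class_dir in enumerate(class_dirs):
        for file in sorted(class_dir.iterdir()):
            if file.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            total += 1
            try:
                with Image.open(file) as im:
                    images.append(np.asarray(im.convert("RGB")))
                labels.append(label)
            except (UnidentifiedImageError, OSError) as exc:
                skipped += 1
                log.warning("skipping unreadable image %s (%s)", file, exc)
    log.info(
        "loaded %d/%d images from %d classes under %s",
        total - skipped, total, len(class_dirs), root,
    )
    if not images:
        raise WorkbenchError(f"no decodable images under {root}")
    return images, np.asarray(labels), [d.name for d in class_dirs]


def save_image_folder(
    images: np.ndarray, labels: np.ndarray, class_names, out_dir
) -> Path:
    """Write a corpus in the same class-per-subdirectory layout + labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {name: 0 for name in class_names}
    for img, label in zip(images, labels):
        name = class_names[int(label)]
        sub = out / name
        sub.mkdir(exist_ok=True)
        fname = f"{name}_{counters[name]:05d}.png"
        counters[name] += 1
        Image.fromarray(np.asarray(img)).save(sub / fname)
        rows.append({"file": f"{name}/{fname}", "class": name, "label": int(label)})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data_dir": None,  # set this OR synthetic.enabled
    "synthetic": {"enabled": True, "per_class": 200, "image_size": [64, 64]},
    "backbone": {"kind": "toy", "feature_dim": 16, "input_size": [32, 32, 3]},
    "model": {"n_qubits": 4, "n_layers": 2, "n_classes": 5},
    "train": {},
    "augment": {"enabled": False, "copies": 1},
    "split": {"ratios": [0.70, 0.20, 0.10]},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None = None) -> dict:
    """Merge a user config over the defaults and validate every block."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    if cfg["data_dir"] is None and not cfg["synthetic"].get("enabled", False):
        raise WorkbenchError(
            "configuration must set 'data_dir' or enable the 'synthetic' block"
        )
    # construct the dataclasses now so invalid blocks fail before any work
    syn = {k: v for k, v in cfg["synthetic"].items() if k != "enabled"}
    syn.setdefault("seed", seed)
    syn["image_size"] = tuple(syn.get("image_size", (224, 224)))
    SyntheticDatasetConfig(**syn)
    TrainConfig(**{**cfg["train"], "seed": cfg["train"].get("seed", seed)})
    aug = {k: v for k, v in cfg["augment"].items() if k not in ("enabled", "copies")}
    AugmentConfig(**aug)
    ratios = cfg["split"]["ratios"]
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise WorkbenchError("split ratios must sum to 1")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_experiment(config: dict | None, out_dir) -> dict:
    """synth/load -> split -> (augment) -> train -> evaluate -> account -> pqsfp.

    Writes trace.csv, metrics.json, ledger.csv, pqsfp.csv, checkpoint.json
    and manifest.json under ``out_dir`` and returns the paths plus headline
    numbers. Any stage failure raises with the stage name.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stage = "setup"
    try:
        stage = "data"
        if cfg["data_dir"] is not None:
            images, labels, class_names = load_image_folder(cfg["data_dir"])
        else:
            syn = {k: v for k, v in cfg["synthetic"].items() if k != "enabled"}
            syn.setdefault("seed", seed)
            syn["image_size"] = tuple(syn.get("image_size", (224, 224)))
            syn_cfg = SyntheticDatasetConfig(**syn)
            images, labels = generate_dataset(syn_cfg)
            class_names = list(syn_cfg.class_names)

        stage = "split"
        train_idx, val_idx, test_idx = stratified_split(
            labels, tuple(cfg["split"]["ratios"]), seed=seed
        )

        stage = "backbone"
        bb_cfg = cfg["backbone"]
        if bb_cfg.get("kind", "toy") != "toy":
            raise WorkbenchError(
                "only the functional 'toy' backbone can run the pipeline; "
                "pretrained profiles are accounting metadata"
            )
        backbone = ToyConvBackbone(
            feature_dim=int(bb_cfg.get("feature_dim", 16)),
            input_size=tuple(bb_cfg.get("input_size", (32, 32, 3))),
            seed=seed,
        )

        stage = "preprocess"
        target = backbone.input_size[:2]

        def prep(idx_list, aug_rng=None, copies=0):
            xs, ys = [], []
            for i in idx_list:
                img = images[i]
                xs.append(preprocess(img, target, backbone.preprocessing))
                ys.append(labels[i])
                for _ in range(copies):
                    a = augment(
                        img,
                        AugmentConfig(
                            **{
                                k: v
                                for k, v in cfg["augment"].items()
                                if k not in ("enabled", "copies")
                            }
                        ),
                        seed=int(aug_rng.integers(2**31)),
                    )
                    xs.append(preprocess(a, target, backbone.preprocessing))
                    ys.append(labels[i])
            return np.stack(xs), np.asarray(ys)

        aug_rng = np.random.default_rng(seed + 1)
        copies = int(cfg["augment"].get("copies", 0)) if cfg["augment"].get(
            "enabled", False
        ) else 0
        x_train, y_train = prep(train_idx, aug_rng, copies)
        x_val, y_val = prep(val_idx)
        x_test, y_test = prep(test_idx)

        stage = "features"
        z_train = extract_features(x_train, backbone)
        z_val = extract_features(x_val, backbone)
        z_test = extract_features(x_test, backbone)

        stage = "train"
        spec = ModelSpec.toy(backbone, **cfg["model"])
        train_cfg = TrainConfig(
            **{**cfg["train"], "seed": cfg["train"].get("seed", seed)}
        )
        model = HybridQuantumClassifier(z_train, y_train, z_val, y_val, spec=spec)
        results = model.fit(train_cfg)
        trace_path = out / "trace.csv"
        results.trace.to_csv(trace_path)
        ckpt_path = out / "checkpoint.json"
        results.save(ckpt_path)

        stage = "evaluate"
        t0 = time.perf_counter()
        report = results.evaluate(z_test, y_test)
        t1 = time.perf_counter()
        eff = metrics_mod.efficiency([max(t1 - t0, 1e-9)], len(y_test))
        dyn = metrics_mod.training_dynamics(
            results.trace.val_acc, results.trace.train_acc
        )
        metrics_path = out / "metrics.json"
        payload = report.to_dict()
        payload.update(
            {
                "class_names": class_names,
                "throughput_img_per_s": eff.throughput,
                "latency_ms_per_img": eff.latency_ms,
                "e90": dyn.e90,
                "sigma_val": dyn.sigma_val,
                "delta_acc": dyn.delta_acc,
            }
        )
        metrics_path.write_text(json.dumps(payload, indent=2))

        stage = "account"
        ledger_path = out / "ledger.csv"
        results.ledger.to_frame().to_csv(ledger_path, index=False)

        stage = "pqsfp"
        point_df = pd.DataFrame(
            [
                {
                    "label": spec.backbone_id,
                    "params": results.ledger.trainable_total,
                    "acc_train": results.trace.train_acc[-1],
                    "acc_val": results.trace.val_acc[-1],
                    "val_loss": results.trace.val_loss[-1],
                }
            ]
        )
        pqsfp_path = out / "pqsfp.csv"
        pqsfp_mod.map_table(point_df).to_csv(pqsfp_path, index=False)

        stage = "manifest"
        artifacts = {
            "trace": trace_path,
            "metrics": metrics_path,
            "ledger": ledger_path,
            "pqsfp": pqsfp_path,
            "checkpoint": ckpt_path,
        }
        manifest = {
            "config": cfg,
            "seed": seed,
            "class_names": class_names,
            "n_images": int(len(labels)),
            "splits": {
                "train": int(len(train_idx)),
                "val": int(len(val_idx)),
                "test": int(len(test_idx)),
            },
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "hashes": {k: _sha256(v) for k, v in artifacts.items()},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # annotate with the failing stage
        raise WorkbenchError(f"experiment failed at stage {stage!r}: {exc}") from exc

    return {
        "out_dir": str(out),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "manifest": str(manifest_path),
        "test_accuracy": report.accuracy,
        "val_accuracy": results.trace.val_acc[-1],
        "summary": results.summary(),
    }
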