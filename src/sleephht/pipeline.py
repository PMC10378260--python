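"""End-to-end orchestration: generate/ingest -> EMD -> features + spectrum
images -> split/standardize -> train -> evaluate.

One global seed fans out deterministically to per-stage seeds, every
intermediate is cached on disk keyed by a hash of the stages that produced
it, and a run manifest records seeds, sizes and stage checksums, so a rerun
with an identical configuration reuses cached intermediates and reproduces
the same report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import ingest
from .emd import EMDConfig, decompose
from .features import featurize_epoch, standardize_features
from .hht import SpectrumGrid, hilbert_spectrum, render_image
from .model import (
    ModelConfig,
    TrainConfig,
    build_cnn_only,
    build_model,
    predict,
    split_dataset,
    train,
)
from .evaluate import confusion_matrix, metrics, per_class_metrics, report
from .synthetic import SyntheticDatasetSpec, generate_dataset

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "extract_inputs"]

logger = logging.getLogger(__name__)

SIXCLASS_ORDER = ["W", "1", "2", "3", "4", "R"]


@dataclass(frozen=True)
class PipelineConfig:
    scheme: str = "binary"  # binary | sixclass
    # input: either a synthetic dataset recipe ...
    n_per_class: int = 400
    stages: tuple[str, ...] = ("W", "3")
    # ... or EDF paths (take precedence when set)
    edf_path: str | None = None
    hypnogram_path: str | None = None
    channel: str = "EEG Pz-Oz"
    balance: bool = True
    emd: EMDConfig = field(default_factory=EMDConfig)
    grid: SpectrumGrid = field(default_factory=SpectrumGrid)
    n_imfs_used: int = 4
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    model_variant: str = "mixed"  # mixed | cnn_only
    out_dir: str = "runs/default"
    seed: int = 0


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the configuration is runnable; each problem names the
    offending field and constraint."""
    problems: list[str] = []
    if config.scheme not in ("binary", "sixclass"):
        problems.append(f"scheme: unknown scheme {config.scheme!r}")
    if config.scheme == "binary" and config.model.n_classes != 2:
        problems.append("model.n_classes: binary scheme requires n_classes == 2")
    if config.scheme == "sixclass" and config.model.n_classes != 6:
        problems.append("model.n_classes: sixclass scheme requires n_classes == 6")
    if config.n_per_class < 1:
        problems.append("n_per_class: must be >= 1")
    if config.grid.freq_max > 50.0 + 1e-9 and config.edf_path is None:
        problems.append("grid.freq_max: exceeds fs/2 = 50 Hz at fs = 100 Hz")
    if config.n_imfs_used < 1:
        problems.append("n_imfs_used: must be >= 1")
    if config.model.feature_dim != 16 * config.n_imfs_used:
        problems.append("model.feature_dim: must equal 16 * n_imfs_used")
    hw = config.grid.n_freq_bins, config.grid.n_time_bins
    if tuple(config.model.image_shape[:2]) != hw:
        problems.append("model.image_shape: must match the spectrum grid bins")
    if config.model_variant not in ("mixed", "cnn_only"):
        problems.append(f"model_variant: unknown variant {config.model_variant!r}")
    try:
        if config.train.epochs < 1:
            problems.append("train.epochs: must be >= 1")
    except Exception as e:  # pragma: no cover - dataclass validation
        problems.append(f"train: {e}")
    return problems


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("data", "balance", "split", "train")
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def _config_key(config: PipelineConfig, stage: str) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    relevant = {
        "data": ["scheme", "n_per_class", "stages", "edf_path", "hypnogram_path",
                 "channel", "balance", "seed"],
        "transform": ["emd", "grid", "n_imfs_used"],
        "trained": ["model", "train", "model_variant"],
    }
    fields: list[str] = []
    for st in ("data", "transform", "trained"):
        fields.extend(relevant[st])
        if st == stage:
            break
    payload = {f: enc(getattr(config, f)) for f in fields}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_epochs(config: PipelineConfig, seeds: dict[str, int]):
    if config.edf_path is not None:
        signal = ingest.read_psg_channel(config.edf_path, config.channel)
        annotations = ingest.read_hypnogram(config.hypnogram_path)
        epochs = ingest.segment_epochs(signal, annotations)
        fs = signal.fs
    else:
        spec = SyntheticDatasetSpec(
            n_per_class=config.n_per_class,
            stages=tuple(config.stages),
            seed=seeds["data"],
        )
        epochs = generate_dataset(spec)
        fs = spec.fs
    logger.info("stage data: %d epochs in", len(epochs))
    if config.scheme == "binary":
        epochs = ingest.map_labels_binary(epochs)
        if config.balance:
            counts = {l: sum(ep.label == l for ep in epochs) for l in ("sleep", "wake")}
            if counts["sleep"] != counts["wake"]:
                epochs = ingest.balance_classes(epochs, seed=seeds["balance"])
        classes = list(ingest_binary_order())
    else:
        epochs = [ep for ep in epochs if ep.label not in ("M", "?")]
        classes = SIXCLASS_ORDER
    logger.info(
        "stage data: %d epochs out, classes %s", len(epochs), classes
    )
    return epochs, classes, fs


def ingest_binary_order() -> list[str]:
    from .evaluate import BINARY_CLASSES

    return BINARY_CLASSES


def extract_inputs(
    epochs,
    emd_config: EMDConfig,
    grid: SpectrumGrid,
    n_imfs_used: int,
    fs: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch EMD -> (feature matrix, image stack)."""
    feats, imgs = [], []
    for ep in epochs:
        dec = decompose(ep.samples, emd_config)
        feats.append(featurize_epoch(dec, n_imfs_used).values)
        spec = hilbert_spectrum(dec, grid, fs=fs)
        imgs.append(render_image(spec))
    return np.asarray(feats), np.asarray(imgs, dtype=np.float32)


def _sweep_data(n_per_class: int, seed: int) -> dict:
    """Aligned feature/image/label arrays plus a held-out test split for
    the training-epoch sweep, on the default synthetic two-class task."""
    seeds = _stage_seeds(seed)
    cfg = PipelineConfig(n_per_class=n_per_class, seed=seed)
    epochs, classes, fs = _load_epochs(cfg, seeds)
    features, images = extract_inputs(epochs, cfg.emd, cfg.grid, cfg.n_imfs_used, fs)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[ep.label] for ep in epochs])
    from dataclasses import replace

    tr, val, te = split_dataset(y, replace(cfg.train, seed=seeds["split"]))
    tr = np.concatenate([tr, val])  # the sweep needs no validation split
    (f_tr, f_te), _ = standardize_features(features[tr], features[te])
    return {
        "features": f_tr, "images": images[tr], "labels": y[tr],
        "features_test": f_te, "images_test": images[te], "labels_test": y[te],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report payload augmented with paths
    and the test-set predictions. Intermediates are cached under
    ``out_dir`` and reused when the producing configuration is unchanged."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}

    # ---- stage 1+2: epochs -> features/images (cached together) ----------
    key = _config_key(config, "transform")
    cache = os.path.join(config.out_dir, f"inputs_{key}.npz")
    if os.path.exists(cache):
        logger.info("stage transform: reusing cache %s", cache)
        blob = np.load(cache, allow_pickle=False)
        features, images = blob["features"], blob["images"]
        labels_str = blob["labels"].tolist()
        classes = blob["classes"].tolist()
    else:
        epochs, classes, fs = _load_epochs(config, seeds)
        if not epochs:
            raise RuntimeError("stage data produced no epochs")
        features, images = extract_inputs(
            epochs, config.emd, config.grid, config.n_imfs_used, fs
        )
        labels_str = [ep.label for ep in epochs]
        np.savez_compressed(
            cache,
            features=features,
            images=images,
            labels=np.array(labels_str),
            classes=np.array(classes),
        )
    manifest["stages"]["inputs"] = {"cache": cache, "sha256": _checksum(cache),
                                    "n_epochs": int(len(features))}

    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels_str])

    # ---- stage 3: split + standardize ------------------------------------
    from dataclasses import replace

    tcfg = replace(config.train, seed=seeds["split"])
    tr, val, te = split_dataset(y, tcfg)
    (f_tr, f_val, f_te), _ = standardize_features(
        features[tr], features[val], features[te]
    )

    # ---- stage 4: train ---------------------------------------------------
    builder = build_model if config.model_variant == "mixed" else build_cnn_only
    tcfg = replace(config.train, seed=seeds["train"])
    model = builder(config.model, seed=seeds["train"])
    history = train(
        model, f_tr, images[tr], y[tr], tcfg,
        validation_data=(f_val, images[val], y[val]),
    )

    # ---- stage 5: evaluate -------------------------------------------------
    pred_codes, probs = predict(model, f_te, images[te])
    y_true = [classes[i] for i in y[te]]
    y_pred = [classes[i] for i in pred_codes]
    cm = confusion_matrix(y_true, y_pred, classes)
    if config.scheme == "binary":
        m = metrics(cm)
    else:
        m = per_class_metrics(cm)
    payload = report(m, history, cm, config.out_dir)
    payload["test_accuracy"] = float(np.mean(pred_codes == y[te]))
    payload["n_test"] = int(len(te))
    manifest["stages"]["report"] = {"path": os.path.join(config.out_dir, "report.json")}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    payload["manifest"] = manifest
    return payload
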