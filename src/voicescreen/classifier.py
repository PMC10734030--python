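"""Building, fine-tuning and running the screening CNNs and their ensemble.

The model maps a 224x224x3 spectrogram image to a probability in (0, 1) whose
semantics are P(label = pass); the screen-positive class for evaluation is
*fail*. Training minimizes binary cross-entropy with Adam, holds out a
participant-level validation split (never window-level, to prevent leakage
between overlapping windows of one speaker), monitors validation loss with
early stopping and a reduce-on-plateau learning-rate schedule, and restores
the best-epoch parameters. Given a seed, the whole train->predict path is
bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import models
from .nn import Adam, Param, Sequential, bce_with_logits, sigmoid

LABEL_TO_TARGET = {"pass": 1.0, "fail": 0.0}


class ConfigurationError(ValueError):
    """Raised for invalid backbone/head/training configuration."""


_FREEZE_BOUNDARIES = {
    "densenet121": "last_dense_block",
    "convnext_tiny": "stage_3",
    "tinycnn": None,
}


@dataclass(frozen=True)
class BackboneSpec:
    """Which CNN to use and where fine-tuning starts."""

    name: str = "tinycnn"
    pretrained: bool = False
    freeze_boundary: Optional[str] = "default"

    def __post_init__(self) -> None:
        if self.name not in models.BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; expected one of {models.BACKBONES}"
            )
        if self.freeze_boundary == "default":
            object.__setattr__(self, "freeze_boundary", _FREEZE_BOUNDARIES[self.name])
        if self.freeze_boundary not in (None, _FREEZE_BOUNDARIES[self.name]):
            raise ConfigurationError(
                f"freeze boundary {self.freeze_boundary!r} is not valid for {self.name}"
            )
        if self.pretrained:
            raise ConfigurationError(
                "no pretrained weights are bundled with this package; "
                "build with pretrained=False (random initialization)"
            )


@dataclass(frozen=True)
class HeadSpec:
    """Global-average pooling head with dropout and one sigmoid unit."""

    pooling: str = "global_average"
    dropout_rate: float = 0.8

    def __post_init__(self) -> None:
        if self.pooling != "global_average":
            raise ConfigurationError("only global_average pooling is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 32
    target_epochs: int = 55
    patience: int = 7
    validation_fraction: float = 0.2
    monitor: str = "val_loss"
    lr_scheduler: bool = True
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must lie in (0, 1)")
        if self.patience < 0:
            raise ConfigurationError("patience must be non-negative")
        if self.target_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("target_epochs and batch_size must be positive")

    @staticmethod
    def for_backbone(name: str, seed: int = 0) -> "TrainConfig":
        """Per-backbone training profile.

        densenet121 / convnext_tiny follow the transfer-learning recipe
        (lr 1e-5, 55/30 target epochs, patience 7/10); tinycnn trains from
        scratch and uses a from-scratch profile (lr 3e-3, 18 epochs,
        patience 4).
        """
        if name == "densenet121":
            return TrainConfig(target_epochs=55, patience=7, seed=seed)
        if name == "convnext_tiny":
            return TrainConfig(target_epochs=30, patience=10, seed=seed)
        if name == "tinycnn":
            return TrainConfig(learning_rate=3e-3, target_epochs=18, patience=4, seed=seed)
        raise ConfigurationError(f"unknown backbone {name!r}")


_DEFAULT_HEAD_DROPOUT = {"densenet121": 0.8, "convnext_tiny": 0.8, "tinycnn": 0.2}


def default_head(backbone_name: str) -> HeadSpec:
    return HeadSpec(dropout_rate=_DEFAULT_HEAD_DROPOUT[backbone_name])


@dataclass
class LabeledImageSet:
    """Spectrogram images with participant/clip provenance and labels."""

    images: np.ndarray          # (N, S, S, 3), values in [0, 1]
    labels: np.ndarray          # (N,) of "pass"/"fail"
    participant_ids: np.ndarray
    clip_ids: np.ndarray
    window_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.images)
        if n == 0:
            raise ValueError("empty image set")
        if not (len(self.labels) == len(self.participant_ids) == len(self.clip_ids) == n):
            raise ValueError("image/label/id lengths differ")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def targets(self) -> np.ndarray:
        return np.array([LABEL_TO_TARGET[l] for l in self.labels], dtype=np.float64)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            participant_ids=self.participant_ids[idx],
            clip_ids=self.clip_ids[idx],
            window_indices=None if self.window_indices is None else self.window_indices[idx],
        )


@dataclass
class ScreenModel:
    """An (untrained or trained) network plus its build specification."""

    network: Sequential
    backbone: BackboneSpec
    head: HeadSpec
    image_size: int = 224
    init_seed: int = 0

    def logits(self, x_nchw: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        return self.network.forward(x_nchw, train=train, rng=rng)[:, 0]


@dataclass
class TrainedModel:
    """A fitted model with its training history and best-epoch index."""

    model: ScreenModel
    config: TrainConfig
    history: dict[str, list[float]]
    best_epoch: int
    val_participants: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.history["val_loss"])


def build_model(
    backbone: BackboneSpec = BackboneSpec(),
    head: HeadSpec | None = None,
    *,
    seed: int = 0,
    image_size: int = 224,
) -> ScreenModel:
    """Build a screening model mapping an image to a probability.

    Layers below the backbone's fine-tuning boundary are frozen (their
    parameters report non-trainable and are bit-identical before and after
    training); the remaining layers and the head are trainable.
    """
    if head is None:
        head = default_head(backbone.name)
    network, frozen_layers = models.build_backbone(backbone.name, head.dropout_rate, seed)
    if backbone.freeze_boundary is not None:
        for layer in frozen_layers:
            layer.freeze()
    return ScreenModel(network=network, backbone=backbone, head=head,
                       image_size=image_size, init_seed=seed)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images.astype(np.float32).transpose(0, 3, 1, 2))


def _forward_probs(model: ScreenModel, images: np.ndarray, chunk: int = 256) -> np.ndarray:
    out = np.empty(len(images), dtype=np.float64)
    for lo in range(0, len(images), chunk):
        batch = _to_nchw(images[lo:lo + chunk])
        out[lo:lo + chunk] = sigmoid(model.logits(batch))
    return out


def _eval_loss_acc(model: ScreenModel, images: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    probs = _forward_probs(model, images)
    eps = 1e-12
    loss = -np.mean(targets * np.log(probs + eps) + (1 - targets) * np.log(1 - probs + eps))
    acc = float(np.mean((probs >= 0.5) == (targets >= 0.5)))
    return float(loss), acc


def split_validation_participants(
    participant_ids: Sequence[str], labels_by_participant: dict[str, str],
    fraction: float, rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Participant-level validation split (images of one speaker never straddle)."""
    seen: dict[str, None] = {}
    for pid in participant_ids:
        seen.setdefault(pid, None)
    participants = list(seen)
    order = rng.permutation(len(participants))
    n_val = max(1, int(round(fraction * len(participants))))
    if n_val >= len(participants):
        n_val = len(participants) - 1
    val = [participants[i] for i in order[:n_val]]
    train = [participants[i] for i in order[n_val:]]
    train_labels = {labels_by_participant[p] for p in train}
    if len(train_labels) < 2:
        raise ValueError(
            "validation split left a single-class training set; "
            "provide more participants per class"
        )
    return train, val


def train(model: ScreenModel, data: LabeledImageSet, config: TrainConfig) -> TrainedModel:
    """Fine-tune a model on labeled spectrogram images.

    Splits off ``validation_fraction`` of *participants* for validation,
    optimizes BCE with Adam, reduces the learning rate on validation-loss
    plateaus, stops early when validation loss has not improved for
    ``patience`` epochs (or at ``target_epochs``), and restores the
    best-epoch parameters.
    """
    labels_present = set(data.labels.tolist())
    if len(labels_present) < 2:
        raise ValueError("training set contains a single class; need both pass and fail")
    if data.image_size != model.image_size:
        raise ValueError(
            f"image size {data.image_size} does not match model input {model.image_size}"
        )

    rng = np.random.default_rng(config.seed)
    labels_by_pid = {pid: lab for pid, lab in zip(data.participant_ids, data.labels)}
    train_pids, val_pids = split_validation_participants(
        data.participant_ids, labels_by_pid, config.validation_fraction, rng
    )
    train_mask = np.isin(data.participant_ids, train_pids)
    tr = data.subset(np.where(train_mask)[0])
    va = data.subset(np.where(~train_mask)[0])
    y_tr = tr.targets()
    y_va = va.targets()

    optimizer = Adam(model.network.params(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": [],
    }
    best_val = np.inf
    best_state: list[np.ndarray] = model.network.get_state()
    best_epoch = -1
    since_best = 0
    sched_since_best = 0

    n = len(tr)
    for epoch in range(config.target_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            x = _to_nchw(tr.images[idx])
            y = y_tr[idx]
            logits = model.logits(x, train=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, y)
            model.network.zero_grad()
            model.network.backward(dlogits[:, None])
            optimizer.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum((sigmoid(logits) >= 0.5) == (y >= 0.5)))

        val_loss, val_acc = _eval_loss_acc(model, va.images, y_va)
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(epoch_correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(optimizer.lr)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.network.get_state()
            best_epoch = epoch
            since_best = 0
            sched_since_best = 0
        else:
            since_best += 1
            sched_since_best += 1
            if config.lr_scheduler and sched_since_best > config.scheduler_patience:
                optimizer.lr *= config.scheduler_factor
                sched_since_best = 0
            if since_best > config.patience:
                break

    model.network.set_state(best_state)
    return TrainedModel(model=model, config=config, history=history,
                        best_epoch=best_epoch, val_participants=val_pids)


def train_backbone(
    backbone_name: str, data: LabeledImageSet, config: TrainConfig | None = None,
    *, seed: int = 0, image_size: int = 224, head: HeadSpec | None = None,
) -> TrainedModel:
    """Convenience: build a fresh model and train it (fully seed-reproducible)."""
    if config is None:
        config = TrainConfig.for_backbone(backbone_name, seed=seed)
    model = build_model(BackboneSpec(name=backbone_name), head,
                        seed=seed, image_size=image_size)
    return train(model, data, config)


def _check_image(model: ScreenModel, image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    expected = (model.image_size, model.image_size, 3)
    if image.shape != expected:
        raise ValueError(f"image shape {image.shape} does not match model input {expected}")
    return image


def predict_window(trained: TrainedModel, image: np.ndarray) -> float:
    """P(label = pass) for one spectrogram image; deterministic (dropout off)."""
    image = _check_image(trained.model, image)
    return float(_forward_probs(trained.model, image[None])[0])


def predict_batch(trained: TrainedModel, images: np.ndarray) -> np.ndarray:
    if len(images) and images[0].shape != (trained.model.image_size,) * 2 + (3,):
        raise ValueError("image shape does not match model input")
    return _forward_probs(trained.model, np.asarray(images))


def ensemble_predict(trained_models: Sequence[TrainedModel], image: np.ndarray) -> float:
    """Unweighted average of member probabilities for one image."""
    if len(trained_models) == 0:
        raise ValueError("ensemble requires at least one model")
    return float(np.mean([predict_window(m, image) for m in trained_models]))


def ensemble_predict_batch(
    trained_models: Sequence[TrainedModel], images: np.ndarray
) -> np.ndarray:
    if len(trained_models) == 0:
        raise ValueError("ensemble requires at least one model")
    return np.mean([predict_batch(m, images) for m in trained_models], axis=0)


# --- checkpoints -------------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path: str | Path) -> Path:
    """Save parameters (.npz) plus a JSON sidecar with specs and history."""
    path = Path(path)
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(trained.model.network.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "backbone": trained.model.backbone.name,
        "freeze_boundary": trained.model.backbone.freeze_boundary,
        "head_dropout": trained.model.head.dropout_rate,
        "image_size": trained.model.image_size,
        "init_seed": trained.model.init_seed,
        "train_config": {
            k: getattr(trained.config, k)
            for k in ("learning_rate", "batch_size", "target_epochs", "patience",
                      "validation_fraction", "lr_scheduler", "scheduler_factor",
                      "scheduler_patience", "seed")
        },
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "val_participants": trained.val_participants,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(
        BackboneSpec(name=meta["backbone"]),
        HeadSpec(dropout_rate=meta["head_dropout"]),
        seed=meta["init_seed"],
        image_size=meta["image_size"],
    )
    with np.load(path.with_suffix(".npz")) as data:
        state = [data[f"param_{i:04d}"] for i in range(len(data.files))]
    model.network.set_state(state)
    config = TrainConfig(**meta["train_config"])
    return TrainedModel(model=model, config=config, history=meta["history"],
                        best_epoch=meta["best_epoch"],
                        val_participants=meta.get("val_participants", []))
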