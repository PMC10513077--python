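"""Training and inference for the two segmentation tasks.

The network is trained separately per task — glomerular tuft (whole-tuft
foreground) and podocyte nuclei — on synthetic scenes with known masks.
Scenes are split into train/validation by scene (no patch of a
validation scene is ever seen in training); optimization runs on random
augmented crops with per-pixel weighted cross-entropy, where the weights
come from the border weight-map scheme.  The validation metric is the
Dice coefficient of the thresholded prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..synthetic import SceneGroundTruth
from .augment import AugmentConfig, augment
from .nn import Adam, EncoderDecoder, weighted_bce_with_logits
from .weightmap import WeightMapParams, make_weight_map

__all__ = ["TrainConfig", "SegmentationModel", "train", "predict", "dice",
           "save_model", "load_model", "split_scenes"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 4
    batch_size: int = 2
    learning_rate: float = 2e-3
    val_fraction: float = 0.2
    crop_size: int = 128
    crops_per_scene: int = 8
    prob_threshold: float = 0.5
    base_channels: int = 8
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    weight_map: WeightMapParams = field(default_factory=WeightMapParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.crop_size % 4:
            raise ValueError("crop_size must be a multiple of 4")


@dataclass
class SegmentationModel:
    """A trained network plus its task tag and architecture descriptor."""

    net: EncoderDecoder
    task: str                      # "tuft" | "nuclei"
    prob_threshold: float = 0.5
    config: TrainConfig | None = None
    training_log: pd.DataFrame | None = None
    val_dice: float = float("nan")
    val_scene_indices: list[int] = field(default_factory=list)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def split_scenes(n_scenes: int, val_fraction: float, seed: int):
    """Seeded scene-level train/validation split.

    Returns ``(train_indices, val_indices)``: disjoint, covering
    ``range(n_scenes)``, with at least one validation scene.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_scenes)
    n_val = max(1, int(round(val_fraction * n_scenes)))
    val_idx = sorted(int(i) for i in order[:n_val])
    train_idx = sorted(int(i) for i in order[n_val:])
    return train_idx, val_idx


def _task_target(scene: SceneGroundTruth, task: str) -> np.ndarray:
    if task == "tuft":
        return scene.tuft_mask
    if task == "nuclei":
        return scene.nuclei_mask
    raise ValueError(f"unknown task {task!r}")


def train(scenes: list[SceneGroundTruth], task: str,
          config: TrainConfig = TrainConfig()) -> SegmentationModel:
    """Train the encoder-decoder on one task.

    Requires at least two scenes so the validation split is nonempty.
    Returns the model with its training log (per-epoch loss and
    validation Dice) attached; aborts on a non-finite loss.
    """
    if len(scenes) < 2:
        raise ValueError("need at least two scenes")
    rng = np.random.default_rng(config.seed)

    train_idx, val_idx = split_scenes(len(scenes), config.val_fraction,
                                      config.seed)
    if not train_idx:
        raise ValueError("validation split leaves no training scenes")

    # per-scene targets and weight maps, computed once
    images = [s.image_wt1 for s in scenes]
    labels = [_task_target(s, task) for s in scenes]
    wmaps = {i: make_weight_map(labels[i], config.weight_map) for i in train_idx}

    net = EncoderDecoder(base_channels=config.base_channels, in_channels=1,
                         seed=config.seed)
    opt = Adam(net, lr=config.learning_rate)
    cs = config.crop_size
    log_rows = []

    for epoch in range(config.epochs):
        batch_x, batch_y, batch_w = [], [], []
        losses = []
        n_iter = len(train_idx) * config.crops_per_scene
        for it in range(n_iter):
            i = train_idx[int(rng.integers(len(train_idx)))]
            img, lab, wm = images[i], labels[i], wmaps[i]
            h, w = img.shape
            r0 = int(rng.integers(0, h - cs + 1))
            c0 = int(rng.integers(0, w - cs + 1))
            ic = img[r0 : r0 + cs, c0 : c0 + cs]
            lc = lab[r0 : r0 + cs, c0 : c0 + cs]
            wc = wm[r0 : r0 + cs, c0 : c0 + cs]
            aug_seed = int(rng.integers(2**31))
            ic, lc2 = augment(ic, lc, config.augmentation, aug_seed)
            wc, _ = augment(wc, lc, config.augmentation, aug_seed)
            batch_x.append(ic)
            batch_y.append(lc2 > 0)
            batch_w.append(wc)
            if len(batch_x) == config.batch_size or it == n_iter - 1:
                x = np.stack(batch_x)[:, None].astype(np.float64)
                y = np.stack(batch_y)[:, None].astype(np.float64)
                wt = np.stack(batch_w)[:, None].astype(np.float64)
                logits = net.forward(x)
                loss, dlogits = weighted_bce_with_logits(logits, y, wt)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
                batch_x, batch_y, batch_w = [], [], []
        val_dice = float(np.mean([
            dice(net.predict_proba(images[i]) >= config.prob_threshold,
                 labels[i] > 0)
            for i in val_idx
        ]))
        log_rows.append({"epoch": epoch, "mean_loss": float(np.mean(losses)),
                         "val_dice": val_dice})

    log = pd.DataFrame(log_rows)
    return SegmentationModel(
        net=net, task=task, prob_threshold=config.prob_threshold,
        config=config, training_log=log,
        val_dice=float(log["val_dice"].iloc[-1]),
        val_scene_indices=val_idx,
    )


def predict(model: SegmentationModel, image,
            threshold: float | None = None):
    """Probability grid and thresholded binary mask for one image."""
    proba = model.net.predict_proba(np.asarray(image, dtype=np.float64))
    thr = model.prob_threshold if threshold is None else threshold
    return proba, proba >= thr


# ---------------------------------------------------------------------------
# checkpoints: one .npz of parameters plus a JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: SegmentationModel, path: str | Path) -> None:
    """Write parameters (.npz) and a JSON sidecar describing them."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    sidecar = {
        "task": model.task,
        "prob_threshold": model.prob_threshold,
        "base_channels": model.net.base_channels,
        "in_channels": model.net.in_channels,
        "val_dice": model.val_dice,
        "config": asdict(model.config) if model.config else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> SegmentationModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = EncoderDecoder(base_channels=sidecar["base_channels"],
                         in_channels=sidecar["in_channels"])
    with np.load(path.with_suffix(".npz")) as state:
        net.load_state_dict(dict(state))
    return SegmentationModel(net=net, task=sidecar["task"],
                             prob_threshold=sidecar["prob_threshold"],
                             val_dice=sidecar.get("val_dice", float("nan")))
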