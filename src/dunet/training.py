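"""L1-loss training loop with paired geometric augmentation.

Training minimises the mean absolute error between the network output and the
clear target on [-1, 1]-normalized pairs, with AdamW (decoupled weight decay
0.01), an initial learning rate of 2e-4 and a cosine decay to 1% of the
initial rate.  Augmentation applies an identical random crop, horizontal flip
(p = 0.5) and rotation from {0, 90, 180, 270} degrees to both images of a
pair, so hazy and clear stay pixel-registered and any pixelwise relation
between them (such as the scattering composite that produced the pair) is
preserved exactly.

The reference schedule (batch 24, 1000 epochs, 256-crops) is far beyond a
single CPU; :data:`DESK_TRAIN` is the scaled-down configuration used by the
tests: 64-pixel crops, batch 4, a few hundred steps on a tiny model.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .haze_synthesis import DatasetManifest, load_image
from .model import DUNet
from .nn.optim import AdamW, cosine_lr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 24
    steps: int = 1000          # optimization steps for this run
    lr: float = 2e-4
    weight_decay: float = 0.01
    lr_final_fraction: float = 0.01   # cosine decay endpoint, as a fraction of lr
    crop: int = 256
    seed: int = 0
    val_interval: int = 50     # steps between validation passes

    def __post_init__(self):
        for name in ("batch_size", "steps", "crop", "val_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


# 200 steps is ~1000x shorter than the reference schedule; the tiny model
# tolerates a proportionally larger learning rate.
DESK_TRAIN = TrainConfig(batch_size=4, steps=200, crop=64, val_interval=50,
                         lr=1e-3)


# ---------------------------------------------------------------------------
# loss and normalization


def l1_loss(pred, target):
    """Mean absolute difference.  Accepts Tensors (differentiable) or arrays."""
    if isinstance(pred, nn.Tensor) or isinstance(target, nn.Tensor):
        pred = pred if isinstance(pred, nn.Tensor) else nn.Tensor(pred)
        target = target if isinstance(target, nn.Tensor) else nn.Tensor(target)
        if pred.shape != target.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
        return (pred - target).abs().mean()
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.abs(pred - target).mean())


def normalize(img: np.ndarray) -> np.ndarray:
    """[0, 1] -> [-1, 1] via x' = 2x - 1."""
    img = np.asarray(img)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("normalize expects values in [0, 1]")
    return 2.0 * img - 1.0


def denormalize(img: np.ndarray) -> np.ndarray:
    """[-1, 1] -> [0, 1]; inverse of :func:`normalize`."""
    return (np.asarray(img) + 1.0) / 2.0


# ---------------------------------------------------------------------------
# augmentation


def augment_pair(hazy: np.ndarray, clear: np.ndarray, rng: np.random.Generator,
                 crop: int) -> tuple[np.ndarray, np.ndarray]:
    """Identical random crop / horizontal flip / 90-degree rotation for a pair.

    Inputs are (H, W, 3) arrays in [0, 1]; outputs are (crop, crop, 3).
    """
    if hazy.shape != clear.shape:
        raise ValueError("pair images must share shape")
    h, w = hazy.shape[:2]
    if h < crop or w < crop:
        raise ValueError(f"images ({h}x{w}) smaller than crop {crop}")
    top = int(rng.integers(0, h - crop + 1))
    left = int(rng.integers(0, w - crop + 1))
    hz = hazy[top:top + crop, left:left + crop]
    cl = clear[top:top + crop, left:left + crop]
    if rng.random() < 0.5:
        hz, cl = hz[:, ::-1], cl[:, ::-1]
    k = int(rng.integers(0, 4))
    if k:
        hz, cl = np.rot90(hz, k), np.rot90(cl, k)
    return np.ascontiguousarray(hz), np.ascontiguousarray(cl)


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    top, left = (h - size) // 2, (w - size) // 2
    return img[top:top + size, left:left + size]


def _to_batch(images: list[np.ndarray]) -> nn.Tensor:
    arr = np.stack([normalize(im) for im in images]).transpose(0, 3, 1, 2)
    return nn.Tensor(arr.astype(nn.DTYPE))


def dehaze_array(model: DUNet, hazy01: np.ndarray) -> np.ndarray:
    """Run the model on one [0, 1] RGB array; reflect-pads to the scale divisor."""
    model.eval()
    div = model.config.divisor
    h, w = hazy01.shape[:2]
    ph, pw = (-h) % div, (-w) % div
    padded = np.pad(hazy01, ((0, ph), (0, pw), (0, 0)), mode="reflect") \
        if (ph or pw) else hazy01
    x = _to_batch([padded])
    out = model(x).data[0].transpose(1, 2, 0)[:h, :w]
    return np.clip(denormalize(out), 0.0, 1.0)


# ---------------------------------------------------------------------------
# the loop


@dataclass
class TrainResult:
    loss_history: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    best_state: dict | None = None
    best_val_psnr: float = -np.inf


def _psnr01(a: np.ndarray, b: np.ndarray) -> float:
    m = float(np.mean((a - b) ** 2))
    return float("inf") if m == 0 else 10.0 * np.log10(1.0 / m)


def train(model: DUNet, manifest: DatasetManifest, cfg: TrainConfig,
          out_dir: str | Path | None = None) -> TrainResult:
    """Seeded AdamW/L1 training on the manifest's train split.

    Validation PSNR is computed on the val split (center-cropped to the crop
    size) every ``val_interval`` steps and the best-scoring weights are kept.
    """
    train_pairs = manifest.paths("train")
    if not train_pairs:
        raise ValueError("manifest has an empty train split")
    val_pairs = manifest.paths("val")
    rng = np.random.default_rng(cfg.seed)

    cache: dict[str, np.ndarray] = {}

    def fetch(path: str) -> np.ndarray:
        if path not in cache:
            cache[path] = load_image(path)
        return cache[path]

    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    result = TrainResult()
    model.train()
    for step in range(cfg.steps):
        opt.lr = cosine_lr(step, cfg.steps, cfg.lr, cfg.lr_final_fraction)
        idx = rng.integers(0, len(train_pairs), size=cfg.batch_size)
        hz_batch, cl_batch = [], []
        for i in idx:
            clear_p, hazy_p = train_pairs[i]
            hz, cl = augment_pair(fetch(hazy_p), fetch(clear_p), rng, cfg.crop)
            hz_batch.append(hz)
            cl_batch.append(cl)
        pred = model(_to_batch(hz_batch))
        loss = l1_loss(pred, _to_batch(cl_batch))
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at step {step}: {loss_val}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        result.loss_history.append(loss_val)
        result.lr_history.append(opt.lr)

        last = step == cfg.steps - 1
        if val_pairs and (step % cfg.val_interval == cfg.val_interval - 1 or last):
            psnr = validate(model, val_pairs, cfg.crop, fetch)
            model.train()
            result.val_steps.append(step + 1)
            result.val_psnr.append(psnr)
            if psnr > result.best_val_psnr:
                result.best_val_psnr = psnr
                result.best_state = model.state_dict()
            logger.info("step %d loss %.4f val_psnr %.2f", step + 1, loss_val, psnr)

    if result.best_state is None:  # no validation split: keep final weights
        result.best_state = model.state_dict()
    model.load_state_dict(result.best_state)
    model.eval()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "train_log.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "loss", "lr"])
            for i, (lo, lr) in enumerate(zip(result.loss_history, result.lr_history)):
                writer.writerow([i + 1, f"{lo:.6f}", f"{lr:.6e}"])
        with open(out_dir / "val_log.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "val_psnr"])
            for s, p in zip(result.val_steps, result.val_psnr):
                writer.writerow([s, f"{p:.4f}"])
    return result


def validate(model: DUNet, pairs: list[tuple[str, str]], crop: int, fetch) -> float:
    """Mean PSNR of model outputs over (clear, hazy) path pairs."""
    model.eval()
    scores = []
    for clear_p, hazy_p in pairs:
        hz = center_crop(fetch(hazy_p), crop)
        cl = center_crop(fetch(clear_p), crop)
        out = dehaze_array(model, hz)
        scores.append(_psnr01(out, cl))
    finite = [s for s in scores if np.isfinite(s)]
    return float(np.mean(finite)) if finite else float("inf")
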