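"""YAML run configuration, validation and the end-to-end smoke pipeline.

A run configuration has four sections — ``synthesis``, ``model``, ``train``
and optional ``eval`` — plus a top-level ``seed`` and ``out_dir``.  The
schema is validated before any file is written and unknown keys are
rejected.  :func:`run_pipeline` executes synth -> train -> dehaze -> eval
with a single seed; every stage's outputs land in the run directory together
with the resolved configuration and its hash, and a failed stage leaves a
``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .evaluation import evaluate_dirs
from .haze_synthesis import (
    DatasetManifest,
    SynthesisParams,
    build_dataset,
    load_image,
    save_image,
)
from .model import ModelConfig, build_dunet, save_checkpoint
from .training import TrainConfig, dehaze_array, train

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "seed": None,
    "out_dir": None,
    "synthesis": {"n_images", "height", "width", "beta", "A", "smoothness"},
    "model": {
        "widths", "depths", "block", "use_dfeu", "mixconv", "dfeu",
        "sk_reduction", "in_channels", "seed",
    },
    "train": {
        "batch_size", "steps", "lr", "weight_decay", "lr_final_fraction",
        "crop", "seed", "val_interval",
    },
    "eval": set(),
}
_REQUIRED = ("synthesis", "model", "train")


def validate_config(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for section in _REQUIRED:
        if section not in raw:
            raise ConfigError(f"missing required section: {section!r}")
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in raw:
            continue
        body = raw[section] or {}
        if not isinstance(body, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(body) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
    # constructing the dataclasses applies their own invariants
    ModelConfig.from_dict(raw["model"])
    TrainConfig(**{k: v for k, v in raw["train"].items()})
    return raw


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# self-contained clear-scene fixtures


def generate_clear_image(height: int, width: int, seed: int) -> np.ndarray:
    """Synthetic clear outdoor scene: smooth color field with row structure.

    Low-frequency per-channel noise (vegetation-like palette) overlaid with a
    faint periodic row pattern; values kept inside [0.05, 0.95] so that haze
    compositing stays in gamut.  Purely a stand-in for real UAV imagery.
    """
    rng = np.random.default_rng(seed)
    sigma = max(min(height, width) / 12.0, 2.0)
    chans = []
    base = (0.30, 0.55, 0.25)  # greenish mean
    for c in range(3):
        noise = gaussian_filter(rng.standard_normal((height, width)), sigma=sigma)
        lo, hi = noise.min(), noise.max()
        span = hi - lo if hi > lo else 1.0
        chans.append(base[c] + 0.5 * ((noise - lo) / span - 0.5))
    img = np.stack(chans, axis=-1)
    rows = 0.06 * np.sin(2 * np.pi * np.arange(height) / max(height / 8, 4))
    img += rows[:, None, None]
    texture = 0.04 * rng.standard_normal((height, width, 3))
    return np.clip(img + texture, 0.05, 0.95)


# ---------------------------------------------------------------------------
# the pipeline


def _log_event(run_dir: Path, stage: str, **payload) -> None:
    with open(run_dir / "pipeline_log.jsonl", "a") as fh:
        fh.write(json.dumps({"t": time.time(), "stage": stage, **payload}) + "\n")


def run_pipeline(config_path: str | Path) -> dict:
    cfg = load_config(config_path)  # raises before any side effect
    digest = config_hash(cfg)
    seed = int(cfg.get("seed", 0))
    run_dir = Path(cfg.get("out_dir", "runs/pipeline"))
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config_hash.txt").write_text(digest + "\n")
    with open(run_dir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    stage = "synth"
    try:
        syn = cfg["synthesis"]
        clear_src = run_dir / "clear_src"
        clear_src.mkdir(exist_ok=True)
        n = int(syn.get("n_images", 10))
        h, w = int(syn.get("height", 96)), int(syn.get("width", 96))
        for i in range(n):
            save_image(generate_clear_image(h, w, seed * 10_000 + i),
                       clear_src / f"scene_{i:03d}.png")
        params = SynthesisParams(
            beta=float(syn.get("beta", 2.0)),
            A=float(syn.get("A", 170 / 255)),
            seed=seed,
            smoothness=float(syn.get("smoothness", 16.0)),
        )
        manifest = build_dataset(clear_src, params, run_dir / "data")
        _log_event(run_dir, stage, counts=manifest.counts(), hash=digest)

        stage = "train"
        model_cfg = ModelConfig.from_dict({**cfg["model"], "seed": seed})
        train_cfg = TrainConfig(**{**cfg["train"], "seed": seed})
        model = build_dunet(model_cfg)
        result = train(model, manifest, train_cfg, out_dir=run_dir)
        ckpt = run_dir / "checkpoint.npz"
        save_checkpoint(model, str(ckpt))
        with np.load(ckpt, allow_pickle=False) as dat:
            state = {k: dat[k] for k in dat.files}
        state["__config_hash__"] = np.frombuffer(digest.encode(), dtype=np.uint8)
        np.savez(ckpt, **state)
        _log_event(run_dir, stage, final_loss=result.loss_history[-1],
                   best_val_psnr=result.best_val_psnr, hash=digest)

        stage = "dehaze"
        pred_dir = run_dir / "pred"
        pred_dir.mkdir(exist_ok=True)
        test_pairs = manifest.paths("test") or manifest.paths("val")
        for clear_p, hazy_p in test_pairs:
            out = dehaze_array(model, load_image(hazy_p))
            save_image(out, pred_dir / Path(hazy_p).name)
        _log_event(run_dir, stage, n_images=len(test_pairs), hash=digest)

        stage = "eval"
        gt_dir = run_dir / "data" / "clear"
        report = evaluate_dirs(pred_dir, gt_dir, run_dir / "report.csv")
        baseline = evaluate_dirs(run_dir / "data" / "hazy", gt_dir,
                                 run_dir / "report_hazy_baseline.csv")
        summary = {
            "config_hash": digest,
            "seed": seed,
            "split_counts": manifest.counts(),
            "mean_psnr_dehazed": report.mean_psnr,
            "mean_ssim_dehazed": report.mean_ssim,
            "mean_psnr_hazy_baseline": baseline.mean_psnr,
            "mean_ssim_hazy_baseline": baseline.mean_ssim,
            "psnr_gain_db": report.mean_psnr - baseline.mean_psnr,
        }
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _log_event(run_dir, stage, **{k: v for k, v in summary.items()
                                      if isinstance(v, (int, float, str))})
        return summary
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
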