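"""Synthetic haze generation via the atmospheric scattering model (ASM).

The ASM relates a clear image J to its hazy observation I through a
transmission map t and a global atmospheric light A::

    I(x) = J(x) * t(x) + A * (1 - t(x)),      t(x) = exp(-beta * d(x))

where beta is the atmospheric scattering coefficient and d is relative scene
depth.  This module provides the forward composite, its algebraic inverse
J = (I - A) / t + A, a seeded generator of smooth synthetic depth fields
(standing in for a monocular depth estimator), and a paired-dataset builder
that writes lossless PNG pairs plus a train/val/test manifest under the
7:1:2 rule.

Images are handled as float arrays in [0, 1]; the conventional 8-bit
atmospheric light A = 170 therefore becomes 170/255.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

DEFAULT_BETA = 2.0
DEFAULT_A = 170.0 / 255.0
SPLIT_RATIOS = (0.7, 0.1, 0.2)
T_MIN = 1e-3


@dataclass(frozen=True)
class SynthesisParams:
    """Scattering coefficient and atmospheric light governing ASM compositing."""

    beta: float = DEFAULT_BETA
    A: float = DEFAULT_A
    seed: int = 0
    smoothness: float = 16.0  # Gaussian sigma (pixels) of the synthetic depth field

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"A must lie in [0, 1] on the normalized scale, got {self.A}")


@dataclass
class ManifestEntry:
    clear_path: str
    hazy_path: str
    split: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def paths(self, split: str) -> list[tuple[str, str]]:
        return [(e.clear_path, e.hazy_path) for e in self.entries if e.split == split]

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "val": 0, "test": 0}
        for e in self.entries:
            out[e.split] += 1
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["clear_path", "hazy_path", "split"])
            for e in self.entries:
                writer.writerow([e.clear_path, e.hazy_path, e.split])

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        manifest = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                manifest.entries.append(
                    ManifestEntry(row["clear_path"], row["hazy_path"], row["split"])
                )
        return manifest


# ---------------------------------------------------------------------------
# core ASM operations


def transmission_from_depth(depth: np.ndarray, beta: float) -> np.ndarray:
    """t = exp(-beta * d), elementwise; strictly positive, 1 where depth is 0."""
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    depth = np.asarray(depth, dtype=np.float64)
    if not np.all(np.isfinite(depth)):
        raise ValueError("depth contains non-finite values")
    if np.any(depth < 0):
        raise ValueError("depth must be nonnegative")
    return np.exp(-beta * depth)


def _broadcast_t(t: np.ndarray, image: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    if t.shape != image.shape[:2]:
        raise ValueError(
            f"transmission shape {t.shape} does not match image spatial shape {image.shape[:2]}"
        )
    return t[..., None] if image.ndim == 3 else t


def apply_asm(clear: np.ndarray, t: np.ndarray, A: float) -> np.ndarray:
    """Composite a hazy image: I = J*t + A*(1 - t)."""
    clear = np.asarray(clear, dtype=np.float64)
    tb = _broadcast_t(t, clear)
    return clear * tb + A * (1.0 - tb)


def invert_asm(hazy: np.ndarray, t: np.ndarray, A: float, t_min: float = T_MIN) -> np.ndarray:
    """Recover the clear image: J = (I - A)/t + A.  Requires t >= t_min > 0."""
    hazy = np.asarray(hazy, dtype=np.float64)
    tb = _broadcast_t(t, hazy)
    if np.any(tb <= 0):
        raise ValueError("transmission must be strictly positive for inversion")
    if np.any(tb < t_min):
        raise ValueError(f"transmission below the inversion floor {t_min}")
    return (hazy - A) / tb + A


def generate_synthetic_depth(height: int, width: int, seed: int,
                             smoothness: float = 16.0) -> np.ndarray:
    """Smooth random relative-depth field, min-max normalized to [0, 1].

    Gaussian-smoothed white noise; ``smoothness`` is the kernel sigma in
    pixels.  Deterministic in (seed, shape, smoothness).
    """
    if height < 8 or width < 8:
        raise ValueError("depth field must be at least 8x8")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    smooth = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:  # pathologically flat draw; keep the contract d in [0,1]
        return np.zeros((height, width))
    return (smooth - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# dataset construction


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_counts(n_total: int, ratios: tuple[float, float, float] = SPLIT_RATIOS
                 ) -> tuple[int, int, int]:
    """Train/val/test counts under the 7:1:2 rule.

    train = round(0.7 N) and test = round(0.2 N) with round-half-up;
    validation takes the remainder, so the counts always sum to N
    (1978 -> 1385/197/396).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    if n_total < 3:
        raise ValueError("need at least 3 items to split")
    n_train = _round_half_up(ratios[0] * n_total)
    n_test = _round_half_up(ratios[2] * n_total)
    n_val = n_total - n_train - n_test
    if n_val < 0:
        raise ValueError("degenerate split")
    return n_train, n_val, n_test


def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB image to float64 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_image(array: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float array losslessly as 8-bit PNG."""
    q = np.clip(np.round(np.asarray(array) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q).save(path)


def load_depth(path: str | Path) -> np.ndarray:
    """Read a relative depth map from single-channel PNG or NPY, rescaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path).astype(np.float64)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    return np.zeros_like(arr) if hi - lo < 1e-12 else (arr - lo) / (hi - lo)


def build_dataset(clear_dir: str | Path, params: SynthesisParams,
                  out_dir: str | Path, depth_dir: str | Path | None = None
                  ) -> DatasetManifest:
    """Composite a paired hazy/clear dataset and write its manifest.

    For every readable RGB image in ``clear_dir`` a depth field is obtained
    (matching file in ``depth_dir`` if given, otherwise a seeded synthetic
    field), converted to transmission with the configured beta, and the ASM
    composite is written as lossless PNG.  Split assignment is a seeded
    shuffle followed by the 7:1:2 rule.  beta is capped at 4 with unit depth,
    so transmission never falls below exp(-4) and the pairs stay invertible.
    """
    clear_dir, out_dir = Path(clear_dir), Path(out_dir)
    if params.beta > 4.0:
        raise ValueError("dataset builder requires beta <= 4 to keep t >= exp(-4)")
    hazy_dir = out_dir / "hazy"
    clear_out = out_dir / "clear"
    depth_out = out_dir / "depth"
    for d in (hazy_dir, clear_out, depth_out):
        d.mkdir(parents=True, exist_ok=True)

    files = sorted(
        p for p in clear_dir.iterdir()
        if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    records = []
    for i, path in enumerate(files):
        try:
            clear = load_image(path)
        except OSError as exc:
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        h, w = clear.shape[:2]
        if depth_dir is not None:
            cand = [Path(depth_dir) / f"{path.stem}{ext}" for ext in (".npy", ".png")]
            found = next((c for c in cand if c.exists()), None)
            depth = load_depth(found) if found is not None else None
        else:
            depth = None
        if depth is None:
            depth = generate_synthetic_depth(h, w, seed=params.seed + i,
                                             smoothness=params.smoothness)
        t = transmission_from_depth(depth, params.beta)
        hazy = apply_asm(clear, t, params.A)
        name = f"{path.stem}.png"
        save_image(clear, clear_out / name)
        save_image(hazy, hazy_dir / name)
        np.save(depth_out / f"{path.stem}.npy", depth.astype(np.float32))
        records.append((str(clear_out / name), str(hazy_dir / name)))

    if not records:
        raise RuntimeError(f"no usable clear images found in {clear_dir}")

    n_train, n_val, n_test = split_counts(len(records))
    order = np.random.default_rng(params.seed).permutation(len(records))
    labels = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            labels[idx] = "train"
        elif rank < n_train + n_val:
            labels[idx] = "val"
        else:
            labels[idx] = "test"
    manifest = DatasetManifest(
        [ManifestEntry(c, hz, labels[i]) for i, (c, hz) in enumerate(records)]
    )
    manifest.save(out_dir / "manifest.csv")
    return manifest
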