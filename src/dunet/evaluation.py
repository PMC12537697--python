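"""Full-reference image quality metrics and batch evaluation reports.

PSNR is computed from the mean squared error over all pixels and channels,
``10 * log10(max_value^2 / MSE)``; identical images yield an infinite-PSNR
sentinel which is excluded from dataset means and counted separately.  SSIM
follows the standard local-statistics formulation

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
           ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),

with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, an 11x11 Gaussian
window (sigma 1.5) and population covariances, averaged over windows, then
over channels.  Both metrics are evaluated on RGB arrays in [0, 1]
(max_value = L = 1); they are invariant to evaluating on 0-255 instead.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .haze_synthesis import load_image

logger = logging.getLogger(__name__)


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / err)


def ssim(a: np.ndarray, b: np.ndarray, L: float = 1.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with the Gaussian 11x11 window, sigma 1.5."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if L <= 0:
        raise ValueError("L must be positive")
    if min(a.shape[0], a.shape[1]) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    kwargs = dict(
        data_range=L, K1=k1, K2=k2,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
    )
    if a.ndim == 3:
        kwargs["channel_axis"] = -1
    return float(structural_similarity(a, b, **kwargs))


@dataclass
class MetricReport:
    rows: list[tuple[str, float, float]] = field(default_factory=list)  # name, psnr, ssim
    n_infinite_psnr: int = 0
    skipped: list[str] = field(default_factory=list)

    @property
    def mean_psnr(self) -> float:
        finite = [p for _, p, _ in self.rows if math.isfinite(p)]
        return float(np.mean(finite)) if finite else math.inf

    @property
    def mean_ssim(self) -> float:
        return float(np.mean([s for _, _, s in self.rows])) if self.rows else math.nan

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "psnr_db", "ssim"])
            for name, p, s in self.rows:
                writer.writerow([name, "inf" if math.isinf(p) else f"{p:.4f}", f"{s:.6f}"])
            writer.writerow(["mean", f"{self.mean_psnr:.4f}", f"{self.mean_ssim:.6f}"])


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    return psnr(pred, gt, max_value=1.0), ssim(pred, gt, L=1.0)


def evaluate_dirs(pred_dir: str | Path, gt_dir: str | Path,
                  report_path: str | Path | None = None) -> MetricReport:
    """Per-image and mean PSNR/SSIM over matching filenames in two directories."""
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    exts = {".png", ".jpg", ".jpeg"}
    preds = {p.name: p for p in pred_dir.iterdir() if p.suffix.lower() in exts}
    gts = {p.name: p for p in gt_dir.iterdir() if p.suffix.lower() in exts}
    report = MetricReport()
    for name in sorted(set(preds) | set(gts)):
        if name not in preds or name not in gts:
            logger.warning("unmatched file %s; skipping", name)
            report.skipped.append(name)
            continue
        p, s = evaluate_pair(load_image(preds[name]), load_image(gts[name]))
        if math.isinf(p):
            report.n_infinite_psnr += 1
        report.rows.append((name, p, s))
    if not report.rows:
        raise RuntimeError("no matching image pairs to evaluate")
    if report_path is not None:
        report.save(report_path)
    return report
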