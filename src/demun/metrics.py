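"""Reconstruction-quality metrics and summary tables.

PSNR uses peak 1.0 (images normalized to [0, 1]) and caps perfect
reconstructions at 100 dB instead of returning infinity.  SSIM follows the
field-standard constants (Gaussian window sigma 1.5, 11x11 support,
K1 = 0.01, K2 = 0.03, data range 1.0); it is implemented here directly and
cross-checked against scikit-image in the tests.  Summary tables reduce
per-image metrics to mean +/- sample standard deviation (ddof = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, ShapeError

__all__ = ["EvalRecord", "psnr", "ssim", "per_step_psnr", "summarize"]

PSNR_CAP_DB = 100.0


@dataclass
class EvalRecord:
    """Per-image evaluation: PSNR, SSIM, and the per-step PSNR trajectory."""

    psnr: float
    ssim: float
    step_psnr: np.ndarray = field(default_factory=lambda: np.array([]))
    config_hash: str = ""


def psnr(x_hat: np.ndarray, x_star: np.ndarray, peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE); capped at 100 dB (returned for MSE = 0)."""
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x_star = np.asarray(x_star, dtype=np.float64)
    if x_hat.shape != x_star.shape:
        raise ShapeError("reconstruction", x_star.shape, x_hat.shape)
    if peak <= 0:
        raise ConfigurationError(f"peak must be > 0, got {peak}")
    mse = float(np.mean((x_hat - x_star) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(PSNR_CAP_DB, 10.0 * np.log10(peak**2 / mse)))


def _ssim_filter(img: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return gaussian_filter(img, sigma=sigma, truncate=truncate, mode="nearest")


def ssim(x_hat: np.ndarray, x_star: np.ndarray, data_range: float = 1.0,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity with an 11x11 Gaussian window."""
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x_star = np.asarray(x_star, dtype=np.float64)
    if x_hat.shape != x_star.shape:
        raise ShapeError("reconstruction", x_star.shape, x_hat.shape)
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)   # 5 -> 11x11 window
    win = 2 * radius + 1
    if min(x_hat.shape) < win:
        raise ConfigurationError(
            f"image sides {x_hat.shape} smaller than the {win}x{win} SSIM window"
        )
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    ux = _ssim_filter(x_hat, sigma, truncate)
    uy = _ssim_filter(x_star, sigma, truncate)
    uxx = _ssim_filter(x_hat * x_hat, sigma, truncate)
    uyy = _ssim_filter(x_star * x_star, sigma, truncate)
    uxy = _ssim_filter(x_hat * x_star, sigma, truncate)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    # exclude the filter's boundary-padded ring from the average
    return float(s[radius:-radius, radius:-radius].mean())


def per_step_psnr(trace, x_star: np.ndarray, peak: float = 1.0) -> np.ndarray:
    """PSNR of every intermediate estimate x_i against the ground truth."""
    xs = trace.xs if hasattr(trace, "xs") else list(trace)
    return np.array([psnr(x, x_star, peak=peak) for x in xs])


def summarize(records: pd.DataFrame, value_cols=("psnr", "ssim"),
              by=("sampling_rate", "config")) -> pd.DataFrame:
    """Mean +/- sample std (ddof = 1) per cell; cells with < 2 records are
    dropped with a warning.

    ``records`` holds one row per evaluated image with the metric columns
    and the grouping keys.
    """
    by = [b for b in by if b in records.columns]
    value_cols = [c for c in value_cols if c in records.columns]
    if not by:
        raise ConfigurationError("no grouping columns present in records")
    rows = []
    for key, group in records.groupby(list(by), sort=True):
        if len(group) < 2:
            warnings.warn(f"cell {key}: fewer than 2 records, omitted", stacklevel=2)
            continue
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(group)
        for c in value_cols:
            row[f"{c}_mean"] = float(group[c].mean())
            row[f"{c}_std"] = float(group[c].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
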