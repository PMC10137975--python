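"""Image-quality and overlap metrics: MSE, PSNR, SSIM, Dice.

All image metrics operate on gray images in [0, 1] of equal shape; Dice
operates on boolean masks.  PSNR may return ``inf`` for identical images;
every other value is finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image_core import validate_gray_image

__all__ = ["QualityReport", "mse", "psnr", "ssim", "dice", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    """Bundle of the four metrics for one reference/test image pair."""

    ssim: float
    mse: float
    psnr: float
    dice: float | None = None


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = validate_gray_image(a)
    b = validate_gray_image(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error, (1/mn) * sum (a - b)^2, in squared intensity units."""
    a, b = _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, bit_depth: int = 8) -> float:
    """Peak signal-to-noise ratio in dB at the given bit depth.

    Intensities are rescaled to [0, 2^n - 1] and
    PSNR = 20 * log10((2^n - 1) / sqrt(MSE_scaled)).  Identical images give
    the +inf sentinel.
    """
    if bit_depth < 1:
        raise ValueError(f"bit depth must be >= 1, got {bit_depth}")
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    peak = 2 ** bit_depth - 1
    mse_scaled = err * peak * peak
    return float(20.0 * math.log10(peak / math.sqrt(mse_scaled)))


def ssim(a: np.ndarray, b: np.ndarray, window: int = 8,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity over all dense ``window x window`` patches.

    Per window, with local means mu, variances sigma^2 and covariance
    sigma_xy (population form), and C1 = (k1 L)^2, C2 = (k2 L)^2 for
    dynamic range L = 1:

        SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
               / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

    The global score is the mean over every valid window position.
    ``ssim(x, x) == 1`` for any image.
    """
    a, b = _check_pair(a, b)
    if window < 1 or window > min(a.shape):
        raise ValueError(
            f"window {window} must be in [1, {min(a.shape)}] for shape {a.shape}")
    c1 = (k1 * 1.0) ** 2
    c2 = (k2 * 1.0) ** 2

    wa = sliding_window_view(a, (window, window))
    wb = sliding_window_view(b, (window, window))
    mu_a = wa.mean(axis=(2, 3))
    mu_b = wb.mean(axis=(2, 3))
    var_a = (wa ** 2).mean(axis=(2, 3)) - mu_a ** 2
    var_b = (wb ** 2).mean(axis=(2, 3)) - mu_b ** 2
    cov = (wa * wb).mean(axis=(2, 3)) - mu_a * mu_b

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A and B| / (|A| + |B|) between two boolean masks.

    Ranges from 0 (disjoint) to 1 (identical).  Two empty masks agree
    perfectly on absence and return 1.0 (with a warning).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        warnings.warn("dice: both masks empty, returning 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def quality_report(reference: np.ndarray, test: np.ndarray,
                   mask_reference: np.ndarray | None = None,
                   mask_test: np.ndarray | None = None,
                   bit_depth: int = 8) -> QualityReport:
    """Compute all metrics for a reference/test pair (Dice if masks given)."""
    d = None
    if mask_reference is not None and mask_test is not None:
        d = dice(mask_reference, mask_test)
    return QualityReport(ssim=ssim(reference, test),
                         mse=mse(reference, test),
                         psnr=psnr(reference, test, bit_depth),
                         dice=d)
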