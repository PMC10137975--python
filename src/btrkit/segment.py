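"""Tumor localization on the filtered image.

The localization chain is: global brightness threshold (Otsu by default,
computed inside the head region only) -> morphological opening/closing with
a disk structuring element -> largest connected component -> bounding box,
centroid and boundary overlay on the original image.

A contrast gate rejects candidate regions that are not meaningfully
brighter than the remaining head tissue, so a slice without a tumor yields
an empty mask instead of a spurious half-of-the-head region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .image_core import validate_gray_image

__all__ = [
    "SegmentationConfig",
    "TumorResult",
    "threshold_brightness",
    "morphological_cleanup",
    "largest_component",
    "localize_tumor",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the localization chain.

    method : 'otsu' (data-driven global threshold) or 'fixed'.
    fixed_t : threshold in [0, 1]; required when method is 'fixed'.
    se_radius : radius in pixels of the disk structuring element.
    connectivity : 4 or 8, for connected-component labeling.
    head_floor : intensity above which a pixel counts as head tissue;
        the Otsu histogram and the contrast gate are restricted to it.
    head_erosion : radius in pixels by which the head region is eroded
        before the threshold histogram is taken.  Diffusion smears the
        head/background boundary into a ring of intermediate intensities
        that would otherwise dominate the histogram; eroding the head
        drops that partial-volume ring.
    min_contrast : minimum brightness excess of the candidate region over
        the rest of the head; below it the slice is declared tumor-free.
    min_zscore : minimum excess of the candidate mean over the interior
        median, in units of the interior standard deviation.  An Otsu
        split of pure tissue texture lands around 1 interior-sd above the
        median regardless of how the intensities were stretched, while a
        genuine hyperintense lesion sits several sd higher, so this
        scale-free gate rejects texture-only splits.
    """

    method: str = "otsu"
    fixed_t: float | None = None
    se_radius: int = 2
    connectivity: int = 8
    head_floor: float = 0.05
    head_erosion: int = 4
    min_contrast: float = 0.1
    min_zscore: float = 2.0

    def __post_init__(self):
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed":
            if self.fixed_t is None:
                raise ValueError("method 'fixed' requires a threshold value")
            if not (0.0 <= self.fixed_t <= 1.0):
                raise ValueError(f"fixed threshold must be in [0, 1], "
                                 f"got {self.fixed_t}")
        if self.se_radius < 1:
            raise ValueError(f"se_radius must be >= 1, got {self.se_radius}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, "
                             f"got {self.connectivity}")
        if self.head_erosion < 0:
            raise ValueError(f"head_erosion must be >= 0, "
                             f"got {self.head_erosion}")


@dataclass
class TumorResult:
    """Localization outcome for one slice.

    ``bbox`` is ``(row0, col0, row1, col1)``, 0-based half-open, tightly
    bounding the mask; ``centroid`` is the fractional-pixel mask centroid.
    An empty mask carries area 0 and ``None`` sentinels for bbox/centroid.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int] | None
    centroid: tuple[float, float] | None
    area: int
    overlay: np.ndarray


def threshold_brightness(img: np.ndarray, method: str = "otsu",
                         t: float | None = None,
                         head_floor: float = 0.05,
                         region: np.ndarray | None = None) -> np.ndarray:
    """Binary mask of pixels strictly brighter than a global threshold.

    For ``method='otsu'`` the threshold maximizes between-class variance of
    a 256-bin histogram restricted to head pixels — those inside ``region``
    if given, else those with intensity above ``head_floor`` — which keeps
    the large dark background from skewing the split.  For
    ``method='fixed'`` the caller supplies ``t`` in [0, 1].
    """
    img = validate_gray_image(img)
    if method == "fixed":
        if t is None:
            raise ValueError("fixed thresholding requires a threshold value")
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"threshold must be in [0, 1], got {t}")
        return img > t
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    head = img[np.asarray(region, dtype=bool)] if region is not None \
        else img[img > head_floor]
    if head.size == 0 or head.min() == head.max():
        return np.zeros_like(img, dtype=bool)
    t = threshold_otsu(head, nbins=256)
    return img > t


def morphological_cleanup(mask: np.ndarray, se_radius: int = 2) -> np.ndarray:
    """Binary opening then closing with a disk structuring element.

    Opening removes specks smaller than the element; closing fills
    comparable holes and gulfs in what remains.
    """
    if se_radius < 1:
        raise ValueError(f"se_radius must be >= 1, got {se_radius}")
    mask = np.asarray(mask, dtype=bool)
    se = morphology.disk(se_radius)
    return morphology.closing(morphology.opening(mask, se), se).astype(bool)


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Retain only the connected component with the most pixels.

    Ties go to the component whose first pixel comes earliest in row-major
    scan order.  An empty mask passes through unchanged.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    # labels are assigned in scan order, so argmax's first-max rule realizes
    # the scan-order tie-break
    return labels == int(np.argmax(counts))


def _overlay_boundary(original: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Burn the mask boundary into the original image at intensity 1."""
    overlay = original.copy()
    if mask.any():
        boundary = mask & ~morphology.erosion(mask, morphology.disk(1))
        overlay[boundary] = 1.0
    return overlay


def localize_tumor(filtered: np.ndarray, original: np.ndarray,
                   cfg: SegmentationConfig = SegmentationConfig()
                   ) -> TumorResult:
    """Full localization chain on a denoised slice.

    Thresholds the filtered image inside the eroded head region, cleans
    the mask morphologically, keeps the largest component, and applies the
    contrast gates: the candidate is accepted only if its mean filtered
    intensity exceeds that of the rest of the head interior by at least
    ``cfg.min_contrast`` and sits at least ``cfg.min_zscore`` interior
    standard deviations above the interior median.  The accepted boundary
    is drawn onto the original image.
    """
    filtered = validate_gray_image(filtered)
    original = validate_gray_image(original)
    if filtered.shape != original.shape:
        raise ValueError(f"image shapes differ: {filtered.shape} vs "
                         f"{original.shape}")

    interior = filtered > cfg.head_floor
    if cfg.head_erosion > 0:
        interior = morphology.erosion(
            interior, morphology.disk(cfg.head_erosion)).astype(bool)
    if cfg.method == "otsu" and interior.any():
        raw = threshold_brightness(filtered, "otsu",
                                   region=interior) & interior
    else:
        raw = threshold_brightness(filtered, cfg.method, cfg.fixed_t,
                                   cfg.head_floor)
    cleaned = morphological_cleanup(raw, cfg.se_radius)
    candidate = largest_component(cleaned, cfg.connectivity)

    if candidate.any():
        rest = interior & ~candidate
        cand_mean = float(filtered[candidate].mean())
        rest_mean = float(filtered[rest].mean()) if rest.any() else 0.0
        interior_sd = float(filtered[interior].std()) if interior.any() \
            else 0.0
        z = np.inf if interior_sd == 0.0 else \
            (cand_mean - float(np.median(filtered[interior]))) / interior_sd
        if cand_mean - rest_mean < cfg.min_contrast or z < cfg.min_zscore:
            candidate = np.zeros_like(candidate)

    if candidate.any():
        rows, cols = np.nonzero(candidate)
        bbox = (int(rows.min()), int(cols.min()),
                int(rows.max()) + 1, int(cols.max()) + 1)
        centroid = (float(rows.mean()), float(cols.mean()))
        area = int(candidate.sum())
    else:
        bbox = None
        centroid = None
        area = 0
    return TumorResult(mask=candidate, bbox=bbox, centroid=centroid,
                       area=area,
                       overlay=_overlay_boundary(original, candidate))
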