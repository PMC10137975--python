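"""Seeded synthetic brain-phantom generator.

Each phantom emulates a single axial T1/T2-like slice: a dark background,
an elliptical "head" of smoothly textured tissue, and (for the abnormal
class) a compact hyperintense "tumor" disk with a soft rim, plus additive
Gaussian acquisition noise.  Every phantom carries its exact ground-truth
tumor mask, so the denoising, segmentation and classification stages can be
scored without any external MRI data.

The generator is fully determined by its seed.  Dataset generation draws
each image from an independent substream keyed by ``(seed, index)``, so a
dataset is stable under changes of its size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "PhantomDataset", "generate_phantom",
           "generate_dataset"]

#: Width in pixels of the soft rim outside the nominal tumor radius.
SOFT_EDGE = 2.0
#: Smoothing radius (pixels) of the interior texture field.
TEXTURE_SMOOTHING = 3.0
#: Intensity of the dark background outside the head.
BACKGROUND_DARK = 0.02

#: Per-image jitter ranges used by :func:`generate_dataset`.
TUMOR_RADIUS_RANGE = (9.0, 14.0)
TUMOR_DELTA_RANGE = (0.25, 0.35)
#: Tumor centers are drawn uniformly inside the head ellipse shrunk by this
#: factor, keeping the full soft rim inside the head.
CENTER_FRACTION = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic slice.

    size : image dimensions (rows, cols).
    head_axes : semi-axes (rows, cols) of the head ellipse, centered in the
        image.
    background_level : tissue intensity inside the head.
    texture_sigma : amplitude of the smoothed interior texture field.
    tumor : whether a tumor disk is present (the abnormal class).
    tumor_center : (row, col); defaults to an off-center location.
    tumor_radius : nominal disk radius in pixels (the ground-truth mask).
    tumor_delta : intensity increment of the tumor over the tissue level.
    noise_sigma : standard deviation of the additive Gaussian noise.
    seed : RNG seed; identical specs produce bitwise-identical phantoms.
    """

    size: tuple[int, int] = (128, 128)
    head_axes: tuple[float, float] = (50.0, 44.0)
    background_level: float = 0.35
    texture_sigma: float = 0.04
    tumor: bool = True
    tumor_center: tuple[float, float] | None = None
    tumor_radius: float = 12.0
    tumor_delta: float = 0.3
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        m, n = self.size
        if m < 8 or n < 8:
            raise ValueError(f"phantom size too small: {self.size}")
        if not (0.0 < self.background_level + self.tumor_delta <= 1.0):
            raise ValueError("background + tumor delta must lie in (0, 1]")
        if self.noise_sigma < 0 or self.texture_sigma < 0:
            raise ValueError("noise/texture sigma must be >= 0")
        if self.tumor:
            cr, cc = self.resolved_center()
            a, b = self.head_axes
            reach = self.tumor_radius + SOFT_EDGE
            ar, br = a - reach, b - reach
            if ar <= 0 or br <= 0:
                raise ValueError("tumor too large for the head ellipse")
            d = (((cr - m / 2) / ar) ** 2 + ((cc - n / 2) / br) ** 2)
            if d > 1.0:
                raise ValueError(
                    f"tumor at {(cr, cc)} (radius {self.tumor_radius}) "
                    "extends outside the head ellipse")

    def resolved_center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        m, n = self.size
        return (0.42 * m, 0.58 * n)


@dataclass
class PhantomDataset:
    """Images with ground-truth masks, binary labels and their specs.

    ``specs`` allows noise-free clean references to be re-rendered for any
    image (same spec with ``noise_sigma=0``).
    """

    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray
    ids: Sequence[str] = field(default_factory=tuple)
    specs: Sequence[PhantomSpec] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.images)

    def clean_image(self, index: int) -> np.ndarray:
        """Noise-free rendering of image ``index`` (same geometry/texture)."""
        img, _, _ = generate_phantom(replace(self.specs[index],
                                             noise_sigma=0.0))
        return img


def _head_ellipse(spec: PhantomSpec) -> np.ndarray:
    m, n = spec.size
    a, b = spec.head_axes
    rr, cc = np.mgrid[0:m, 0:n]
    return ((rr - m / 2) / a) ** 2 + ((cc - n / 2) / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Render one phantom: ``(image, ground_truth_mask, label)``.

    The head ellipse sits at ``background_level`` plus a Gaussian-smoothed
    texture field; the tumor (if any) raises a disk by ``tumor_delta`` with
    a 2-pixel soft rim outside the nominal radius; Gaussian noise is added
    everywhere and the result clipped into [0, 1].  The mask is the hard
    disk of ``tumor_radius``; label is 1 iff a tumor is present.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.size
    head = _head_ellipse(spec)

    img = np.full((m, n), BACKGROUND_DARK)
    img[head] = spec.background_level

    if spec.texture_sigma > 0:
        raw = rng.standard_normal((m, n))
        texture = gaussian_filter(raw, TEXTURE_SMOOTHING)
        sd = texture.std()
        if sd > 0:
            texture *= spec.texture_sigma / sd
        img[head] += texture[head]

    mask = np.zeros((m, n), dtype=bool)
    if spec.tumor:
        cr, cc = spec.resolved_center()
        rr, col = np.mgrid[0:m, 0:n]
        dist = np.hypot(rr - cr, col - cc)
        mask = dist <= spec.tumor_radius
        # unit plateau inside the radius, linear ramp to 0 over the soft rim
        w = np.clip((spec.tumor_radius + SOFT_EDGE - dist) / SOFT_EDGE,
                    0.0, 1.0)
        img += spec.tumor_delta * w

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, (m, n))

    return np.clip(img, 0.0, 1.0), mask, int(spec.tumor)


def _jittered_spec(base: PhantomSpec, tumor: bool, seed: int,
                   index: int) -> PhantomSpec:
    """Draw per-image tumor geometry from the (seed, index) substream."""
    rng = np.random.default_rng([seed, index])
    sub_seed = int(rng.integers(0, 2 ** 31))
    if not tumor:
        return replace(base, tumor=False, seed=sub_seed)
    radius = rng.uniform(*TUMOR_RADIUS_RANGE)
    delta = rng.uniform(*TUMOR_DELTA_RANGE)
    m, n = base.size
    a, b = base.head_axes
    while True:  # uniform over the shrunken ellipse by rejection
        u = rng.uniform(-1.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        if u * u + v * v <= 1.0:
            break
    center = (m / 2 + u * a * CENTER_FRACTION,
              n / 2 + v * b * CENTER_FRACTION)
    return replace(base, tumor=True, tumor_center=center,
                   tumor_radius=radius, tumor_delta=delta, seed=sub_seed)


def generate_dataset(n_abnormal: int, n_normal: int,
                     base_spec: PhantomSpec | None = None,
                     seed: int = 0) -> PhantomDataset:
    """Generate a labeled phantom cohort (abnormal slices first).

    Tumor center, radius and intensity increment are jittered per image
    within the module-level ranges; everything is reproducible from ``seed``
    and independent of the cohort size.
    """
    if n_abnormal < 0 or n_normal < 0 or n_abnormal + n_normal < 2:
        raise ValueError("need at least 2 images in total")
    base = base_spec if base_spec is not None else PhantomSpec()
    images, masks, labels, ids, specs = [], [], [], [], []
    for index in range(n_abnormal + n_normal):
        tumor = index < n_abnormal
        spec = _jittered_spec(base, tumor, seed, index)
        img, mask, label = generate_phantom(spec)
        images.append(img)
        masks.append(mask)
        labels.append(label)
        ids.append(f"phantom_{index:04d}")
        specs.append(spec)
    return PhantomDataset(images=images, masks=masks,
                          labels=np.asarray(labels, dtype=np.int64),
                          ids=tuple(ids), specs=tuple(specs))
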