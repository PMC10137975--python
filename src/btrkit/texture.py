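"""Statistical texture features: first-order moments, GLCM features, coarseness.

The feature set combines

* five first-order statistics of the intensity distribution — mean,
  standard deviation, histogram entropy, skewness, kurtosis;
* five second-order (Haralick-style) features of the gray-level
  co-occurrence matrix (GLCM) — energy (angular second moment), contrast,
  inverse difference moment, directional moment, correlation;
* a coarseness summary of texture granularity.

Together they form the fixed-order 11-element vector consumed by the
tumor/no-tumor classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .image_core import quantize, validate_gray_image

__all__ = [
    "FEATURE_NAMES",
    "GLCMConfig",
    "GLCM",
    "FeatureVector",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "coarseness",
    "feature_vector",
]

#: Fixed ordering of the feature vector (column names of the feature CSV).
FEATURE_NAMES = (
    "mean", "sd", "entropy", "skewness", "kurtosis",
    "energy", "contrast", "idm", "dm", "correlation", "coarseness",
)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Construction parameters for gray-level co-occurrence matrices.

    levels : number of quantized gray levels L (matrix is L x L).
    offsets : pixel displacements (drow, dcol) defining the co-occurring
        neighbor; the default is the 4 canonical directions at distance 1.
    symmetric : count each pair in both orders, yielding a symmetric matrix.
    normalize : divide counts by the total pair count so entries sum to 1.
    """

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        offs = tuple(tuple(o) for o in self.offsets)
        if any(o == (0, 0) for o in offs):
            raise ValueError("offset (0, 0) is not a valid displacement")
        if not offs:
            raise ValueError("at least one offset is required")
        object.__setattr__(self, "offsets", offs)


@dataclass
class GLCM:
    """A co-occurrence matrix for one offset (or an average over offsets)."""

    matrix: np.ndarray
    config: GLCMConfig
    pair_count: int


class Coarseness(NamedTuple):
    """Literal coarseness value and its log2 (safe against underflow)."""

    value: float
    log2_value: float


@dataclass(frozen=True)
class FeatureVector:
    """The 11 texture statistics in fixed order (see :data:`FEATURE_NAMES`)."""

    mean: float
    sd: float
    entropy: float
    skewness: float
    kurtosis: float
    energy: float
    contrast: float
    idm: float
    dm: float
    correlation: float
    coarseness: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def first_order_features(img: np.ndarray, L: int = 8):
    """Mean, population standard deviation, L-bin histogram entropy (bits),
    skewness and (raw, non-excess) kurtosis of the intensity distribution.

    Skewness and kurtosis are the standardized central moments; on a
    constant image (sigma = 0) both return 0 by convention, as does the
    entropy (a single occupied bin).
    """
    img = validate_gray_image(img)
    flat = img.ravel()
    mean = float(flat.mean())
    var = float(((flat - mean) ** 2).mean())
    sd = float(np.sqrt(var))

    counts = np.bincount(quantize(img, L).ravel(), minlength=L)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    if sd == 0.0:
        skew = kurt = 0.0
    else:
        z = (flat - mean) / sd
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean())
    return mean, sd, entropy, skew, kurt


def compute_glcm(qimg: np.ndarray, config: GLCMConfig = GLCMConfig()) -> GLCM:
    """Build the co-occurrence matrix of a quantized image.

    For every offset ``(dr, dc)`` the ordered gray-level pairs
    ``(v[r, c], v[r + dr, c + dc])`` over all in-bounds positions are
    counted; symmetric mode adds the transposed counts, and normalization
    divides by the total pair count.
    """
    q = np.asarray(qimg)
    if not np.issubdtype(q.dtype, np.integer):
        raise ValueError("quantized image must have an integer dtype")
    L = config.levels
    if q.min() < 0 or q.max() >= L:
        raise ValueError(f"quantized values must lie in [0, {L - 1}]")
    m, n = q.shape
    mat = np.zeros((L, L), dtype=np.float64)
    total = 0
    for dr, dc in config.offsets:
        if abs(dr) >= m or abs(dc) >= n:
            raise ValueError(
                f"offset {(dr, dc)} reaches outside a {m}x{n} image "
                "(no valid pairs)")
        r0, r1 = max(0, -dr), min(m, m - dr)
        c0, c1 = max(0, -dc), min(n, n - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L)
        mat += counts
        total += a.size
        if config.symmetric:
            mat += counts.T
            total += a.size
    if config.normalize:
        mat = mat / total
    return GLCM(matrix=mat, config=config, pair_count=total)


def glcm_features(g: GLCM):
    """Energy, contrast, inverse difference moment, directional moment and
    correlation of a normalized GLCM.

    With ``p(x, y)`` the normalized co-occurrence probability and ``x, y``
    the gray levels:

        energy      = sum p^2                 (angular second moment)
        contrast    = sum (x - y)^2 p
        idm         = sum p / (1 + (x - y)^2) (homogeneity)
        dm          = sum |x - y| p
        correlation = sum (x - Mx)(y - My) p / (sigma_x sigma_y)

    where Mx, My, sigma_x, sigma_y are the marginal means and standard
    deviations.  Correlation returns 0 by convention when a marginal is
    degenerate (sigma_x * sigma_y = 0).
    """
    p = np.asarray(g.matrix, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("glcm_features requires a normalized GLCM "
                         "(entries summing to 1)")
    L = p.shape[0]
    x = np.arange(L)[:, None]
    y = np.arange(L)[None, :]
    d = x - y

    energy = float((p ** 2).sum())
    contrast = float((d ** 2 * p).sum())
    idm = float((p / (1.0 + d ** 2)).sum())
    dm = float((np.abs(d) * p).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(L, dtype=np.float64)
    mx, my = float(px @ lv), float(py @ lv)
    sx = float(np.sqrt(px @ (lv - mx) ** 2))
    sy = float(np.sqrt(py @ (lv - my) ** 2))
    if sx * sy == 0.0:
        corr = 0.0
    else:
        corr = float(((x - mx) * (y - my) * p).sum() / (sx * sy))
    return energy, contrast, idm, dm, corr


def coarseness(img: np.ndarray) -> Coarseness:
    """Texture coarseness, Cness = 2^-(m+n) * sum f(x, y).

    The prefactor shrinks double-exponentially with image size, so the
    literal value is vanishingly small at realistic resolutions; the log2
    form ``log2(sum f) - (m + n)`` is returned alongside and stays finite
    whenever the image is not all-zero.
    """
    img = validate_gray_image(img)
    m, n = img.shape
    s = float(img.sum())
    if s == 0.0:
        return Coarseness(0.0, float("-inf"))
    log2v = float(np.log2(s)) - (m + n)
    return Coarseness(float(2.0 ** log2v), log2v)


def feature_vector(img: np.ndarray,
                   config: GLCMConfig = GLCMConfig()) -> FeatureVector:
    """Assemble the full 11-feature vector for one image.

    The image is quantized to ``config.levels`` gray levels; one normalized
    GLCM per offset is computed and the matrices are averaged before the
    second-order features are read off.  Deterministic.
    """
    img = validate_gray_image(img)
    mean, sd, entropy, skew, kurt = first_order_features(img, config.levels)

    cfg_norm = GLCMConfig(levels=config.levels, offsets=config.offsets,
                          symmetric=config.symmetric, normalize=True)
    mats = [
        compute_glcm(quantize(img, config.levels),
                     GLCMConfig(levels=config.levels, offsets=(off,),
                                symmetric=config.symmetric,
                                normalize=True)).matrix
        for off in cfg_norm.offsets
    ]
    avg = GLCM(matrix=np.mean(mats, axis=0), config=cfg_norm, pair_count=0)
    energy, contrast, idm, dm, corr = glcm_features(avg)

    return FeatureVector(mean=mean, sd=sd, entropy=entropy, skewness=skew,
                         kurtosis=kurt, energy=energy, contrast=contrast,
                         idm=idm, dm=dm, correlation=corr,
                         coarseness=coarseness(img).value)
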