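"""Image loading, normalization, and gray-level quantization.

Conventions used throughout the package:

* A *gray image* is a 2-D ``float64`` :class:`numpy.ndarray` with every value
  finite and in ``[0, 1]``.  Indexing is row-major, 0-based, ``(row, col)``.
* A *quantized image* is a 2-D integer array with values in ``[0, L-1]``
  for some number of gray levels ``L >= 2``; it is the discrete carrier
  required by co-occurrence statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_gray_image",
    "validate_gray_image",
    "load_image",
    "quantize",
]

# ITU-R BT.601 luminance weights for RGB -> gray reduction.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Raised for unreadable files or unsupported pixel formats."""


def validate_gray_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid gray image and return it as float64.

    Raises ``ValueError`` if the array is not 2-D with at least 2 pixels on
    each side, or contains non-finite values or values outside ``[0, 1]``.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"gray image must be at least 2x2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("gray image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("gray image values must lie in [0, 1]")
    return arr


def as_gray_image(values, clip: bool = False) -> np.ndarray:
    """Coerce array-like ``values`` to a validated gray image.

    With ``clip=True`` values are clipped into ``[0, 1]`` first (useful after
    arithmetic that may overshoot by rounding).
    """
    arr = np.asarray(values, dtype=np.float64)
    if clip:
        arr = np.clip(arr, 0.0, 1.0)
    return validate_gray_image(arr)


def _to_float01(arr: np.ndarray) -> np.ndarray:
    """Normalize a raster pixel array to float64 in [0, 1] by bit depth."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    if arr.dtype == np.int16:  # common in DICOM pixel data
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    raise ImageFormatError(f"unsupported pixel dtype: {arr.dtype}")


def _reduce_channels(arr: np.ndarray) -> np.ndarray:
    """Reduce a multi-channel image to one channel by luminance weighting."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0]
        if arr.shape[2] in (3, 4):
            return arr[:, :, :3] @ _LUMA_WEIGHTS
    raise ImageFormatError(f"unsupported image shape: {arr.shape}")


def load_image(path, target_size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a raster file as a gray image in ``[0, 1]``.

    Parameters
    ----------
    path : str or path-like
        PNG/JPEG/BMP/TIFF file, or a DICOM file (requires ``pydicom``).
    target_size : (rows, cols), optional
        If given, the image is resized with bilinear interpolation and
        clipped back into ``[0, 1]``.

    8-bit inputs are divided by 255, 16-bit by 65535; RGB(A) inputs are
    reduced to one channel with the 0.299/0.587/0.114 luminance weights.
    """
    import os

    path = os.fspath(path)
    if not os.path.isfile(path) or os.path.getsize(path) == 0:
        raise ImageFormatError(f"unreadable or empty image file: {path}")

    if path.lower().endswith((".dcm", ".dicom")):
        arr = _read_dicom(path)
    else:
        import imageio.v3 as iio

        try:
            raw = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
        arr = _to_float01(_reduce_channels_raw(raw))

    arr = np.clip(arr, 0.0, 1.0)
    if target_size is not None:
        from skimage.transform import resize

        arr = resize(arr, tuple(target_size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        arr = np.clip(arr, 0.0, 1.0)
    return validate_gray_image(arr)


def _reduce_channels_raw(raw: np.ndarray) -> np.ndarray:
    """Channel reduction that keeps integer scaling correct.

    Luminance weights sum to 1, so weighting before bit-depth division and
    after are equivalent; we convert each channel to float first to avoid
    integer overflow.
    """
    if raw.ndim == 3:
        scaled = _to_float01(raw.reshape(-1, raw.shape[2])).reshape(raw.shape)
        return _reduce_channels(scaled)
    return _to_float01(raw)


def _read_dicom(path: str) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImageFormatError("DICOM support requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def quantize(img: np.ndarray, L: int) -> np.ndarray:
    """Quantize a gray image to ``L`` discrete levels.

    A value ``v`` maps to ``min(floor(v * L), L - 1)``: the unit interval is
    split into ``L`` equal bins, with 1.0 clamped into the top bin.  The
    mapping is monotone non-decreasing in ``v``.
    """
    if int(L) != L or L < 2:
        raise ValueError(f"number of gray levels must be an integer >= 2, got {L}")
    img = validate_gray_image(img)
    q = np.floor(img * L).astype(np.int64)
    return np.minimum(q, L - 1)
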