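"""Contrast-stretch preprocessing.

Linearly maps the occupied intensity range of an image onto the full
``[0, 1]`` scale.  Unlike histogram equalization this preserves the relative
ordering of gray levels: if one pixel is darker than another before the
stretch it stays darker (or equal, after clipping) afterwards.
"""

from __future__ import annotations

import warnings

import numpy as np

from .image_core import validate_gray_image

__all__ = ["contrast_stretch"]


def contrast_stretch(img: np.ndarray, low_pct: float = 0.0,
                     high_pct: float = 100.0) -> np.ndarray:
    """Stretch the intensity spectrum of ``img`` onto ``[0, 1]``.

    The intensities at the ``low_pct`` and ``high_pct`` percentiles are mapped
    to 0 and 1 respectively; values outside are clipped.  The defaults give a
    pure min-max stretch; tightening the percentiles makes the stretch robust
    to isolated hot or dead pixels.

    A constant image has no spectrum to stretch: it is mapped to all zeros
    and a ``UserWarning`` is emitted.
    """
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError(
            f"percentiles must satisfy 0 <= low < high <= 100, "
            f"got ({low_pct}, {high_pct})")
    img = validate_gray_image(img)
    a, b = np.percentile(img, [low_pct, high_pct])
    if b == a:
        warnings.warn("contrast_stretch: degenerate intensity range, "
                      "returning all-zero image", stacklevel=2)
        return np.zeros_like(img)
    return np.clip((img - a) / (b - a), 0.0, 1.0)
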