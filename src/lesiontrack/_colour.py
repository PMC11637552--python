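"""sRGB <-> CIE L*a*b* conversion and colour-difference helpers.

Thin wrappers over scikit-image's colour module so the rest of the package
shares one conversion path (sRGB gamma expansion, D65 white point, CIELAB).
"""

from __future__ import annotations

import numpy as np
from skimage.color import lab2rgb, rgb2lab


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB values to CIE L*a*b* (D65).

    Parameters
    ----------
    rgb : array-like, shape (..., 3), uint8 or float in [0, 255]
        sRGB pixel values.

    Returns
    -------
    ndarray, shape (..., 3)
        L* in [0, 100], a* and b* unbounded.
    """
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    return rgb2lab(arr)


def lab_to_srgb(lab) -> np.ndarray:
    """Convert CIE L*a*b* (D65) to 8-bit sRGB, clipping out-of-gamut values."""
    rgb = lab2rgb(np.asarray(lab, dtype=np.float64))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def delta_e(lab1, lab2) -> np.ndarray:
    """CIE76 colour difference: Euclidean distance in L*a*b* space."""
    a = np.asarray(lab1, dtype=np.float64)
    b = np.asarray(lab2, dtype=np.float64)
    return np.sqrt(np.sum((a - b) ** 2, axis=-1))
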