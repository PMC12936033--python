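"""Single-level stationary 3-D wavelet decomposition into 8 sub-bands.

The stationary (undecimated) transform keeps every sub-band on the input
grid, so the region mask applies unchanged.  Band names map the
approximation/detail axis choice to L/H per axis: LLL ... HHH.
"""

from __future__ import annotations

import numpy as np
import pywt

from .schema import WAVELET_BANDS


def wavelet_bands(
    values: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Decompose a 3-D array into its 8 single-level stationary sub-bands.

    Axes are padded (edge mode) to even length for the transform and the
    result is cropped back, so every band has the input shape.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D array")
    pad = [(0, (2 - s % 2) % 2 if s > 1 else 2 - s) for s in arr.shape]
    padded = np.pad(arr, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet=wavelet, level=1, start_level=0)[0]
    out: dict[str, np.ndarray] = {}
    crop = tuple(slice(0, s) for s in arr.shape)
    for key, band in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = band[crop]
    assert set(out) == set(WAVELET_BANDS)
    return out
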