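"""Loess-style smoothing of positional profiles.

Profiles live on a uniform 1-nt offset grid, so local quadratic least
squares (Savitzky-Golay) gives the loess-type smoothing used for motif and
crosslink metaprofiles; the span is the fraction of the grid inside each
local fit.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter


def loess_smooth(y: np.ndarray, span: float = 0.1) -> np.ndarray:
    """Smooth ``y`` with a local quadratic fit spanning ``span`` of the grid."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        return y.copy()
    window = int(round(span * n))
    window = max(5, window | 1)  # odd, at least 5
    window = min(window, n if n % 2 else n - 1)
    return savgol_filter(y, window_length=window, polyorder=2, mode="interp")
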