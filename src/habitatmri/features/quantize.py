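"""Region-wise gray-level quantization.

Equal-width bins between the region minimum and maximum; the maximum value is
assigned to the top bin (half-open bins, last closed).  A constant region maps
entirely to level 0.  Per-region min-max quantization makes all downstream
histogram/texture features invariant to affine intensity rescaling of a
subject.
"""

from __future__ import annotations

import numpy as np


def quantize(values: np.ndarray, levels: int = 64) -> np.ndarray:
    """Map region intensities to integer levels in [0, levels-1]."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot quantize an empty region")
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    return q
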