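"""First-order intensity histogram and local-binary-pattern histogram features.

First order: the 64-bin normalized histogram of region intensities after
region min-max quantization.

LBP: slice-wise (axial) 2D local binary pattern with P=6 ring neighbors at
radius R=1, giving exactly 2^6 = 64 codes.  Neighbor intensities are sampled
from the underlying image by bilinear interpolation (the mask selects which
pixels are pooled, not which neighbors may be read — thin shells keep valid
codes); the comparison is ``neighbor >= center``, so a constant region
produces the all-ones code (63).  Codes are computed at every in-mask pixel
at least one pixel from the image border, pooled over all slices and
L1-normalized.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .quantize import quantize

LBP_P = 6
LBP_R = 1.0

FIRST_ORDER_NAMES: tuple[str, ...] = tuple(f"firstorder_hist_bin{i:02d}" for i in range(64))
LBP_NAMES: tuple[str, ...] = tuple(f"lbp_code{i:02d}" for i in range(64))


def first_order_features(channel: np.ndarray, mask: np.ndarray, levels: int = 64) -> np.ndarray:
    """64-bin normalized histogram of quantized region voxels (sums to 1)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("first-order features require a non-empty mask")
    q = quantize(np.asarray(channel)[mask], levels=levels)
    hist = np.bincount(q, minlength=levels).astype(np.float64)
    return hist / hist.sum()


def _ring_offsets(p: int = LBP_P, r: float = LBP_R) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(p) / p
    return np.stack([r * np.cos(angles), r * np.sin(angles)], axis=1)  # (row, col)


def lbp_codes_slice(image2d: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """LBP code (0..63) at each pixel where ``valid`` is true."""
    rows, cols = np.nonzero(valid)
    center = image2d[rows, cols].astype(np.float64)
    codes = np.zeros(len(rows), dtype=np.int64)
    for k, (dr, dc) in enumerate(_ring_offsets()):
        sampled = ndimage.map_coordinates(
            image2d.astype(np.float64),
            np.stack([rows + dr, cols + dc]),
            order=1,
            mode="nearest",
        )
        codes |= (sampled >= center - 1e-12).astype(np.int64) << k
    return codes


def _interior_2d(mask2d: np.ndarray) -> np.ndarray:
    # in-mask pixels whose full neighbor ring lies inside the image
    interior = mask2d.copy()
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return interior


def lbp_histogram(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled 64-bin LBP code histogram over axial slices, L1-normalized."""
    channel = np.asarray(channel)
    mask = np.asarray(mask, dtype=bool)
    counts = np.zeros(2**LBP_P, dtype=np.float64)
    total = 0
    for z in range(mask.shape[2]):
        m = mask[:, :, z]
        if not m.any():
            continue
        valid = _interior_2d(m)
        if not valid.any():
            continue
        codes = lbp_codes_slice(channel[:, :, z], valid)
        counts += np.bincount(codes, minlength=2**LBP_P)
        total += len(codes)
    if total == 0:
        raise ValueError("LBP requires at least one slice with interior pixels")
    return counts / counts.sum()
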