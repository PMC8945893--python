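"""Dense gradient-orientation (SIFT-style) descriptors encoded as a
bag-of-visual-words histogram against a learned 1024-word codebook.

Descriptors are the classic 128-d layout: a 16x16-pixel patch split into
4x4 spatial cells, each accumulating an 8-bin gradient-orientation
histogram weighted by gradient magnitude and a Gaussian window; upright
(no dominant-orientation rotation), L2-normalized, clipped at 0.2 and
renormalized.  Keypoints are placed densely on axial slices at in-mask
pixels on a regular stride grid.  The codebook is mini-batch k-means with
a fixed seed, trained on the training split only; a region histogram is
the L1-normalized assignment count over its descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import pairwise_distances_argmin

PATCH = 16  # pixels per side
CELLS = 4  # spatial cells per side
ORI_BINS = 8
DESCRIPTOR_DIM = CELLS * CELLS * ORI_BINS  # 128
DEFAULT_WORDS = 1024

SIFT_FEATURE_NAMES: tuple[str, ...] = tuple(f"sift_word{i:04d}" for i in range(DEFAULT_WORDS))


class InsufficientDescriptorsError(ValueError):
    """Codebook training set yielded fewer descriptors than visual words."""


@dataclass
class VisualWordCodebook:
    centroids: np.ndarray  # (n_words, 128)
    seed: int
    n_training_descriptors: int

    @property
    def n_words(self) -> int:
        return self.centroids.shape[0]


def _gaussian_window() -> np.ndarray:
    half = PATCH / 2.0
    ax = np.arange(PATCH) - half + 0.5
    gg = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * (half) ** 2))
    return gg


_WINDOW = _gaussian_window()


def dense_descriptors(
    image2d: np.ndarray, mask2d: np.ndarray, stride: int = 4
) -> np.ndarray:
    """Upright 128-d descriptors at in-mask grid points of one slice."""
    img = np.asarray(image2d, dtype=np.float64)
    h, w = img.shape
    gy, gx = np.gradient(img)
    mag = np.sqrt(gx**2 + gy**2)
    ori = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    obin = np.minimum((ori / (2.0 * np.pi) * ORI_BINS).astype(np.int64), ORI_BINS - 1)

    half = PATCH // 2
    rows = np.arange(half, h - half + 1, stride)
    cols = np.arange(half, w - half + 1, stride)
    if len(rows) == 0 or len(cols) == 0:
        return np.empty((0, DESCRIPTOR_DIM))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = mask2d[rr, cc]
    rr = rr[keep]
    cc = cc[keep]
    if len(rr) == 0:
        return np.empty((0, DESCRIPTOR_DIM))

    dr = np.arange(-half, half)
    cell_idx = np.arange(PATCH) // (PATCH // CELLS)  # 0..3 per pixel row/col
    # gather patches with broadcasting: (nkp, PATCH, PATCH)
    pr = rr[:, None, None] + dr[None, :, None]
    pc = cc[:, None, None] + dr[None, None, :]
    pmag = mag[pr, pc] * _WINDOW[None, :, :]
    pbin = obin[pr, pc]
    # component index = cell_row*32 + cell_col*8 + orientation_bin
    comp2d = cell_idx[:, None] * (CELLS * ORI_BINS) + cell_idx[None, :] * ORI_BINS
    comp = comp2d[None, :, :] + pbin
    flat = np.zeros((len(rr), DESCRIPTOR_DIM))
    kidx = np.broadcast_to(np.arange(len(rr))[:, None, None], pmag.shape)
    np.add.at(flat, (kidx.ravel(), comp.ravel()), pmag.ravel())

    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    flat[nz] /= norms[nz]
    np.clip(flat, 0.0, 0.2, out=flat)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    flat[nz] /= norms[nz]
    return flat


def region_descriptors(channel: np.ndarray, mask: np.ndarray, stride: int = 4) -> np.ndarray:
    """Descriptors pooled over all axial slices of a 3D region."""
    mask = np.asarray(mask, dtype=bool)
    parts = []
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            d = dense_descriptors(channel[:, :, z], mask[:, :, z], stride=stride)
            if len(d):
                parts.append(d)
    if not parts:
        return np.empty((0, DESCRIPTOR_DIM))
    return np.vstack(parts)


def build_codebook(
    descriptors: np.ndarray, seed: int = 0, n_words: int = DEFAULT_WORDS
) -> VisualWordCodebook:
    """Learn the visual-word codebook by mini-batch k-means (fixed seed)."""
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if descriptors.shape[0] < n_words:
        raise InsufficientDescriptorsError(
            f"codebook training needs at least {n_words} descriptors, "
            f"got {descriptors.shape[0]}"
        )
    km = MiniBatchKMeans(
        n_clusters=n_words,
        random_state=seed,
        n_init=1,
        batch_size=max(1024, n_words),
        max_iter=100,
    )
    km.fit(descriptors)
    return VisualWordCodebook(
        centroids=km.cluster_centers_.copy(),
        seed=seed,
        n_training_descriptors=int(descriptors.shape[0]),
    )


def sift_features(
    channel: np.ndarray,
    mask: np.ndarray,
    codebook: VisualWordCodebook,
    stride: int = 4,
) -> np.ndarray:
    """L1-normalized visual-word histogram of one region (len = n_words).

    A region too small to yield any descriptor returns the zero vector and
    emits a warning.
    """
    descs = region_descriptors(channel, mask, stride=stride)
    hist = np.zeros(codebook.n_words, dtype=np.float64)
    if len(descs) == 0:
        warnings.warn("region yielded no descriptors; returning zero histogram")
        return hist
    words = pairwise_distances_argmin(descs, codebook.centroids)
    np.add.at(hist, words, 1.0)
    return hist / hist.sum()
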