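"""Gray-level co-occurrence matrix features (22 statistics x 4 in-plane offsets).

Per axial slice and per offset (0, 45, 90, 135 degrees at distance 1), pairs of
quantized levels whose two pixels both lie in the mask are accumulated
bidirectionally (symmetric GLCM).  Count matrices are pooled (summed) across
slices before normalization, then the 22-statistic set below is computed per
offset.  Gray levels enter the statistics 1-based (level index + 1).
"""

from __future__ import annotations

import numpy as np

from .quantize import quantize

# (row, col) steps; angles follow the usual image convention
GLCM_OFFSETS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_STAT_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "joint_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_moment",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "sum_of_squares_variance",
)

GLCM_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"glcm_{stat}_{ang:03d}" for ang in GLCM_OFFSETS for stat in GLCM_STAT_NAMES
)


def cooccurrence_counts(
    qimg: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
) -> np.ndarray:
    """Symmetric pair counts for one 2D slice and one offset."""
    dr, dc = offset
    h, w = qimg.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    a_mask = mask[r0:r1, c0:c1]
    b_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    both = a_mask & b_mask
    a = qimg[r0:r1, c0:c1][both]
    b = qimg[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    return counts


def pooled_glcm(
    channel: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int = 64
) -> np.ndarray:
    """Normalized symmetric GLCM pooled over axial slices."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLCM requires a non-empty region")
    q3 = np.zeros(mask.shape, dtype=np.int64)
    q3[mask] = quantize(np.asarray(channel)[mask], levels=levels)
    counts = np.zeros((levels, levels), dtype=np.float64)
    for z in range(mask.shape[2]):
        m = mask[:, :, z]
        if m.any():
            counts += cooccurrence_counts(q3[:, :, z], m, offset, levels)
    total = counts.sum()
    if total == 0:
        raise ValueError("GLCM requires at least one in-mask neighbor pair")
    return counts / total


def _safe_log2(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = np.log2(x[nz])
    return out


def glcm_statistics(p: np.ndarray) -> dict[str, float]:
    """The 22-statistic set from one normalized symmetric GLCM."""
    levels = p.shape[0]
    i = np.arange(1, levels + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal-sum and diagonal-difference distributions
    ksum = np.arange(2, 2 * levels + 1, dtype=np.float64)
    p_sum = np.zeros(len(ksum))
    kdiff = np.arange(0, levels, dtype=np.float64)
    p_diff = np.zeros(len(kdiff))
    sums = (ii + jj).astype(int)
    diffs = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())
    np.add.at(p_diff, diffs.ravel(), p.ravel())

    contrast = float(((ii - jj) ** 2 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p**2).sum())
    entropy = float(-(p * _safe_log2(p)).sum())
    autocorr = float((ii * jj * p).sum())
    cluster = ii + jj - mu_x - mu_y
    cluster_tendency = float((cluster**2 * p).sum())
    cluster_shade = float((cluster**3 * p).sum())
    cluster_prominence = float((cluster**4 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 1.0
    inverse_difference = float((p / (1.0 + np.abs(ii - jj))).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    offdiag = ii != jj
    inverse_variance = float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum())
    max_prob = float(p.max())
    sum_average = float((ksum * p_sum).sum())
    sum_entropy = float(-(p_sum * _safe_log2(p_sum)).sum())
    sum_variance = float(((ksum - sum_average) ** 2 * p_sum).sum())
    diff_average = float((kdiff * p_diff).sum())
    diff_entropy = float(-(p_diff * _safe_log2(p_diff)).sum())
    diff_variance = float(((kdiff - diff_average) ** 2 * p_diff).sum())
    variance = float((((ii - mu_x) ** 2) * p).sum())

    # information measures of correlation
    hxy = entropy
    hx = float(-(px * _safe_log2(px)).sum())
    hy = float(-(py * _safe_log2(py)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * _safe_log2(pxpy)).sum())
    hxy2 = float(-(pxpy * _safe_log2(pxpy)).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "cluster_tendency": cluster_tendency,
        "contrast": contrast,
        "correlation": correlation,
        "joint_average": mu_x,
        "difference_entropy": diff_entropy,
        "difference_variance": diff_variance,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": entropy,
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_difference": inverse_difference,
        "inverse_difference_moment": idm,
        "inverse_variance": inverse_variance,
        "maximum_probability": max_prob,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "sum_of_squares_variance": variance,
    }


def glcm_features(channel: np.ndarray, mask: np.ndarray, levels: int = 64) -> dict[str, float]:
    """88 GLCM features: 22 statistics per in-plane offset (0/45/90/135 deg)."""
    out: dict[str, float] = {}
    for ang, offset in GLCM_OFFSETS.items():
        p = pooled_glcm(channel, mask, offset, levels=levels)
        stats = glcm_statistics(p)
        for name, value in stats.items():
            out[f"glcm_{name}_{ang:03d}"] = value
    return out
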