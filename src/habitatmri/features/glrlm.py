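"""Gray-level run-length matrix features (11 statistics x 4 in-plane directions).

Per axial slice and direction (0, 45, 90, 135 degrees), maximal runs of equal
quantized level along in-mask line segments are counted into an L x Rmax
matrix; a masked-out pixel terminates a run.  Run matrices are pooled (summed)
across slices per direction.  Gray levels enter the statistics 1-based.
"""

from __future__ import annotations

import numpy as np

from .quantize import quantize

GLRLM_DIRECTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLRLM_STAT_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"glrlm_{stat}_{ang:03d}" for ang in GLRLM_DIRECTIONS for stat in GLRLM_STAT_NAMES
)


def _line_runs(levels_1d: np.ndarray, mask_1d: np.ndarray):
    """Yield (level, run_length) for maximal in-mask constant runs of one line."""
    n = len(levels_1d)
    start = 0
    while start < n:
        if not mask_1d[start]:
            start += 1
            continue
        end = start + 1
        while end < n and mask_1d[end] and levels_1d[end] == levels_1d[start]:
            end += 1
        yield int(levels_1d[start]), end - start
        start = end


def _slice_lines(arr2d: np.ndarray, direction: tuple[int, int]):
    """All scan lines of a 2D array along one of the four directions."""
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(arr2d.shape[0]):
            yield arr2d[r, :]
    elif (dr, dc) == (-1, 0):
        for c in range(arr2d.shape[1]):
            yield arr2d[:, c]
    elif (dr, dc) == (-1, 1):  # anti-diagonals, bottom-left to top-right
        flipped = arr2d[::-1, :]
        for off in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=off)
    else:  # (-1, -1): diagonals running up-left
        flipped = arr2d[::-1, ::-1]
        for off in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=off)


def run_length_matrix(
    qimg: np.ndarray, mask: np.ndarray, direction: tuple[int, int], levels: int
) -> np.ndarray:
    """L x Rmax run-count matrix of one 2D slice in one direction."""
    rmax = max(qimg.shape)
    counts = np.zeros((levels, rmax), dtype=np.float64)
    for lev_line, mask_line in zip(
        _slice_lines(qimg, direction), _slice_lines(mask, direction)
    ):
        if not mask_line.any():
            continue
        for level, length in _line_runs(lev_line, mask_line):
            counts[level, length - 1] += 1.0
    return counts


def pooled_glrlm(
    channel: np.ndarray, mask: np.ndarray, direction: tuple[int, int], levels: int = 64
) -> np.ndarray:
    """Run matrix pooled (summed) over axial slices."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLRLM requires a non-empty region")
    q3 = np.zeros(mask.shape, dtype=np.int64)
    q3[mask] = quantize(np.asarray(channel)[mask], levels=levels)
    rmax = max(mask.shape[0], mask.shape[1])
    counts = np.zeros((levels, rmax), dtype=np.float64)
    for z in range(mask.shape[2]):
        m = mask[:, :, z]
        if m.any():
            counts += run_length_matrix(q3[:, :, z], m, direction, levels)
    return counts


def glrlm_statistics(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11-statistic set from one run-length count matrix."""
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    g = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    rl = r / n_runs
    rg_sum = r.sum(axis=1)
    rlen_sum = r.sum(axis=0)
    return {
        "short_run_emphasis": float((rl / l**2).sum()),
        "long_run_emphasis": float((rl * l**2).sum()),
        "gray_level_nonuniformity": float((rg_sum**2).sum() / n_runs),
        "run_length_nonuniformity": float((rlen_sum**2).sum() / n_runs),
        "run_percentage": float(n_runs / n_voxels),
        "low_gray_level_run_emphasis": float((rl / g**2).sum()),
        "high_gray_level_run_emphasis": float((rl * g**2).sum()),
        "short_run_low_gray_level_emphasis": float((rl / (g**2 * l**2)).sum()),
        "short_run_high_gray_level_emphasis": float((rl * g**2 / l**2).sum()),
        "long_run_low_gray_level_emphasis": float((rl * l**2 / g**2).sum()),
        "long_run_high_gray_level_emphasis": float((rl * g**2 * l**2).sum()),
    }


def glrlm_features(channel: np.ndarray, mask: np.ndarray, levels: int = 64) -> dict[str, float]:
    """44 GLRLM features: 11 statistics per direction (0/45/90/135 deg)."""
    mask = np.asarray(mask, dtype=bool)
    n_voxels = int(mask.sum())
    out: dict[str, float] = {}
    for ang, direction in GLRLM_DIRECTIONS.items():
        counts = pooled_glrlm(channel, mask, direction, levels=levels)
        stats = glrlm_statistics(counts, n_voxels)
        for name, value in stats.items():
            out[f"glrlm_{name}_{ang:03d}"] = value
    return out
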