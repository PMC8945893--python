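"""GLCM/GLRLM against independent brute-force pair and run enumeration.

The oracles below re-derive the matrices by explicit per-pixel loops and the
statistics by explicit double loops, sharing no code with the implementation.
"""

import numpy as np
import pytest

from habitatmri.features import (
    GLCM_OFFSETS,
    GLRLM_DIRECTIONS,
    glcm_features,
    glrlm_features,
)
from habitatmri.features.quantize import quantize

# ---------------------------------------------------------------- oracles


def brute_glcm_matrix(q2d, mask2d, offset, levels):
    dr, dc = offset
    counts = np.zeros((levels, levels))
    h, w = q2d.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask2d[r, c] and mask2d[r2, c2]:
                counts[q2d[r, c], q2d[r2, c2]] += 1
                counts[q2d[r2, c2], q2d[r, c]] += 1
    return counts


def brute_glcm_stats(p):
    L = p.shape[0]
    lev = np.arange(1, L + 1)
    px = p.sum(1)
    py = p.sum(0)
    mux = sum(lev[i] * px[i] for i in range(L))
    muy = sum(lev[j] * py[j] for j in range(L))
    sdx = np.sqrt(sum((lev[i] - mux) ** 2 * px[i] for i in range(L)))
    sdy = np.sqrt(sum((lev[j] - muy) ** 2 * py[j] for j in range(L)))
    psum = {}
    pdiff = {}
    for i in range(L):
        for j in range(L):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]

    def ent(d):
        return -sum(v * np.log2(v) for v in d if v > 0)

    sa = sum(k * v for k, v in psum.items())
    da = sum(k * v for k, v in pdiff.items())
    out = {}
    out["autocorrelation"] = sum(
        lev[i] * lev[j] * p[i, j] for i in range(L) for j in range(L)
    )
    for power, name in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[name] = sum(
            (lev[i] + lev[j] - mux - muy) ** power * p[i, j]
            for i in range(L)
            for j in range(L)
        )
    out["contrast"] = sum((lev[i] - lev[j]) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out["correlation"] = (
        (out["autocorrelation"] - mux * muy) / (sdx * sdy) if sdx > 0 and sdy > 0 else 1.0
    )
    out["joint_average"] = mux
    out["difference_entropy"] = ent(pdiff.values())
    out["difference_variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    out["dissimilarity"] = sum(
        abs(lev[i] - lev[j]) * p[i, j] for i in range(L) for j in range(L)
    )
    out["energy"] = (p**2).sum()
    out["entropy"] = ent(p.ravel())
    hx = ent(px)
    hy = ent(py)
    hxy = out["entropy"]
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    out["inverse_difference"] = sum(
        p[i, j] / (1 + abs(lev[i] - lev[j])) for i in range(L) for j in range(L)
    )
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (lev[i] - lev[j]) ** 2) for i in range(L) for j in range(L)
    )
    out["inverse_variance"] = sum(
        p[i, j] / (lev[i] - lev[j]) ** 2 for i in range(L) for j in range(L) if i != j
    )
    out["maximum_probability"] = p.max()
    out["sum_average"] = sa
    out["sum_entropy"] = ent(psum.values())
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    out["sum_of_squares_variance"] = sum(
        (lev[i] - mux) ** 2 * p[i, j] for i in range(L) for j in range(L)
    )
    return out


def brute_runs(q2d, mask2d, direction):
    """Enumerate maximal in-mask constant runs by walking each scan line."""
    dr, dc = direction
    h, w = q2d.shape
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur = None
        length = 0
        while 0 <= r < h and 0 <= c < w:
            if mask2d[r, c]:
                if cur is not None and q2d[r, c] == cur:
                    length += 1
                else:
                    if cur is not None:
                        runs.append((cur, length))
                    cur = q2d[r, c]
                    length = 1
            else:
                if cur is not None:
                    runs.append((cur, length))
                cur = None
                length = 0
            r += dr
            c += dc
        if cur is not None:
            runs.append((cur, length))
    return runs


def brute_glrlm_stats(runs, n_voxels, levels):
    n_runs = len(runs)
    out = dict.fromkeys(
        (
            "short_run_emphasis",
            "long_run_emphasis",
            "low_gray_level_run_emphasis",
            "high_gray_level_run_emphasis",
            "short_run_low_gray_level_emphasis",
            "short_run_high_gray_level_emphasis",
            "long_run_low_gray_level_emphasis",
            "long_run_high_gray_level_emphasis",
        ),
        0.0,
    )
    by_level = {}
    by_length = {}
    for level, length in runs:
        g = level + 1
        out["short_run_emphasis"] += 1 / length**2
        out["long_run_emphasis"] += length**2
        out["low_gray_level_run_emphasis"] += 1 / g**2
        out["high_gray_level_run_emphasis"] += g**2
        out["short_run_low_gray_level_emphasis"] += 1 / (g**2 * length**2)
        out["short_run_high_gray_level_emphasis"] += g**2 / length**2
        out["long_run_low_gray_level_emphasis"] += length**2 / g**2
        out["long_run_high_gray_level_emphasis"] += g**2 * length**2
        by_level[g] = by_level.get(g, 0) + 1
        by_length[length] = by_length.get(length, 0) + 1
    for k in out:
        out[k] /= n_runs
    out["gray_level_nonuniformity"] = sum(v**2 for v in by_level.values()) / n_runs
    out["run_length_nonuniformity"] = sum(v**2 for v in by_length.values()) / n_runs
    out["run_percentage"] = n_runs / n_voxels
    return out


# ---------------------------------------------------------------- tests


def test_glcm_constant_region():
    img = np.full((5, 5, 1), 3.0)
    mask = np.ones((5, 5, 1), dtype=bool)
    f = glcm_features(img, mask)
    for ang in (0, 45, 90, 135):
        assert f[f"glcm_contrast_{ang:03d}"] == 0.0
        assert f[f"glcm_energy_{ang:03d}"] == 1.0
        assert f[f"glcm_entropy_{ang:03d}"] == 0.0


def test_glcm_checkerboard_horizontal():
    img = (np.indices((6, 6)).sum(axis=0) % 2).astype(float)[:, :, None]
    mask = np.ones((6, 6, 1), dtype=bool)
    f = glcm_features(img, mask, levels=2)
    assert f["glcm_contrast_000"] == pytest.approx(1.0)
    assert f["glcm_energy_000"] == pytest.approx(0.5)


@pytest.mark.parametrize("trial", range(25))
def test_glcm_matches_brute_force_random_patches(trial):
    rng = np.random.default_rng(1000 + trial)
    levels = int(rng.integers(2, 7))
    h, w = rng.integers(3, 9, size=2)
    img = rng.integers(0, 40, size=(h, w)).astype(float)
    mask = rng.random((h, w)) > 0.25
    if mask.sum() < 4:
        mask[:2, :2] = True
    q = np.zeros((h, w), dtype=np.int64)
    q[mask] = quantize(img[mask], levels)
    f = glcm_features(img[:, :, None], mask[:, :, None], levels=levels)
    for ang, off in GLCM_OFFSETS.items():
        counts = brute_glcm_matrix(q, mask, off, levels)
        if counts.sum() == 0:
            continue
        expected = brute_glcm_stats(counts / counts.sum())
        for name, val in expected.items():
            assert f[f"glcm_{name}_{ang:03d}"] == pytest.approx(val, abs=1e-9), (name, ang)


def test_glrlm_single_line_runs():
    img = np.full((1, 8, 1), 2.0)
    mask = np.ones((1, 8, 1), dtype=bool)
    f = glrlm_features(img, mask)
    assert f["glrlm_long_run_emphasis_000"] == pytest.approx(64.0)
    assert f["glrlm_run_percentage_000"] == pytest.approx(1.0 / 8.0)


def test_glrlm_alternating_line():
    img = (np.arange(8) % 2).astype(float).reshape(1, 8, 1)
    mask = np.ones((1, 8, 1), dtype=bool)
    f = glrlm_features(img, mask, levels=2)
    assert f["glrlm_short_run_emphasis_000"] == pytest.approx(1.0)
    assert f["glrlm_run_percentage_000"] == pytest.approx(1.0)


@pytest.mark.parametrize("trial", range(25))
def test_glrlm_matches_brute_force_random_patches(trial):
    rng = np.random.default_rng(2000 + trial)
    levels = int(rng.integers(2, 7))
    h, w = rng.integers(3, 9, size=2)
    img = rng.integers(0, 40, size=(h, w)).astype(float)
    mask = rng.random((h, w)) > 0.25
    if mask.sum() < 4:
        mask[:2, :2] = True
    q = np.zeros((h, w), dtype=np.int64)
    q[mask] = quantize(img[mask], levels)
    f = glrlm_features(img[:, :, None], mask[:, :, None], levels=levels)
    n_vox = int(mask.sum())
    for ang, direction in GLRLM_DIRECTIONS.items():
        runs = brute_runs(q, mask, direction)
        assert sum(length for _, length in runs) == n_vox  # runs partition the region
        expected = brute_glrlm_stats(runs, n_vox, levels)
        for name, val in expected.items():
            assert f[f"glrlm_{name}_{ang:03d}"] == pytest.approx(val, abs=1e-9), (name, ang)


def test_texture_errors_on_empty_region():
    img = np.ones((4, 4, 1))
    empty = np.zeros((4, 4, 1), dtype=bool)
    with pytest.raises(ValueError):
        glcm_features(img, empty)
    with pytest.raises(ValueError):
        glrlm_features(img, empty)
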