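"""Synthetic multi-parametric GBM phantom subjects and cohorts.

A phantom subject is a set of four nested habitat shells (necrosis core,
solid enhancing rim, peritumoral tissue, peritumoral edema) voxelized on a
regular grid, plus four MR-like channels (T1-CE, T2-W, FLAIR, ADC) with
per-habitat mean contrast, per-habitat texture, an optional multiplicative
bias field and Rician noise.

Cohort generation draws per-subject habitat volume *fractions* of the
abnormal bulk volume (ABV) from a two-component mixture of
normalized-independent-gamma distributions — each component a strict
generalization of the Dirichlet (equal gamma scales recover it), the mixture
representing cohort heterogeneity — whose parameters are calibrated so that
the cohort means of all ten habitat volume ratios (the four /ABV fractions
and the six cross-habitat ratios) converge to the targets stored in the
preset.  The calibration uses closed forms for ratio-of-gamma moments and a
1-D integral representation (fixed Gauss-Legendre nodes) for the /ABV
moments, so it is fast and deterministic.

All randomness flows from explicit integer seeds; geometry (labels) and
appearance (channels) use separate derived streams, so label maps are
bit-identical whether or not channels are rendered.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .io import write_subject
from .types import CHANNEL_NAMES, HABITAT_NAMES, HabitatLabelMap, MultiParametricVolume

RATIO_NAMES: tuple[str, ...] = (
    "necrosis/abv",
    "solid/abv",
    "peritumoral_tissue/abv",
    "edema/abv",
    "necrosis/solid",
    "peritumoral_tissue/solid",
    "edema/solid",
    "necrosis/peritumoral_tissue",
    "solid/peritumoral_tissue",
    "edema/peritumoral_tissue",
)

# (numerator, denominator) habitat indices for the six cross-habitat ratios,
# in the order they appear in RATIO_NAMES[4:]
_CROSS_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (2, 1), (3, 1), (0, 2), (1, 2), (3, 2))


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass
class TextureModel:
    """Habitat texture: 'flat', 'speckle' (grain_mm sets the correlation
    length) or 'stripe' (period_mm sets the spatial period along `axis`)."""

    kind: str = "flat"
    amplitude: float = 0.0
    grain_mm: float = 2.0
    period_mm: float = 4.0
    axis: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "speckle", "stripe"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.kind != "flat" and self.amplitude < 0:
            raise ValueError("texture amplitude must be >= 0")


@dataclass
class HabitatGeometryConfig:
    """Nested-shell geometry of a single phantom subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    core_radius_mm: float = 10.0
    shell_thickness_mm: dict[str, float] = field(
        default_factory=lambda: {"solid": 4.0, "peritumoral_tissue": 1.5, "edema": 4.0}
    )
    shape_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 32:
            raise ValueError("grid must be at least 32 voxels per axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.core_radius_mm <= 0:
            raise ValueError("core radius must be > 0")
        for name in ("solid", "peritumoral_tissue", "edema"):
            if self.shell_thickness_mm.get(name, 0.0) <= 0:
                raise ValueError(f"shell thickness for {name!r} must be > 0")
        if not 0.0 <= self.shape_perturbation < 0.5:
            raise ValueError("shape perturbation must be in [0, 0.5)")

    def shell_radii_mm(self) -> np.ndarray:
        """Outer radius of each habitat shell (necrosis, solid, PT, edema)."""
        r1 = self.core_radius_mm
        r2 = r1 + self.shell_thickness_mm["solid"]
        r3 = r2 + self.shell_thickness_mm["peritumoral_tissue"]
        r4 = r3 + self.shell_thickness_mm["edema"]
        return np.array([r1, r2, r3, r4])


def _default_channel_means() -> dict[str, dict[str, float]]:
    # arbitrary-unit magnitudes emulating typical habitat contrast per sequence
    return {
        "t1ce": {"background": 30, "necrosis": 40, "solid": 180, "peritumoral_tissue": 90, "edema": 70},
        "t2w": {"background": 30, "necrosis": 160, "solid": 110, "peritumoral_tissue": 125, "edema": 185},
        "flair": {"background": 30, "necrosis": 90, "solid": 130, "peritumoral_tissue": 150, "edema": 200},
        "adc": {"background": 80, "necrosis": 200, "solid": 100, "peritumoral_tissue": 130, "edema": 170},
    }


def _default_textures() -> dict[str, TextureModel]:
    return {
        "necrosis": TextureModel("speckle", amplitude=12.0, grain_mm=1.5),
        "solid": TextureModel("speckle", amplitude=18.0, grain_mm=3.0),
        "peritumoral_tissue": TextureModel("stripe", amplitude=12.0, period_mm=4.0, axis=0),
        "edema": TextureModel("flat"),
    }


@dataclass
class HabitatAppearanceConfig:
    """Per-channel habitat contrast, texture models, noise and shading."""

    channel_means: dict[str, dict[str, float]] = field(default_factory=_default_channel_means)
    textures: dict[str, TextureModel] = field(default_factory=_default_textures)
    rician_sigma: float = 5.0
    bias_field_amplitude: float = 0.0
    min_contrast_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")
        for ch in CHANNEL_NAMES:
            means = self.channel_means[ch]
            vals = sorted(means[h] for h in HABITAT_NAMES)
            gaps = np.diff(vals)
            if len(gaps) and gaps.min() < self.min_contrast_margin:
                raise ValueError(
                    f"habitat means on channel {ch!r} closer than margin "
                    f"{self.min_contrast_margin}"
                )


@dataclass
class CohortPreset:
    """Targets for cohort-level habitat-volume ratio distributions.

    ``ratio_targets`` maps each name in :data:`RATIO_NAMES` to ``(mean, sd)``.
    ``abv_radius_mm`` gives the lognormal (median, sigma-of-log) of the
    subject ABV equivalent-sphere radius.
    """

    name: str
    n_subjects: int
    ratio_targets: dict[str, tuple[float, float]]
    abv_radius_mm: tuple[float, float] = (17.0, 0.08)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in RATIO_NAMES if r not in self.ratio_targets]
        if missing:
            raise ValueError(f"preset lacks ratio targets: {missing}")
        fr = self.abv_fraction_means()
        if np.any(fr <= 0):
            raise ValueError("ABV fraction targets must all be positive")
        if abs(fr.sum() - 1.0) > 0.02:
            raise ValueError(
                f"ABV fraction targets must sum to 1 within rounding, got {fr.sum():.3f}"
            )

    def abv_fraction_means(self) -> np.ndarray:
        return np.array([self.ratio_targets[f"{h}/abv"][0] for h in HABITAT_NAMES])

    def abv_fraction_sds(self) -> np.ndarray:
        return np.array([self.ratio_targets[f"{h}/abv"][1] for h in HABITAT_NAMES])


def local_cohort_preset() -> CohortPreset:
    """Local-hospital training cohort targets (n=23)."""
    return CohortPreset(
        name="local",
        n_subjects=23,
        ratio_targets={
            "necrosis/abv": (0.23, 0.12),
            "solid/abv": (0.31, 0.16),
            "peritumoral_tissue/abv": (0.08, 0.02),
            "edema/abv": (0.39, 0.21),
            "necrosis/solid": (0.97, 0.91),
            "peritumoral_tissue/solid": (0.31, 0.19),
            "edema/solid": (1.98, 1.80),
            "necrosis/peritumoral_tissue": (2.94, 1.42),
            "solid/peritumoral_tissue": (4.12, 2.03),
            "edema/peritumoral_tissue": (5.89, 4.34),
        },
        metadata={
            "source": "published volumetric ratio statistics, local GBM training cohort",
            "ranges": {
                "necrosis/abv": (0.05, 0.55),
                "solid/abv": (0.10, 0.62),
                "peritumoral_tissue/abv": (0.05, 0.11),
                "edema/abv": (0.02, 0.74),
            },
        },
    )


def tcia_cohort_preset() -> CohortPreset:
    """TCIA (TCGA-GBM) validation cohort targets (n=31).

    The published necrosis/ABV SD is printed as 0.83, inconsistent with its
    own range (0.05-0.33) and CI (0.14-0.20); it is stored here as 0.083.
    """
    return CohortPreset(
        name="tcia",
        n_subjects=31,
        ratio_targets={
            "necrosis/abv": (0.17, 0.083),
            "solid/abv": (0.43, 0.15),
            "peritumoral_tissue/abv": (0.09, 0.03),
            "edema/abv": (0.31, 0.19),
            "necrosis/solid": (0.44, 0.21),
            "peritumoral_tissue/solid": (0.22, 0.10),
            "edema/solid": (0.96, 0.82),
            "necrosis/peritumoral_tissue": (2.20, 1.18),
            "solid/peritumoral_tissue": (5.16, 1.49),
            "edema/peritumoral_tissue": (4.25, 3.31),
        },
        metadata={
            "source": "published volumetric ratio statistics, TCIA validation cohort",
            "necrosis/abv_sd_note": "printed SD 0.83 corrected to 0.083 (typo vs range/CI)",
        },
    )


# --------------------------------------------------------------------------
# fraction sampler: normalized independent gammas calibrated to ratio targets
# --------------------------------------------------------------------------


# fixed quadrature nodes mapped from (-1,1) to (0,inf) via t = u/(1-u);
# accurate to ~1e-12 against adaptive quadrature for the parameter ranges used
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(400)
_GL_U = 0.5 * (_GL_NODES + 1.0)
_GL_T = _GL_U / (1.0 - _GL_U)
_GL_W = 0.5 * _GL_WEIGHTS / (1.0 - _GL_U) ** 2


def _gamma_frac_moments(k: np.ndarray, th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First two moments of g_i / sum(g) for independent gammas.

    Uses 1/S = int_0^inf exp(-tS) dt and 1/S^2 = int_0^inf t exp(-tS) dt,
    which turn the moments into 1-D integrals of products of gamma MGFs,
    evaluated on fixed Gauss-Legendre nodes.
    """
    t = _GL_T
    terms = [(1.0 + th[j] * t) ** (-k[j]) for j in range(4)]
    m1 = np.empty(4)
    m2 = np.empty(4)
    for i in range(4):
        others = np.ones_like(t)
        for j in range(4):
            if j != i:
                others = others * terms[j]
        f1 = k[i] * th[i] * (1 + th[i] * t) ** (-(k[i] + 1)) * others
        f2 = t * k[i] * (k[i] + 1) * th[i] ** 2 * (1 + th[i] * t) ** (-(k[i] + 2)) * others
        m1[i] = float((f1 * _GL_W).sum())
        m2[i] = float((f2 * _GL_W).sum())
    return m1, m2


def _gamma_cross_moments(k: np.ndarray, th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact first two moments of g_i/g_j for the six cross-habitat pairs."""
    m1, m2 = [], []
    for i, j in _CROSS_PAIRS:
        m1.append(k[i] * th[i] / ((k[j] - 1.0) * th[j]))
        m2.append(k[i] * (k[i] + 1.0) * th[i] ** 2 / ((k[j] - 1.0) * (k[j] - 2.0) * th[j] ** 2))
    return np.array(m1), np.array(m2)


def _unpack_component(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # all shapes kept > 2: ratio means/variances stay finite (solid and PT
    # are denominators) and no habitat piles probability mass at zero volume
    k = 2.0 + np.exp(x[:4])
    th = np.array([np.exp(x[4]), 1.0, np.exp(x[5]), np.exp(x[6])])
    return k, th


def _mixture_moments(x: np.ndarray):
    lam = 1.0 / (1.0 + np.exp(-x[14]))
    k1, t1 = _unpack_component(x[:7])
    k2, t2 = _unpack_component(x[7:14])
    f1a, f2a = _gamma_frac_moments(k1, t1)
    c1a, c2a = _gamma_cross_moments(k1, t1)
    f1b, f2b = _gamma_frac_moments(k2, t2)
    c1b, c2b = _gamma_cross_moments(k2, t2)
    fm1 = lam * f1a + (1 - lam) * f1b
    fm2 = lam * f2a + (1 - lam) * f2b
    cm1 = lam * c1a + (1 - lam) * c1b
    cm2 = lam * c2a + (1 - lam) * c2b
    return fm1, fm2, cm1, cm2, lam


_SD_WEIGHT = 0.3  # ratio means are the primary calibration targets
_FRACTION_FLOOR = 0.02  # no component may have a mean habitat fraction below this
_FLOOR_WEIGHT = 5.0


@functools.lru_cache(maxsize=16)
def _fit_fraction_params(
    mean_targets: tuple[float, ...], sd_targets: tuple[float, ...]
) -> tuple[float, tuple, tuple, tuple, tuple]:
    """Calibrate the two-component mixture to the 10 ratio means (+ SDs).

    A penalty keeps each component's mean habitat fractions above
    ``_FRACTION_FLOOR`` so every synthetic subject has all four habitats at
    a voxelizable size (the published per-ratio ranges bottom out near 0.02).
    """
    abv_m = np.array(mean_targets[:4])
    cross_m = np.array(mean_targets[4:])
    abv_s = np.array(sd_targets[:4])
    cross_s = np.array(sd_targets[4:])

    def resid(x: np.ndarray) -> np.ndarray:
        lam = 1.0 / (1.0 + np.exp(-x[14]))
        k1, t1 = _unpack_component(x[:7])
        k2, t2 = _unpack_component(x[7:14])
        f1a, f2a = _gamma_frac_moments(k1, t1)
        f1b, f2b = _gamma_frac_moments(k2, t2)
        c1a, c2a = _gamma_cross_moments(k1, t1)
        c1b, c2b = _gamma_cross_moments(k2, t2)
        fm1 = lam * f1a + (1 - lam) * f1b
        fm2 = lam * f2a + (1 - lam) * f2b
        cm1 = lam * c1a + (1 - lam) * c1b
        cm2 = lam * c2a + (1 - lam) * c2b
        fsd = np.sqrt(np.maximum(fm2 - fm1**2, 1e-12))
        csd = np.sqrt(np.maximum(cm2 - cm1**2, 1e-12))
        floor_pen = (
            np.concatenate(
                [np.maximum(0.0, _FRACTION_FLOOR - f1a), np.maximum(0.0, _FRACTION_FLOOR - f1b)]
            )
            / _FRACTION_FLOOR
            * _FLOOR_WEIGHT
        )
        return np.concatenate(
            [
                (fm1 - abv_m) / abv_m,
                (cm1 - cross_m) / cross_m,
                _SD_WEIGHT * (fsd - abv_s) / abv_s,
                _SD_WEIGHT * (csd - cross_s) / cross_s,
                floor_pen,
            ]
        )

    m = abv_m / abv_m.sum()
    c0 = 9.0  # Dirichlet-like start
    base = np.array([np.log(max(c0 * m[i] - 2.0, 0.1)) for i in range(4)] + [0.0, 0.0, 0.0])
    # deterministic asymmetric start so the two components separate
    tilt = np.array([0.3, 0.0, 0.0, -0.3, 0.0, 0.0, 0.0])
    x0 = np.concatenate([base + tilt, base - tilt, [0.0]])
    lb = np.concatenate([np.full(14, -4.0), [-2.5]])
    ub = np.concatenate([np.full(14, 4.5), [2.5]])
    sol = optimize.least_squares(
        resid, x0, bounds=(lb, ub), xtol=1e-13, ftol=1e-13, max_nfev=6000
    )
    k1, t1 = _unpack_component(sol.x[:7])
    k2, t2 = _unpack_component(sol.x[7:14])
    lam = 1.0 / (1.0 + np.exp(-sol.x[14]))
    return float(lam), tuple(k1), tuple(t1), tuple(k2), tuple(t2)


class FractionSampler:
    """Draw per-subject (necrosis, solid, PT, edema)/ABV fraction vectors.

    Fractions come from a calibrated two-component mixture of normalized
    independent gammas; ``weight_``, ``shapes_`` (2x4) and ``scales_`` (2x4)
    hold the fitted parameters.
    """

    def __init__(self, preset: CohortPreset):
        self.preset = preset
        means = tuple(preset.ratio_targets[r][0] for r in RATIO_NAMES)
        sds = tuple(preset.ratio_targets[r][1] for r in RATIO_NAMES)
        lam, k1, t1, k2, t2 = _fit_fraction_params(means, sds)
        self.weight_ = lam
        self.shapes_ = np.array([k1, k2])
        self.scales_ = np.array([t1, t2])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = (rng.random(n) >= self.weight_).astype(int)  # 0 -> first component
        g = rng.gamma(self.shapes_[comp], self.scales_[comp])
        return g / g.sum(axis=1, keepdims=True)

    def expected_ratio_means(self) -> dict[str, float]:
        out = np.zeros(10)
        for w, k, th in (
            (self.weight_, self.shapes_[0], self.scales_[0]),
            (1.0 - self.weight_, self.shapes_[1], self.scales_[1]),
        ):
            fm1, _ = _gamma_frac_moments(k, th)
            cm1, _ = _gamma_cross_moments(k, th)
            out += w * np.concatenate([fm1, cm1])
        return dict(zip(RATIO_NAMES, out))


# --------------------------------------------------------------------------
# subject realization
# --------------------------------------------------------------------------


def _radial_modulation(grid_shape, spacing, center, perturbation, rng):
    """Smooth angular modulation field m(u) = 1 + eps*s(u), shared by all shells.

    Because every shell boundary is scaled by the same angular factor, habitat
    volume *fractions* are unchanged by the deformation (each directional
    volume element scales by m^3 for all shells alike).
    """
    idx = np.indices(grid_shape, dtype=np.float64)
    coords = [(idx[a] - center[a]) * spacing[a] for a in range(3)]
    r = np.sqrt(coords[0] ** 2 + coords[1] ** 2 + coords[2] ** 2)
    if perturbation == 0.0:
        return r, np.ones_like(r)
    rr = np.maximum(r, 1e-9)
    u = [c / rr for c in coords]
    # zero-mean band-limited function of direction: first + second harmonics
    v = rng.normal(size=(3, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = rng.normal(size=(3, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    c1 = rng.normal(size=3)
    c2 = rng.normal(size=3)
    s = np.zeros(grid_shape)
    for j in range(3):
        d1 = v[j, 0] * u[0] + v[j, 1] * u[1] + v[j, 2] * u[2]
        d2 = w[j, 0] * u[0] + w[j, 1] * u[1] + w[j, 2] * u[2]
        s += c1[j] * d1 + c2[j] * (d2**2 - 1.0 / 3.0)
    smax = np.abs(s).max()
    if smax > 0:
        s /= smax
    return r, 1.0 + perturbation * s


def _voxelize_shells(radii_mm, grid_shape, spacing, perturbation, rng) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in grid_shape]
    r, mod = _radial_modulation(grid_shape, spacing, center, perturbation, rng)
    rnorm = r / mod
    labels = np.zeros(grid_shape, dtype=np.int16)
    # outermost first, then overwrite inward
    for lbl, rad in ((4, radii_mm[3]), (3, radii_mm[2]), (2, radii_mm[1]), (1, radii_mm[0])):
        labels[rnorm <= rad] = lbl
    return labels


def _smooth_noise(shape, spacing, grain_mm, rng):
    noise = rng.normal(size=shape)
    sigma = [max(grain_mm / s, 1e-6) for s in spacing]
    sm = ndimage.gaussian_filter(noise, sigma=sigma)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _render_channels(labels, spacing, appearance: HabitatAppearanceConfig, rng):
    shape = labels.shape
    habitat_of = {1: "necrosis", 2: "solid", 3: "peritumoral_tissue", 4: "edema"}
    # habitat-shared texture fields (same spatial field added to every channel)
    texture = np.zeros(shape)
    idx = np.indices(shape, dtype=np.float64)
    for lbl, hab in habitat_of.items():
        tm = appearance.textures[hab]
        mask = labels == lbl
        if not mask.any() or tm.kind == "flat" or tm.amplitude == 0:
            continue
        if tm.kind == "speckle":
            fieldv = _smooth_noise(shape, spacing, tm.grain_mm, rng) * tm.amplitude
        else:  # stripe
            pos_mm = idx[tm.axis] * spacing[tm.axis]
            fieldv = tm.amplitude * np.sin(2 * np.pi * pos_mm / tm.period_mm)
        texture[mask] = fieldv[mask]

    bias = np.ones(shape)
    if appearance.bias_field_amplitude > 0:
        # low-order polynomial shading with random orientation
        zc = [(idx[a] - (shape[a] - 1) / 2) / shape[a] for a in range(3)]
        coef = rng.normal(size=6)
        poly = (
            coef[0] * zc[0] + coef[1] * zc[1] + coef[2] * zc[2]
            + coef[3] * zc[0] * zc[1] + coef[4] * zc[1] * zc[2] + coef[5] * zc[0] * zc[2]
        )
        pmax = np.abs(poly).max()
        if pmax > 0:
            poly /= pmax
        bias = 1.0 + appearance.bias_field_amplitude * poly

    channels = {}
    for ch in CHANNEL_NAMES:
        means = appearance.channel_means[ch]
        img = np.full(shape, float(means["background"]))
        for lbl, hab in habitat_of.items():
            img[labels == lbl] = means[hab]
        img = (img + texture) * bias
        if appearance.rician_sigma > 0:
            n1 = rng.normal(scale=appearance.rician_sigma, size=shape)
            n2 = rng.normal(scale=appearance.rician_sigma, size=shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        channels[ch] = img.astype(np.float32)
    return channels


class DegenerateGeometryError(ValueError):
    """A habitat voxelized to zero voxels at the given grid/spacing."""


def _realize_subject(
    radii_mm: np.ndarray,
    geometry: HabitatGeometryConfig,
    appearance: HabitatAppearanceConfig,
    seed_seq: np.random.SeedSequence,
    channels: bool = True,
):
    geom_seq, app_seq = seed_seq.spawn(2)
    rng_geom = np.random.default_rng(geom_seq)
    labels = _voxelize_shells(
        radii_mm, geometry.grid_shape, geometry.voxel_spacing, geometry.shape_perturbation, rng_geom
    )
    counts = {h: int(np.count_nonzero(labels == i + 1)) for i, h in enumerate(HABITAT_NAMES)}
    for hab, cnt in counts.items():
        if cnt == 0:
            raise DegenerateGeometryError(
                f"habitat {hab!r} has zero voxels at grid {geometry.grid_shape} "
                f"spacing {geometry.voxel_spacing}"
            )
    labelmap = HabitatLabelMap(labels=labels, voxel_spacing=geometry.voxel_spacing)
    volume = None
    if channels:
        rng_app = np.random.default_rng(app_seq)
        chans = _render_channels(labels, geometry.voxel_spacing, appearance, rng_app)
        volume = MultiParametricVolume(channels=chans, voxel_spacing=geometry.voxel_spacing)
    voxvol = float(np.prod(geometry.voxel_spacing))
    log = {
        "shell_radii_mm": [float(r) for r in radii_mm],
        "habitat_voxel_counts": counts,
        "habitat_volumes_mm3": {h: c * voxvol for h, c in counts.items()},
    }
    return volume, labelmap, log


def generate_subject(
    geometry: HabitatGeometryConfig | None = None,
    appearance: HabitatAppearanceConfig | None = None,
    seed: int = 0,
    return_log: bool = False,
):
    """Generate one phantom subject; deterministic for a fixed seed."""
    geometry = geometry or HabitatGeometryConfig()
    appearance = appearance or HabitatAppearanceConfig()
    volume, labelmap, log = _realize_subject(
        geometry.shell_radii_mm(), geometry, appearance, np.random.SeedSequence(seed)
    )
    if return_log:
        return volume, labelmap, log
    return volume, labelmap


def _radii_from_fractions(fractions: np.ndarray, abv_radius_mm: float) -> np.ndarray:
    """Shell radii realizing the given ABV fractions for (possibly deformed)
    concentric shells: cumulative volume fractions map to cubed radii."""
    cum = np.cumsum(fractions)
    cum = cum / cum[-1]
    return abv_radius_mm * np.cbrt(cum)


def generate_cohort(
    preset: CohortPreset,
    geometry: HabitatGeometryConfig | None = None,
    appearance: HabitatAppearanceConfig | None = None,
    seed: int = 0,
    n_subjects: int | None = None,
    channels: bool = True,
):
    """Generate a phantom cohort whose ratio means converge to preset targets.

    Returns ``(subjects, log)`` where ``subjects`` is a list of
    ``(MultiParametricVolume | None, HabitatLabelMap)`` pairs and ``log``
    records seeds, sampled fractions and true voxel-counted volumes.
    Set ``channels=False`` to produce label maps only (identical labels).
    """
    geometry = geometry or HabitatGeometryConfig(shape_perturbation=0.1)
    appearance = appearance or HabitatAppearanceConfig()
    n = preset.n_subjects if n_subjects is None else n_subjects
    sampler = FractionSampler(preset)  # raises before generation if unsatisfiable

    root = np.random.SeedSequence(seed)
    frac_seq, subj_root = root.spawn(2)
    rng = np.random.default_rng(frac_seq)
    fractions = sampler.sample(n, rng)
    mu, sig = preset.abv_radius_mm
    abv_radii = mu * np.exp(rng.normal(scale=sig, size=n))
    # keep the outer shell inside the grid with deformation headroom
    half_extent = min(
        gs * sp for gs, sp in zip(geometry.grid_shape, geometry.voxel_spacing)
    ) / 2.0
    r_cap = half_extent / (1.0 + geometry.shape_perturbation) - 2.0
    abv_radii = np.clip(abv_radii, 6.0, r_cap)

    subject_seqs = subj_root.spawn(n)
    subjects = []
    logs = []
    for i in range(n):
        radii = _radii_from_fractions(fractions[i], abv_radii[i])
        volume, labelmap, slog = _realize_subject(
            radii, geometry, appearance, subject_seqs[i], channels=channels
        )
        slog["sampled_fractions"] = [float(f) for f in fractions[i]]
        slog["abv_radius_mm"] = float(abv_radii[i])
        subjects.append((volume, labelmap))
        logs.append(slog)
    log = {
        "preset": preset.name,
        "seed": int(seed),
        "n_subjects": n,
        "sampler_weight": float(sampler.weight_),
        "sampler_shapes": sampler.shapes_.tolist(),
        "sampler_scales": sampler.scales_.tolist(),
        "subjects": logs,
    }
    return subjects, log


def write_cohort(directory: str | Path, subjects, log: dict) -> Path:
    """Write a generated cohort as per-subject NIfTI directories + a JSON log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (volume, labelmap) in enumerate(subjects):
        if volume is None:
            raise ValueError("cannot write a labels-only cohort as NIfTI subjects")
        write_subject(directory / f"subject_{i:04d}", volume, labelmap)
    log_path = directory / "generation_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    return log_path
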