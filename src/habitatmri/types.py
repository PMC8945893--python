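"""Core in-memory containers for multi-parametric MR volumes and habitat label maps.

Conventions used throughout the package:

* channels are ordered ``(t1ce, t2w, flair, adc)`` — gadolinium contrast-enhanced
  T1, T2-weighted, T2-FLAIR and the ADC map;
* habitat labels are ``0`` background, ``1`` necrosis, ``2`` solid (enhancing)
  tumor, ``3`` peritumoral tissue, ``4`` peritumoral edema;
* voxel indexing is 0-based, spacing is millimetres per axis, volumes are mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_NAMES: tuple[str, ...] = ("t1ce", "t2w", "flair", "adc")

HABITAT_LABELS: dict[int, str] = {
    0: "background",
    1: "necrosis",
    2: "solid",
    3: "peritumoral_tissue",
    4: "edema",
}
HABITAT_NAMES: tuple[str, ...] = ("necrosis", "solid", "peritumoral_tissue", "edema")
TUMOR_LABELS: tuple[int, ...] = (1, 2, 3, 4)


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class MultiParametricVolume:
    """Four co-registered 3D scalar channels sharing shape, spacing and affine."""

    channels: dict[str, np.ndarray]
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_NAMES if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        # normalize channel order regardless of input dict ordering
        self.channels = {c: np.asarray(self.channels[c]) for c in CHANNEL_NAMES}
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels["t1ce"].shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        return self.channels[name]


@dataclass
class HabitatLabelMap:
    """Integer habitat map on the same grid as its companion volume.

    Legend: 0 background, 1 necrosis, 2 solid tumor, 3 peritumoral tissue,
    4 peritumoral edema.
    """

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    legend: dict[int, str] = field(default_factory=lambda: dict(HABITAT_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"labels must be integer, got {self.labels.dtype}")
        extra = set(np.unique(self.labels)) - set(HABITAT_LABELS)
        if extra:
            raise ValueError(f"labels outside {{0..4}}: {sorted(int(v) for v in extra)}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))
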