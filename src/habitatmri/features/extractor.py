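"""Assembly of the full 1316-feature per-habitat radiomic vector.

Family layout (fixed order, fixed cardinalities):
32 geometry + 64 first-order histogram + 64 LBP histogram + 88 GLCM
+ 44 GLRLM + 1024 SIFT bag-of-visual-words = 1316.

Geometry is computed from the habitat mask; intensity, texture and SIFT
features are computed on a single designated channel (default T1-CE, the
post-contrast sequence the annotations were drawn on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..io import habitat_mask
from ..types import HABITAT_LABELS, HabitatLabelMap, MultiParametricVolume
from .geometry import GEOMETRY_FEATURE_NAMES, geometry_features
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .glrlm import GLRLM_FEATURE_NAMES, glrlm_features
from .intensity import FIRST_ORDER_NAMES, LBP_NAMES, first_order_features, lbp_histogram
from .sift import (
    DEFAULT_WORDS,
    VisualWordCodebook,
    build_codebook,
    region_descriptors,
    sift_features,
)

FAMILY_SIZES: dict[str, int] = {
    "geometry": 32,
    "first_order": 64,
    "lbp": 64,
    "glcm": 88,
    "glrlm": 44,
    "sift": 1024,
}
TOTAL_FEATURES = sum(FAMILY_SIZES.values())  # 1316


def feature_names(n_words: int = DEFAULT_WORDS) -> list[str]:
    names = list(GEOMETRY_FEATURE_NAMES)
    names += list(FIRST_ORDER_NAMES)
    names += list(LBP_NAMES)
    names += list(GLCM_FEATURE_NAMES)
    names += list(GLRLM_FEATURE_NAMES)
    names += [f"sift_word{i:04d}" for i in range(n_words)]
    return names


def family_slices(n_words: int = DEFAULT_WORDS) -> dict[str, slice]:
    out = {}
    start = 0
    for fam, size in FAMILY_SIZES.items():
        size = n_words if fam == "sift" else size
        out[fam] = slice(start, start + size)
        start += size
    return out


@dataclass
class RegionFeatureVector:
    names: list[str]
    values: np.ndarray
    habitat: int
    channel: str

    def __len__(self) -> int:
        return len(self.values)

    def family(self, fam: str) -> np.ndarray:
        n_words = len(self.values) - (TOTAL_FEATURES - FAMILY_SIZES["sift"])
        return self.values[family_slices(n_words)[fam]]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def extract_all(
    volume: MultiParametricVolume,
    labelmap: HabitatLabelMap,
    habitat: int,
    codebook: VisualWordCodebook,
    channel: str = "t1ce",
    levels: int = 64,
    sift_stride: int = 4,
) -> RegionFeatureVector:
    """Extract the full per-habitat feature vector (length 1316)."""
    mask = habitat_mask(labelmap, habitat)
    if not mask.any():
        raise ValueError(
            f"habitat {habitat} ({HABITAT_LABELS.get(habitat)}) not present in label map"
        )
    img = volume.channel(channel)
    parts = [
        np.array(list(geometry_features(mask, labelmap.voxel_spacing).values())),
        first_order_features(img, mask, levels=levels),
        lbp_histogram(img, mask),
        np.array(list(glcm_features(img, mask, levels=levels).values())),
        np.array(list(glrlm_features(img, mask, levels=levels).values())),
        sift_features(img, mask, codebook, stride=sift_stride),
    ]
    values = np.concatenate(parts)
    return RegionFeatureVector(
        names=feature_names(codebook.n_words), values=values, habitat=habitat, channel=channel
    )


class RegionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Per-habitat radiomic feature extraction as a scikit-learn transformer.

    ``fit`` learns the SIFT visual-word codebook from the training subjects'
    tumor regions (all four habitats pooled); ``transform`` returns one row of
    1316 named features per subject x habitat.

    Parameters
    ----------
    channel : str
        Channel for intensity/texture/SIFT features (default "t1ce").
    levels : int
        Gray levels for quantization (default 64).
    n_words : int
        Visual-word count (default 1024).
    sift_stride : int
        Dense keypoint stride in pixels.
    random_state : int
        Codebook k-means seed.
    """

    def __init__(
        self,
        channel: str = "t1ce",
        levels: int = 64,
        n_words: int = DEFAULT_WORDS,
        sift_stride: int = 4,
        random_state: int = 0,
    ):
        self.channel = channel
        self.levels = levels
        self.n_words = n_words
        self.sift_stride = sift_stride
        self.random_state = random_state

    def fit(self, subjects, y=None):
        """``subjects`` is a sequence of (MultiParametricVolume, HabitatLabelMap)."""
        descs = []
        for volume, labelmap in subjects:
            img = volume.channel(self.channel)
            descs.append(
                region_descriptors(img, labelmap.labels > 0, stride=self.sift_stride)
            )
        all_descs = np.vstack([d for d in descs if len(d)]) if descs else np.empty((0, 128))
        self.codebook_ = build_codebook(
            all_descs, seed=self.random_state, n_words=self.n_words
        )
        self.feature_names_ = feature_names(self.n_words)
        return self

    def transform(self, subjects, habitats=(1, 2, 3, 4)) -> pd.DataFrame:
        rows = []
        index = []
        for si, (volume, labelmap) in enumerate(subjects):
            for hab in habitats:
                vec = extract_all(
                    volume,
                    labelmap,
                    hab,
                    self.codebook_,
                    channel=self.channel,
                    levels=self.levels,
                    sift_stride=self.sift_stride,
                )
                rows.append(vec.values)
                index.append((si, HABITAT_LABELS[hab]))
        return pd.DataFrame(
            rows,
            columns=self.feature_names_,
            index=pd.MultiIndex.from_tuples(index, names=["subject", "habitat"]),
        )
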