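"""NIfTI subject I/O with co-registration and label-convention checks.

A subject on disk is a directory holding one NIfTI file per channel plus a
label file, described by a ``manifest.json`` mapping channel names to file
names.  All images are reoriented to the closest canonical (RAS) axes on load
so downstream axis conventions are unambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import CHANNEL_NAMES, HABITAT_LABELS, HabitatLabelMap, MultiParametricVolume


class CoregistrationError(ValueError):
    """Raised when a channel does not share the reference grid."""


class LabelError(ValueError):
    """Raised when a label volume contains values outside {0..4}."""


MANIFEST_NAME = "manifest.json"
LABELS_KEY = "labels"

# accepted aliases when reading manifests written by other tools
_CHANNEL_ALIASES = {
    "t1ce": "t1ce", "t1-ce": "t1ce", "t1_ce": "t1ce", "t1gd": "t1ce",
    "t2w": "t2w", "t2": "t2w", "t2-wi": "t2w", "t2wi": "t2w",
    "flair": "flair", "t2-flair": "flair", "t2flair": "flair",
    "adc": "adc",
}


def _load_canonical(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), spacing


def write_subject(
    directory: str | Path,
    volume: MultiParametricVolume,
    labelmap: HabitatLabelMap,
    extra_metadata: dict | None = None,
) -> Path:
    """Write channels + labels as .nii.gz files and a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"channels": {}, LABELS_KEY: "labels.nii.gz"}
    for name in CHANNEL_NAMES:
        fname = f"{name}.nii.gz"
        img = nib.Nifti1Image(volume.channel(name).astype(np.float32), volume.affine)
        img.header.set_zooms(volume.voxel_spacing)
        nib.save(img, str(directory / fname))
        manifest["channels"][name] = fname
    lab = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    lab.header.set_zooms(labelmap.voxel_spacing)
    nib.save(lab, str(directory / "labels.nii.gz"))
    if extra_metadata:
        manifest["metadata"] = extra_metadata
    mpath = directory / MANIFEST_NAME
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_subject(directory: str | Path) -> tuple[MultiParametricVolume, HabitatLabelMap]:
    """Read and validate a co-registered subject.

    Raises
    ------
    CoregistrationError
        if any channel (or the label map) disagrees with the T1-CE grid in
        shape, spacing or affine.
    LabelError
        if the label volume contains values outside ``{0..4}``.
    """
    directory = Path(directory)
    mpath = directory / MANIFEST_NAME
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        channel_files = {
            _CHANNEL_ALIASES[k.lower()]: v for k, v in manifest["channels"].items()
        }
        label_file = manifest[LABELS_KEY]
    else:  # fall back to conventional file names
        channel_files = {c: f"{c}.nii.gz" for c in CHANNEL_NAMES}
        label_file = "labels.nii.gz"
    missing = [c for c in CHANNEL_NAMES if c not in channel_files]
    if missing:
        raise FileNotFoundError(f"manifest lacks channels {missing}")

    channels: dict[str, np.ndarray] = {}
    ref_affine = ref_spacing = ref_shape = None
    for name in CHANNEL_NAMES:
        data, affine, spacing = _load_canonical(directory / channel_files[name])
        if ref_affine is None:
            ref_affine, ref_spacing, ref_shape = affine, spacing, data.shape
        else:
            if data.shape != ref_shape or not np.allclose(affine, ref_affine, atol=1e-4):
                raise CoregistrationError(
                    f"channel {name!r} is not co-registered with t1ce: "
                    f"shape {data.shape} vs {ref_shape}"
                )
        channels[name] = data.astype(np.float32)

    lab_data, lab_affine, lab_spacing = _load_canonical(directory / label_file)
    if lab_data.shape != ref_shape or not np.allclose(lab_affine, ref_affine, atol=1e-4):
        raise CoregistrationError(
            f"label map is not co-registered: shape {lab_data.shape} vs {ref_shape}"
        )
    lab_int = np.rint(lab_data).astype(np.int16)
    bad = set(np.unique(lab_int)) - set(HABITAT_LABELS)
    if bad:
        raise LabelError(f"labels outside {{0..4}}: {sorted(int(v) for v in bad)}")

    volume = MultiParametricVolume(channels=channels, voxel_spacing=ref_spacing, affine=ref_affine)
    labelmap = HabitatLabelMap(labels=lab_int, voxel_spacing=lab_spacing, affine=lab_affine)
    return volume, labelmap


def habitat_mask(labelmap: HabitatLabelMap, habitat: int) -> np.ndarray:
    """Boolean mask of one habitat; ``habitat`` must be in {1..4}."""
    if habitat not in (1, 2, 3, 4):
        raise ValueError(f"habitat must be in {{1..4}}, got {habitat}")
    return labelmap.labels == habitat


def validate_subject(directory: str | Path) -> dict:
    """Validate a subject directory; returns a summary dict (raises on failure)."""
    volume, labelmap = read_subject(directory)
    counts = {
        name: int(np.count_nonzero(labelmap.labels == lbl))
        for lbl, name in HABITAT_LABELS.items()
        if lbl != 0
    }
    return {
        "shape": list(volume.shape),
        "voxel_spacing_mm": list(volume.voxel_spacing),
        "habitat_voxel_counts": counts,
    }
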