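"""Slice extraction and per-slice pre-processing.

Each 3D volume yields 24 two-dimensional sections: 8 per anatomical plane
(axial, coronal, sagittal), taken at fixed fractional depths so that slice
positions depend only on the axis length, never on image content.  Sections
are bilinearly resized to 156 x 156, min-max normalized to [0, 1] and finally
quantized to 8 gray levels for co-occurrence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import nibabel as nib
from skimage.transform import resize as _sk_resize

from braintex.synthetic_data import BrainVolume

PLANES = ("axial", "coronal", "sagittal")
#: axis sliced through, for a volume indexed (x, y, z)
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}
#: fractional depths of the 8 standard slices: 0.15, 0.25, ..., 0.85
SLICE_FRACTIONS = tuple(np.linspace(0.15, 0.85, 8))
DEFAULT_SIDE = 156
DEFAULT_LEVELS = 8


@dataclass
class SliceImage:
    subject_id: str
    plane: str
    slice_index: int
    pixels: np.ndarray  # side x side, values in [0, 1]


@dataclass
class QuantizedSlice:
    subject_id: str
    plane: str
    slice_index: int
    levels: np.ndarray  # side x side integers in {1, ..., n_levels}


def slice_positions(axis_length: int, n_slices: int = 8) -> list[int]:
    """Integer slice indices: round(f * (axis_length - 1)) at the standard depths."""
    if n_slices == len(SLICE_FRACTIONS):
        fracs = SLICE_FRACTIONS
    else:
        fracs = np.linspace(0.15, 0.85, n_slices)
    return [int(round(f * (axis_length - 1))) for f in fracs]


def extract_slices(volume: BrainVolume | np.ndarray, plane: str,
                   n_slices: int = 8) -> list[np.ndarray]:
    """Cut ``n_slices`` 2D sections perpendicular to the plane's axis."""
    if plane not in _PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    voxels = volume.voxels if isinstance(volume, BrainVolume) else np.asarray(volume)
    axis = _PLANE_AXIS[plane]
    length = voxels.shape[axis]
    if not 1 <= n_slices <= length:
        raise ValueError(f"n_slices={n_slices} outside [1, {length}]")
    return [np.take(voxels, idx, axis=axis) for idx in slice_positions(length, n_slices)]


def resize_to_square(section: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Bilinear resize to ``side x side``; constants are preserved exactly."""
    if side < 2:
        raise ValueError("side must be >= 2")
    section = np.asarray(section, dtype=np.float64)
    if section.size == 0:
        raise ValueError("empty input section")
    return _sk_resize(section, (side, side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def normalize_unit(section: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; an all-constant section maps to all zeros."""
    section = np.asarray(section, dtype=np.float64)
    if not np.all(np.isfinite(section)):
        raise ValueError("section contains non-finite pixels")
    lo, hi = section.min(), section.max()
    if hi == lo:
        return np.zeros_like(section)
    return (section - lo) / (hi - lo)


def quantize(slice_image: SliceImage, n_levels: int = DEFAULT_LEVELS) -> QuantizedSlice:
    """Linear min-max binning of the slice into ``n_levels`` gray levels 1..n.

    Bin edges split [min, max] of this slice into equal widths (the gray-limit
    convention of standard co-occurrence routines); the maximum maps to level
    ``n_levels`` and a constant slice maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    px = np.asarray(slice_image.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        levels = np.ones(px.shape, dtype=np.int64)
    else:
        levels = np.floor((px - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        np.clip(levels, 1, n_levels, out=levels)
    return QuantizedSlice(slice_image.subject_id, slice_image.plane,
                          slice_image.slice_index, levels)


def slices_for_volume(volume: BrainVolume, planes=PLANES, n_slices: int = 8,
                      side: int = DEFAULT_SIDE, via_png: bool = False) -> list[SliceImage]:
    """Full per-volume slice pipeline: extract, resize, normalize.

    With ``via_png`` the pixel grid is additionally rounded through 8-bit
    (0-255) before the final [0, 1] normalization, emulating a PNG
    intermediate on disk.
    """
    out: list[SliceImage] = []
    for plane in planes:
        for k, section in enumerate(extract_slices(volume, plane, n_slices)):
            img = normalize_unit(resize_to_square(section, side))
            if via_png:
                img = normalize_unit(np.round(img * 255.0))
            out.append(SliceImage(volume.subject_id, plane, k, img))
    return out


def save_png(slice_image: SliceImage, directory: str | Path) -> Path:
    """Export one slice as 8-bit grayscale ``<subject>_<plane>_<k>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{slice_image.subject_id}_{slice_image.plane}_{slice_image.slice_index}.png"
    iio.imwrite(path, np.round(slice_image.pixels * 255.0).astype(np.uint8))
    return path


def load_volume(path: str | Path, subject_id: str | None = None,
                group: str = "") -> BrainVolume:
    """Read a skull-stripped NIfTI-1 volume from disk."""
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else Path(path).stem
    return BrainVolume(subject_id=sid, group=group, voxels=voxels, voxel_size_mm=zooms)
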