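"""End-to-end helpers: cohort of volumes -> assembled feature matrix."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from braintex.synthetic_data import BrainVolume
from braintex.volume_prep import PLANES, quantize, slices_for_volume
from braintex.glcm_features import (
    FEATURE_NAMES,
    OFFSET_LABELS,
    features_for_slice,
)
from braintex.dataset_assembly import SliceFeatures, SubjectFeatureMatrix, assemble


def slice_features_for_volume(volume: BrainVolume, planes: Sequence[str] = PLANES,
                              n_slices: int = 8, side: int = 156,
                              n_levels: int = 8,
                              via_png: bool = False) -> list[SliceFeatures]:
    """Slice one volume and compute the 22 x 4 texture block per slice."""
    out = []
    for img in slices_for_volume(volume, planes, n_slices, side, via_png=via_png):
        q = quantize(img, n_levels)
        out.append(SliceFeatures(volume.subject_id, volume.group, img.plane,
                                 img.slice_index, features_for_slice(q)))
    return out


def extract_cohort_features(volumes: Iterable[BrainVolume],
                            planes: Sequence[str] = PLANES,
                            n_slices: int = 8, side: int = 156,
                            n_levels: int = 8,
                            via_png: bool = False) -> SubjectFeatureMatrix:
    """Full feature-extraction pipeline for a cohort of volumes."""
    feats: list[SliceFeatures] = []
    for v in volumes:
        feats.extend(slice_features_for_volume(v, planes, n_slices, side,
                                               n_levels, via_png))
    return assemble(feats, plane_set=planes, n_slices=n_slices)


def tidy_slice_features(feats: Iterable[SliceFeatures]) -> pd.DataFrame:
    """Long-format table: subject_id, plane, slice_index, feature, offset, value."""
    rows = []
    for sf in feats:
        for fi, feat in enumerate(FEATURE_NAMES):
            for oi, off in enumerate(OFFSET_LABELS):
                rows.append((sf.subject_id, sf.plane, sf.slice_index,
                             feat, off, sf.values[fi, oi]))
    return pd.DataFrame(rows, columns=["subject_id", "plane", "slice_index",
                                       "feature", "offset", "value"])
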