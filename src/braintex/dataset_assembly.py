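"""Assembly of subjects-x-features matrices and column-wise z-scoring.

Feature columns are ordered plane-major (axial, coronal, sagittal), then
slice index 0-7, then the fixed texture-feature order, then offset order —
giving 22 x 4 x 8 = 704 columns per plane and 2112 for all three planes.
Column names encode the full provenance as ``plane.slice.feature.offset``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from braintex.volume_prep import PLANES
from braintex.glcm_features import FEATURE_NAMES, OFFSET_LABELS


class AssemblyError(ValueError):
    """A subject is missing required slice features."""


@dataclass
class SliceFeatures:
    """Texture features of one slice: array of shape (22, 4)."""

    subject_id: str
    group: str
    plane: str
    slice_index: int
    values: np.ndarray


@dataclass
class SubjectFeatureMatrix:
    """Subjects-by-features table with group labels and column provenance."""

    data: pd.DataFrame      # index: subject_id; columns: plane.slice.feature.offset
    groups: pd.Series       # aligned with data.index
    plane_set: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_groups(self, groups: Iterable[str]) -> "SubjectFeatureMatrix":
        """Row subset for a pairwise (or any) group comparison."""
        keep = self.groups.isin(list(groups))
        return SubjectFeatureMatrix(self.data.loc[keep.values],
                                    self.groups.loc[keep.values], self.plane_set)

    def subset_planes(self, plane_set: Iterable[str]) -> "SubjectFeatureMatrix":
        """Column subset restricted to ``plane_set`` (order kept plane-major)."""
        plane_set = tuple(p for p in PLANES if p in set(plane_set))
        cols = [c for c in self.data.columns if c.split(".", 1)[0] in plane_set]
        return SubjectFeatureMatrix(self.data[cols], self.groups, plane_set)


def column_order(plane_set: Iterable[str], n_slices: int = 8) -> list[str]:
    """Deterministic column labels: plane-major, slice, feature, offset."""
    planes = tuple(p for p in PLANES if p in set(plane_set))
    return [
        f"{plane}.{k}.{feat}.{off}"
        for plane in planes
        for k in range(n_slices)
        for feat in FEATURE_NAMES
        for off in OFFSET_LABELS
    ]


def assemble(slice_features: Iterable[SliceFeatures],
             plane_set: Iterable[str] = PLANES,
             n_slices: int = 8) -> SubjectFeatureMatrix:
    """Build the subjects-x-features matrix from per-slice feature blocks.

    Every subject must contribute all ``n_slices`` slices of every plane in
    ``plane_set``; a missing slice raises :class:`AssemblyError` naming the
    subject.  Input order is irrelevant to the result.
    """
    plane_set = tuple(p for p in PLANES if p in set(plane_set))
    cols = column_order(plane_set, n_slices)
    per_subject: dict[str, dict[str, np.ndarray]] = {}
    groups: dict[str, str] = {}
    for sf in slice_features:
        if sf.plane not in plane_set:
            continue
        key = f"{sf.plane}.{sf.slice_index}"
        per_subject.setdefault(sf.subject_id, {})[key] = np.asarray(sf.values)
        groups[sf.subject_id] = sf.group

    subject_ids = sorted(per_subject)
    rows = np.empty((len(subject_ids), len(cols)))
    block_keys = [f"{p}.{k}" for p in plane_set for k in range(n_slices)]
    for r, sid in enumerate(subject_ids):
        blocks = per_subject[sid]
        missing = [k for k in block_keys if k not in blocks]
        if missing:
            raise AssemblyError(f"subject {sid} is missing slices: {missing}")
        # each block flattens feature-major then offset, matching column_order
        rows[r] = np.concatenate([blocks[k].ravel() for k in block_keys])
    data = pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"),
                        columns=cols)
    grp = pd.Series([groups[s] for s in subject_ids], index=data.index, name="group")
    return SubjectFeatureMatrix(data=data, groups=grp, plane_set=plane_set)


def zscore_columns(m: SubjectFeatureMatrix) -> SubjectFeatureMatrix:
    """Standardize each column to mean 0 / SD 1 (SD with denominator n-1).

    Zero-variance columns become all zeros.  Requires at least two rows.
    """
    if m.data.shape[0] < 2:
        raise ValueError("z-scoring needs >= 2 rows (column SD undefined)")
    vals = m.data.to_numpy(dtype=np.float64)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    out = np.zeros_like(vals)
    nz = sd > 0
    out[:, nz] = (vals[:, nz] - mean[nz]) / sd[nz]
    return SubjectFeatureMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        m.groups, m.plane_set)


def fit_column_scaler(train: pd.DataFrame):
    """Column mean/SD fitted on training rows only (leakage-free variant)."""
    vals = train.to_numpy(dtype=np.float64)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)

    def transform(df: pd.DataFrame) -> pd.DataFrame:
        scaled = (df.to_numpy(dtype=np.float64) - mean) / sd_safe
        scaled[:, sd == 0] = 0.0
        return pd.DataFrame(scaled, index=df.index, columns=df.columns)

    return transform


def write_matrix_csv(m: SubjectFeatureMatrix, values_path, labels_path=None) -> None:
    """Persist the matrix (and optionally row labels) as CSV."""
    m.data.to_csv(values_path, float_format="%.10g")
    if labels_path is not None:
        m.groups.to_frame().to_csv(labels_path)
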