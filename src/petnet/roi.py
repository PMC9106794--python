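"""Region-mean extraction from a volumetric SUV image plus a label map.

Consumes the product of a delineation step: a 3-D SUV volume and an
integer label volume of the same shape, with a mapping from labels to
region names. Volumes are consumed in voxel space; mismatched shapes or
affines are an error rather than being silently resampled, because
interpolating SUVs changes regional means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .data import SubjectRecord
from .regions import RegionSet

__all__ = ["LabelMapSpec", "extract_region_means", "extract_from_nifti"]


@dataclass(frozen=True)
class LabelMapSpec:
    """Mapping from integer voxel labels to region names.

    ``background_labels`` (default {0}) are ignored; they must be
    disjoint from the mapped labels, and no region may be mapped by more
    than one label.
    """

    label_to_region: Mapping[int, str]
    background_labels: frozenset[int] = field(default_factory=lambda: frozenset({0}))

    def __post_init__(self) -> None:
        mapping = {int(k): str(v) for k, v in self.label_to_region.items()}
        object.__setattr__(self, "label_to_region", mapping)
        object.__setattr__(self, "background_labels", frozenset(self.background_labels))
        overlap = set(mapping) & self.background_labels
        if overlap:
            raise ValueError(f"labels {sorted(overlap)} are both mapped and background")
        regions = list(mapping.values())
        dupes = sorted({r for r in regions if regions.count(r) > 1})
        if dupes:
            raise ValueError(f"region(s) mapped by more than one label: {dupes}")

    def validate_regions(self, region_set: RegionSet) -> None:
        mapped = set(self.label_to_region.values())
        missing = [r for r in region_set if r not in mapped]
        if missing:
            raise ValueError(f"no label mapped for region(s): {missing}")


def extract_region_means(
    suv_image: np.ndarray,
    labels: np.ndarray,
    spec: LabelMapSpec,
    aggregate: str = "mean",
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-region aggregate SUV over the voxels carrying each label.

    Returns ``(region -> value, region -> voxel count)``. The default
    aggregate is the arithmetic mean (what a regional SUV_mean is);
    ``aggregate="median"`` is available for robustness studies. Regions
    with zero voxels are an error listing them; labels present in the
    volume but unmapped produce a warning.
    """
    suv = np.asarray(suv_image, dtype=float)
    lab = np.asarray(labels)
    if not np.issubdtype(lab.dtype, np.integer):
        if not np.all(lab == np.round(lab)):
            raise ValueError("label volume must contain integers")
        lab = lab.astype(np.int64)
    if suv.shape != lab.shape:
        raise ValueError(
            f"image shape {suv.shape} does not match label shape {lab.shape}"
        )
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    present = set(int(v) for v in np.unique(lab))
    known = set(spec.label_to_region) | spec.background_labels
    unmapped = sorted(present - known)
    if unmapped:
        warnings.warn(f"unmapped label(s) present in volume: {unmapped}", stacklevel=2)
    values: dict[str, float] = {}
    counts: dict[str, int] = {}
    empty = []
    agg = np.mean if aggregate == "mean" else np.median
    for label, region in spec.label_to_region.items():
        mask = lab == label
        n = int(mask.sum())
        counts[region] = n
        if n == 0:
            empty.append(region)
        else:
            values[region] = float(agg(suv[mask]))
    if empty:
        raise ValueError(f"no voxels for region(s): {empty}")
    return values, counts


def extract_from_nifti(
    image_path: str | Path,
    labels_path: str | Path,
    spec: LabelMapSpec,
    subject_id: str,
    age: float,
    sex: int,
    region_set: RegionSet | None = None,
    aggregate: str = "mean",
    affine_tol: float = 1e-4,
) -> SubjectRecord:
    """Build a :class:`SubjectRecord` from NIfTI SUV and label volumes.

    The two volumes must share shape and affine (to ``affine_tol``);
    no resampling is performed. When ``region_set`` is given, the label
    map must cover it completely.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    lab = nib.load(str(labels_path))
    if not np.allclose(img.affine, lab.affine, atol=affine_tol):
        raise ValueError(
            f"affine mismatch between {image_path} and {labels_path}; "
            "resample upstream if this is intended"
        )
    if region_set is not None:
        spec.validate_regions(region_set)
    values, _ = extract_region_means(
        np.asanyarray(img.dataobj), np.asanyarray(lab.dataobj), spec, aggregate
    )
    return SubjectRecord(subject_id=subject_id, age=age, sex=sex, suv=values)
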