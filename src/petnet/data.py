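"""Subject and cohort containers.

A :class:`SubjectRecord` holds one subject's covariates and mean SUV per
region; a :class:`CohortTable` aligns a list of subjects into an
``N_subjects x M`` SUV matrix plus an ``N_subjects x C`` covariate matrix
(age and sex by default), the inputs every network construction consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .regions import RegionSet

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identity, covariates, and per-region mean SUV.

    ``suv`` must cover every region of the cohort's :class:`RegionSet`
    exactly once with finite, non-negative values. ``weight`` (kg) and
    ``dose`` (MBq) are carried as metadata only; SUV normalisation by dose
    and weight happens upstream of this package.
    """

    subject_id: str
    age: float
    sex: int
    suv: Mapping[str, float]
    weight: float | None = None
    dose: float | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be a positive real, got {self.age}")
        if self.sex not in (0, 1):
            raise ValueError(f"{self.subject_id}: sex must be coded 0/1, got {self.sex!r}")
        for check, name in ((self.weight, "weight"), (self.dose, "dose")):
            if check is not None and (not np.isfinite(check) or check <= 0):
                raise ValueError(f"{self.subject_id}: {name} must be positive, got {check}")
        suv = dict(self.suv)
        for region, value in suv.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.subject_id}: SUV for {region!r} must be finite and >= 0, got {value}"
                )
            suv[region] = v
        object.__setattr__(self, "suv", suv)

    def suv_vector(self, region_set: RegionSet) -> np.ndarray:
        """SUVs ordered by ``region_set``; raises on any missing region."""
        missing = [r for r in region_set if r not in self.suv]
        if missing:
            raise ValueError(f"{self.subject_id}: missing SUV for regions {missing}")
        return np.array([self.suv[r] for r in region_set], dtype=float)


@dataclass(frozen=True)
class CohortTable:
    """Aligned subjects x regions SUV matrix with covariates.

    Rows of ``suv_matrix`` follow ``subjects`` order; columns follow
    ``region_set`` order. Covariates default to (age, sex). Missing cells
    are rejected outright — the data model has none — and any region whose
    column is constant across a cohort of >= 3 subjects is an error,
    because a zero-variance column has no defined correlation.
    """

    subjects: tuple[SubjectRecord, ...]
    region_set: RegionSet
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    suv_matrix: np.ndarray = field(init=False, repr=False)
    covariates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        object.__setattr__(self, "subjects", subjects)
        if not subjects:
            raise ValueError("cohort must contain at least one subject")
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id: {dupes}")
        suv = np.vstack([s.suv_vector(self.region_set) for s in subjects])
        cov = np.column_stack(
            [[getattr(s, name) for s in subjects] for name in self.covariate_names]
        ).astype(float)
        suv.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "suv_matrix", suv)
        object.__setattr__(self, "covariates", cov)
        if len(subjects) >= 2:
            constant = [
                self.region_set.names[j]
                for j in range(suv.shape[1])
                if np.ptp(suv[:, j]) == 0.0
            ]
            if constant:
                if len(subjects) >= 3:
                    raise ValueError(f"zero-variance region column(s): {constant}")
                warnings.warn(
                    f"zero-variance region column(s) in small cohort: {constant}",
                    stacklevel=2,
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.subjects)

    def region_means(self) -> np.ndarray:
        """Per-region mean SUV across the cohort, in region order."""
        return self.suv_matrix.mean(axis=0)

    def subset(self, indices: Sequence[int]) -> "CohortTable":
        """New cohort from a subset (or permutation) of subject rows."""
        return CohortTable(
            subjects=tuple(self.subjects[int(i)] for i in indices),
            region_set=self.region_set,
            covariate_names=self.covariate_names,
        )

    def drop(self, subject_id: str) -> "CohortTable":
        """New cohort without the named subject."""
        keep = [s for s in self.subjects if s.subject_id != subject_id]
        if len(keep) == len(self.subjects):
            raise KeyError(f"subject {subject_id!r} not in cohort")
        return CohortTable(tuple(keep), self.region_set, self.covariate_names)

    def with_subject(self, subject: SubjectRecord) -> "CohortTable":
        """New cohort with ``subject`` appended (distinct id required)."""
        if subject.subject_id in self.subject_ids:
            raise ValueError(f"subject {subject.subject_id!r} already in cohort")
        return CohortTable(
            self.subjects + (subject,), self.region_set, self.covariate_names
        )
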