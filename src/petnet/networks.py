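"""Network containers and canonical edge-vector helpers.

All networks are symmetric M x M matrices over a shared :class:`RegionSet`
with the diagonal fixed to 0 (self-edges are never used). Vectorised
statistics operate on the canonical edge vector: the row-major upper
triangle of the matrix, length M*(M-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .regions import RegionSet

_SYM_TOL = 1e-12


def _as_symmetric(matrix: np.ndarray, m: int, what: str) -> np.ndarray:
    a = np.asarray(matrix, dtype=float)
    if a.shape != (m, m):
        raise ValueError(f"{what}: expected shape ({m}, {m}), got {a.shape}")
    if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{what}: matrix is not symmetric")
    if np.any(np.diag(a) != 0.0):
        raise ValueError(f"{what}: diagonal must be exactly 0")
    a = 0.5 * (a + a.T)  # exact symmetry after tolerance check
    np.fill_diagonal(a, 0.0)
    a.setflags(write=False)
    return a


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Canonical edge vector: row-major upper triangle, diagonal excluded."""
    a = np.asarray(matrix)
    iu, ju = np.triu_indices(a.shape[0], k=1)
    return a[iu, ju]


def from_upper_triangle(edges: np.ndarray, m: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from its edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.size != m * (m - 1) // 2:
        raise ValueError(f"edge vector length {edges.size} != {m}*({m}-1)/2")
    out = np.zeros((m, m))
    iu, ju = np.triu_indices(m, k=1)
    out[iu, ju] = edges
    out[ju, iu] = edges
    return out


@dataclass(frozen=True)
class CorrelationNetwork:
    """Partial-correlation network (serves as refNET, ptbNET and patNET).

    Off-diagonal entries are partial Pearson correlations in [-1, 1];
    ``n_subjects`` records how many subjects the network was estimated
    from and ``covariate_names`` which covariates were regressed out.
    """

    matrix: np.ndarray
    region_set: RegionSet
    n_subjects: int
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = _as_symmetric(self.matrix, self.region_set.m, "CorrelationNetwork")
        off = upper_triangle(a)
        if np.any(~np.isfinite(off)) or np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("correlations must be finite and within [-1, 1]")
        object.__setattr__(self, "matrix", a)

    def edge_vector(self) -> np.ndarray:
        return upper_triangle(self.matrix)


@dataclass(frozen=True)
class ResidualNetwork:
    """Thresholded difference ptbNET - refNET (resNET).

    Entries eliminated by the threshold are exactly 0; surviving entries
    are differences of correlations, hence in [-2, 2].
    """

    matrix: np.ndarray
    region_set: RegionSet
    threshold_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_fraction <= 1.0:
            raise ValueError(
                f"threshold_fraction must be in [0, 1], got {self.threshold_fraction}"
            )
        a = _as_symmetric(self.matrix, self.region_set.m, "ResidualNetwork")
        off = upper_triangle(a)
        if np.any(~np.isfinite(off)) or np.any(np.abs(off) > 2.0 + 1e-12):
            raise ValueError("residual entries must be finite and within [-2, 2]")
        object.__setattr__(self, "matrix", a)

    def edge_vector(self) -> np.ndarray:
        return upper_triangle(self.matrix)


@dataclass(frozen=True)
class ZScoreNetwork:
    """Edge-wise abnormality Z-scores (ZCC) for one scored subject.

    ``n_group`` is the size of the augmented group (controls + 1) that the
    perturbed network was built from.
    """

    matrix: np.ndarray
    region_set: RegionSet
    n_group: int

    def __post_init__(self) -> None:
        a = _as_symmetric(self.matrix, self.region_set.m, "ZScoreNetwork")
        if not np.all(np.isfinite(a)):
            raise ValueError("Z-scores must be finite everywhere")
        object.__setattr__(self, "matrix", a)

    def edge_vector(self) -> np.ndarray:
        return upper_triangle(self.matrix)


@dataclass(frozen=True)
class StrengthVector:
    """Per-region abnormality strength STR: mean |ZCC| over incident edges."""

    values: Mapping[str, float]
    region_set: RegionSet

    def __post_init__(self) -> None:
        values = {r: float(self.values[r]) for r in self.region_set}
        missing = [r for r in self.region_set if r not in self.values]
        if missing:
            raise ValueError(f"strength missing for regions {missing}")
        if any(v < 0 or not np.isfinite(v) for v in values.values()):
            raise ValueError("strengths must be finite and >= 0")
        object.__setattr__(self, "values", values)

    @property
    def summed_strength(self) -> float:
        """Total abnormality strength, summed over all regions."""
        return float(sum(self.values.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.values[r] for r in self.region_set])

    def ranked(self) -> list[tuple[str, float]]:
        """Regions sorted by descending strength (ties broken by region order)."""
        order = np.argsort(-self.as_array(), kind="stable")
        names = self.region_set.names
        return [(names[i], self.values[names[i]]) for i in order]


@dataclass(frozen=True)
class EdgeSignificance:
    """Bonferroni-corrected two-sided edge significance flags.

    An edge is flagged iff |ZCC| exceeds ``critical_z``, the standard
    normal quantile for a two-sided test at level ``alpha / n_tests``.
    """

    flags: np.ndarray
    region_set: RegionSet
    alpha: float
    critical_z: float
    n_tests: int = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        f = np.asarray(self.flags, dtype=bool)
        m = self.region_set.m
        if f.shape != (m, m):
            raise ValueError(f"flags: expected shape ({m}, {m}), got {f.shape}")
        if not np.array_equal(f, f.T) or np.any(np.diag(f)):
            raise ValueError("flags must be symmetric with a false diagonal")
        f.setflags(write=False)
        object.__setattr__(self, "flags", f)
        object.__setattr__(self, "n_tests", m * (m - 1) // 2)

    @property
    def n_significant(self) -> int:
        """Count of significant undirected edges."""
        return int(upper_triangle(self.flags).sum())

    def significant_edges(self) -> list[tuple[str, str]]:
        pairs = self.region_set.edge_pairs()
        mask = upper_triangle(self.flags)
        return [p for p, keep in zip(pairs, mask) if keep]
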