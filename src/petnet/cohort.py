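"""Cohort-level validation analyses.

Four analyses probe the framework before it is trusted on single cases:

* within-group similarity — how alike the controls' own abnormality
  networks are (Pearson correlation of Z-score edge vectors, averaged
  over all pairs);
* resampling reproducibility — how stable the reference network is under
  random re-selection of the control group from a larger pool;
* sample-size sensitivity — how many controls are needed before a
  patient's residual network stabilises;
* group-vs-individual comparison — whether the mean of the individual
  edge Z-scores across a patient group tracks the conventional
  group-level difference network, plus the organ-level check that node
  strength tracks |dSUV|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    partial_corr_network,
    perturbed_network,
    residual_network,
    score_subject,
)
from .data import CohortTable, SubjectRecord
from .networks import (
    CorrelationNetwork,
    ResidualNetwork,
    StrengthVector,
    ZScoreNetwork,
    upper_triangle,
)

__all__ = [
    "SimilarityReport",
    "GroupDiffNetwork",
    "DeltaSuvVector",
    "network_similarity",
    "within_group_similarity",
    "score_controls_loo",
    "resample_reproducibility",
    "sample_size_sensitivity",
    "group_level_diff",
    "mean_individual_diff",
    "delta_suv",
    "strength_vs_deltasuv",
]


@dataclass(frozen=True)
class SimilarityReport:
    """Pairwise network similarities with their mean and SD."""

    pairwise: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.pairwise)
        if any(abs(v) > 1.0 + 1e-12 for v in vals):
            raise ValueError("pairwise similarities must lie in [-1, 1]")
        object.__setattr__(self, "pairwise", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.pairwise))

    @property
    def sd(self) -> float:
        return float(np.std(self.pairwise, ddof=1)) if len(self.pairwise) > 1 else 0.0

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise)


@dataclass(frozen=True)
class GroupDiffNetwork:
    """Per-edge group-level and mean individual-level difference vectors.

    Both vectors follow the canonical edge ordering (row-major upper
    triangle). ``undefined_edges`` records edge indices where the
    group-level ratio has a zero denominator; those edges are excluded
    from the correlation between the two vectors.
    """

    diff_group: np.ndarray
    diff_individual: np.ndarray
    undefined_edges: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        g = np.asarray(self.diff_group, dtype=float)
        d = np.asarray(self.diff_individual, dtype=float)
        if g.shape != d.shape:
            raise ValueError("diff vectors must have equal length")
        g.setflags(write=False)
        d.setflags(write=False)
        object.__setattr__(self, "diff_group", g)
        object.__setattr__(self, "diff_individual", d)
        object.__setattr__(self, "undefined_edges", frozenset(self.undefined_edges))

    def correlation(self) -> float:
        """Pearson r between the two difference vectors on defined edges."""
        keep = np.ones(len(self.diff_group), dtype=bool)
        keep[list(self.undefined_edges)] = False
        return _pearson(self.diff_group[keep], self.diff_individual[keep])


@dataclass(frozen=True)
class DeltaSuvVector:
    """Signed per-region SUV deviation of a subject from the control means."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", {k: float(v) for k, v in self.values.items()}
        )

    @property
    def abs_values(self) -> dict[str, float]:
        return {k: abs(v) for k, v in self.values.items()}

    def as_array(self, region_set) -> np.ndarray:
        return np.array([self.values[r] for r in region_set])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("correlation undefined: both edge vectors are constant")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined: an edge vector is constant")
    return float(stats.pearsonr(a, b)[0])


def network_similarity(a: ZScoreNetwork, b: ZScoreNetwork) -> float:
    """Pearson correlation of two networks' canonical edge vectors."""
    if a.region_set != b.region_set:
        raise ValueError("networks use different region sets")
    return _pearson(a.edge_vector(), b.edge_vector())


def within_group_similarity(networks: Sequence[ZScoreNetwork]) -> SimilarityReport:
    """Similarity over all unordered pairs of the given networks.

    For k networks this evaluates exactly k*(k-1)/2 pairs and reports
    their mean and SD. A pair whose similarity is undefined raises with
    the pair identity attached.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    pairwise = []
    for (i, a), (j, b) in combinations(enumerate(networks), 2):
        try:
            pairwise.append(network_similarity(a, b))
        except ValueError as exc:
            raise ValueError(f"pair ({i}, {j}): {exc}") from exc
    return SimilarityReport(tuple(pairwise))


def score_controls_loo(
    controls: CohortTable,
    threshold_fraction: float = 0.3,
    threshold_mode: str = "relative",
    include_self: bool = False,
) -> list[ZScoreNetwork]:
    """Abnormality network for each control against the remaining controls.

    By default each control is scored against the reference built from
    the other N-1 controls (leave-one-out), so the control never
    contributes to its own reference; the resulting Z-score networks have
    n_group = N. ``include_self=True`` instead keeps the control in the
    reference (the full-cohort reading), scoring the N+1-subject group
    that duplicates the control's data under a synthetic id.
    """
    if controls.n_subjects < 5:
        raise ValueError(f"need at least 5 controls, got {controls.n_subjects}")
    out = []
    for subject in controls.subjects:
        if include_self:
            base = controls
            probe = SubjectRecord(
                subject_id=subject.subject_id + "__self",
                age=subject.age,
                sex=subject.sex,
                suv=subject.suv,
                weight=subject.weight,
                dose=subject.dose,
            )
        else:
            base = controls.drop(subject.subject_id)
            probe = subject
        zcc, _ = score_subject(
            base, probe, threshold_fraction, threshold_mode=threshold_mode
        )
        out.append(zcc)
    return out


def resample_reproducibility(
    pool: CohortTable,
    k: int,
    reps: int,
    seed: int,
    min_abs_corr_kept: float | None = None,
) -> SimilarityReport:
    """Reproducibility of the reference network under control re-selection.

    Draws ``reps`` random size-``k`` subsets of ``pool`` without
    replacement, builds a reference network from each, and reports the
    pairwise Pearson similarity of their correlation edge vectors. No
    single scored subject exists in this comparison, so raw correlation
    edges (not Z-scores) are correlated. Fully reproducible given
    (pool, k, reps, seed).
    """
    if k > pool.n_subjects:
        raise ValueError(f"k={k} exceeds pool size {pool.n_subjects}")
    if reps < 2:
        raise ValueError("need reps >= 2")
    rng = np.random.default_rng(seed)
    nets = []
    for _ in range(reps):
        idx = rng.choice(pool.n_subjects, size=k, replace=False)
        nets.append(partial_corr_network(pool.subset(idx)))
    pairwise = tuple(
        _pearson(a.edge_vector(), b.edge_vector()) for a, b in combinations(nets, 2)
    )
    return SimilarityReport(pairwise)


def _patient_resnet(
    controls: CohortTable,
    patient: SubjectRecord,
    threshold_fraction: float,
    threshold_mode: str,
) -> ResidualNetwork:
    ref = partial_corr_network(controls)
    ptb = perturbed_network(controls, patient)
    return residual_network(ptb, ref, threshold_fraction, mode=threshold_mode)


def sample_size_sensitivity(
    pool: CohortTable,
    sizes: Sequence[int],
    reps: int,
    patients: CohortTable,
    reference_k: int,
    seed: int,
    threshold_fraction: float = 0.3,
    threshold_mode: str = "relative",
) -> dict[int, float]:
    """Mean patient-resNET similarity as a function of control-group size.

    For each size ``s`` and each of ``reps`` random draws of ``s``
    controls from ``pool``, every patient's residual network against the
    drawn controls is correlated (edge vectors) with the same patient's
    residual network against the fixed reference control set — the first
    ``reference_k`` subjects of ``pool``. Returns {size: mean similarity}
    averaged over patients and reps.
    """
    if patients.n_subjects == 0:
        raise ValueError("patients cohort is empty")
    for s in sizes:
        if s > pool.n_subjects:
            raise ValueError(f"size {s} exceeds pool size {pool.n_subjects}")
    if reference_k > pool.n_subjects:
        raise ValueError(f"reference_k={reference_k} exceeds pool size")
    reference_controls = pool.subset(range(reference_k))
    reference_edges = {
        p.subject_id: _patient_resnet(
            reference_controls, p, threshold_fraction, threshold_mode
        ).edge_vector()
        for p in patients.subjects
    }
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for s in sizes:
        sims = []
        for _ in range(reps):
            idx = rng.choice(pool.n_subjects, size=s, replace=False)
            sampled = pool.subset(idx)
            for p in patients.subjects:
                res = _patient_resnet(sampled, p, threshold_fraction, threshold_mode)
                sims.append(_pearson(res.edge_vector(), reference_edges[p.subject_id]))
        out[int(s)] = float(np.mean(sims))
    return out


def group_level_diff(
    ref: CorrelationNetwork,
    pat: CorrelationNetwork,
    diff_individual: np.ndarray | None = None,
) -> GroupDiffNetwork:
    """Normalised group-level difference per edge.

    Diff_group_i = (refNET_i - patNET_i) / (refNET_i + patNET_i) on the
    canonical edge vector. Edges with a zero denominator are flagged as
    undefined (value NaN) and excluded from any downstream correlation
    rather than treated as fatal.
    """
    if ref.region_set != pat.region_set:
        raise ValueError("networks use different region sets")
    r = ref.edge_vector()
    p = pat.edge_vector()
    denom = r + p
    undefined = np.nonzero(denom == 0.0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = (r - p) / denom
    diff[undefined] = np.nan
    if diff_individual is None:
        diff_individual = np.full_like(diff, np.nan)
    return GroupDiffNetwork(
        diff_group=diff,
        diff_individual=np.asarray(diff_individual, dtype=float),
        undefined_edges=frozenset(int(i) for i in undefined),
    )


def mean_individual_diff(patient_zccs: Sequence[ZScoreNetwork]) -> np.ndarray:
    """Per-edge mean of ZCC across patients (canonical edge ordering)."""
    if not patient_zccs:
        raise ValueError("need at least one patient network")
    region_set = patient_zccs[0].region_set
    if any(z.region_set != region_set for z in patient_zccs):
        raise ValueError("patient networks use different region sets")
    return np.mean([z.edge_vector() for z in patient_zccs], axis=0)


def delta_suv(subject: SubjectRecord, controls: CohortTable) -> DeltaSuvVector:
    """Per-region SUV deviation: subject SUV minus control-group mean."""
    vec = subject.suv_vector(controls.region_set)
    means = controls.region_means()
    return DeltaSuvVector(
        values=dict(zip(controls.region_set.names, vec - means))
    )


def strength_vs_deltasuv(
    strength: StrengthVector, dsuv: DeltaSuvVector
) -> dict[str, float]:
    """OLS regression of node strength on |dSUV| across regions.

    Returns slope, intercept, R^2 and the two-sided p-value for the
    slope. Checks whether the network's node-level abnormality tracks the
    conventional organ-level uptake deviation.
    """
    region_set = strength.region_set
    if region_set.m < 3:
        raise ValueError("need at least 3 regions for a regression")
    x = np.array([abs(dsuv.values[r]) for r in region_set])
    y = strength.as_array()
    if np.ptp(x) == 0.0:
        raise ValueError("|dSUV| is constant across regions: regression undefined")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
    }
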