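"""Network construction: partial correlations, perturbation, Z-scores, strength.

The pipeline for scoring one subject against a control cohort:

1. ``partial_corr_network`` — reference network (refNET): partial Pearson
   correlation between every region pair across controls, with age and sex
   regressed out of each region's SUVs first.
2. ``perturbed_network`` — the same construction on controls + the subject
   (ptbNET, N+1 subjects).
3. ``residual_network`` — resNET = ptbNET - refNET with weak entries
   eliminated by a threshold.
4. ``zscore_network`` — edge-wise abnormality Z-scores:
   ZCC = resNET * (N - 1) / (1 - refNET^2), with the group mean of resNET
   taken as 0 (its distribution is symmetric under the null).
5. ``node_strength`` — STR_m = mean |ZCC_mi| over the M-1 incident edges.

Partial correlations are computed by residualising each region column on
[intercept, covariates] by least squares and correlating the residuals.
With more regions than subjects (M = 18 vs N = 24 in the default design)
the precision-matrix route is ill-conditioned; the pairwise definition is
not, and is what the construction means by correlation "between each
region pair".
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import CohortTable, SubjectRecord
from .networks import (
    CorrelationNetwork,
    EdgeSignificance,
    ResidualNetwork,
    StrengthVector,
    ZScoreNetwork,
    upper_triangle,
)

__all__ = [
    "partial_corr_network",
    "perturbed_network",
    "residual_network",
    "zscore_network",
    "node_strength",
    "edge_significance",
    "score_subject",
]


def _residualize(suv: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each SUV column after least-squares fit on [1, covariates]."""
    n = suv.shape[0]
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "covariate matrix is rank-deficient (a covariate is constant "
            "or collinear); drop or recode it"
        )
    beta, *_ = np.linalg.lstsq(design, suv, rcond=None)
    return suv - design @ beta


def partial_corr_network(cohort: CohortTable) -> CorrelationNetwork:
    """Partial Pearson correlation network over the cohort's regions.

    For each region pair, both SUV columns are residualised on the
    covariates (age and sex by default) and the Pearson correlation of the
    residuals is taken. Since the residualisation is identical for every
    column, this equals the correlation matrix of the residualised SUV
    matrix. Diagonal is stored as 0.

    Raises
    ------
    ValueError
        If the cohort has fewer than C + 3 subjects (no residual degrees
        of freedom), a covariate is collinear, or a region's residuals are
        constant.
    """
    n, c = cohort.n_subjects, cohort.covariates.shape[1]
    if n < c + 3:
        raise ValueError(
            f"need at least {c + 3} subjects for {c} covariates, got {n}"
        )
    resid = _residualize(cohort.suv_matrix, cohort.covariates)
    sd = resid.std(axis=0)
    dead = [cohort.region_set.names[j] for j in np.nonzero(sd == 0.0)[0]]
    if dead:
        raise ValueError(f"constant residuals for region(s): {dead}")
    corr = np.corrcoef(resid, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 0.0)
    return CorrelationNetwork(
        matrix=corr,
        region_set=cohort.region_set,
        n_subjects=n,
        covariate_names=cohort.covariate_names,
    )


def perturbed_network(
    controls: CohortTable, subject: SubjectRecord
) -> CorrelationNetwork:
    """Perturbed network (ptbNET): controls plus one test subject.

    Identical construction to :func:`partial_corr_network` applied to the
    augmented (N+1)-subject group, so it equals the reference network
    recomputed on ``controls.with_subject(subject)`` exactly.
    """
    return partial_corr_network(controls.with_subject(subject))


def residual_network(
    ptb: CorrelationNetwork,
    ref: CorrelationNetwork,
    threshold_fraction: float = 0.3,
    mode: str = "relative",
) -> ResidualNetwork:
    """Residual network resNET = ptbNET - refNET with weak entries removed.

    Residual entries are differences of correlations with no fixed scale,
    so the default threshold is relative to the strongest residual: an
    entry is eliminated (set to exactly 0) when
    ``|raw| < threshold_fraction * max(|raw|)``. Ties at the boundary are
    retained. ``mode="absolute"`` instead cuts at ``|raw| <
    threshold_fraction`` directly.
    """
    if ptb.region_set != ref.region_set:
        raise ValueError("perturbed and reference networks use different regions")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    raw = ptb.matrix - ref.matrix
    if mode == "relative":
        cut = threshold_fraction * np.max(np.abs(raw))
    else:
        cut = threshold_fraction
    out = np.where(np.abs(raw) < cut, 0.0, raw)
    np.fill_diagonal(out, 0.0)
    return ResidualNetwork(
        matrix=out, region_set=ref.region_set, threshold_fraction=threshold_fraction
    )


def zscore_network(
    res: ResidualNetwork,
    ref: CorrelationNetwork,
    n_group: int,
    sqrt_denominator: bool = False,
) -> ZScoreNetwork:
    """Edge-wise abnormality Z-scores ZCC from resNET and refNET.

    The per-edge scale is ``(1 - refNET_ij^2) / (N - 1)`` where N is the
    size of the augmented group (controls + 1); the mean is fixed at 0:

        ZCC_ij = resNET_ij * (N - 1) / (1 - refNET_ij^2).

    ``sqrt_denominator=True`` uses the square root of that scale instead
    (a standard-error-like variant for sensitivity analysis).

    Raises
    ------
    ValueError
        If any reference edge has |r| = 1 (the Z-score would be infinite);
        the offending edge is named.
    """
    if res.region_set != ref.region_set:
        raise ValueError("residual and reference networks use different regions")
    if n_group < 4:
        raise ValueError(f"n_group must be >= 4, got {n_group}")
    r = ref.matrix
    sat = np.abs(upper_triangle(r)) >= 1.0
    if np.any(sat):
        pairs = ref.region_set.edge_pairs()
        bad = [p for p, s in zip(pairs, sat) if s]
        raise ValueError(f"|refNET| = 1 on edge(s) {bad}: Z-score undefined")
    denom = (1.0 - r * r) / (n_group - 1)
    if sqrt_denominator:
        denom = np.sqrt(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = res.matrix / denom
    np.fill_diagonal(z, 0.0)
    return ZScoreNetwork(matrix=z, region_set=ref.region_set, n_group=n_group)


def node_strength(zcc: ZScoreNetwork) -> StrengthVector:
    """Abnormality strength per region: STR_m = sum_i |ZCC_mi| / (M - 1)."""
    m = zcc.region_set.m
    str_values = np.abs(zcc.matrix).sum(axis=1) / (m - 1)
    return StrengthVector(
        values=dict(zip(zcc.region_set.names, str_values)),
        region_set=zcc.region_set,
    )


def edge_significance(zcc: ZScoreNetwork, alpha: float = 0.01) -> EdgeSignificance:
    """Two-sided standard-normal test per edge, Bonferroni-corrected.

    Each edge's ZCC is referred to N(0, 1) at level ``alpha / n_edges``
    (n_edges = M*(M-1)/2 tests), i.e. flagged iff
    ``|ZCC| > Phi^-1(1 - alpha / (2 * n_edges))``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n_tests = zcc.region_set.n_edges
    critical_z = float(stats.norm.isf(alpha / (2 * n_tests)))
    flags = np.abs(zcc.matrix) > critical_z
    np.fill_diagonal(flags, False)
    return EdgeSignificance(
        flags=flags, region_set=zcc.region_set, alpha=alpha, critical_z=critical_z
    )


def score_subject(
    controls: CohortTable,
    subject: SubjectRecord,
    threshold_fraction: float = 0.3,
    threshold_mode: str = "relative",
    sqrt_denominator: bool = False,
    ref: CorrelationNetwork | None = None,
) -> tuple[ZScoreNetwork, StrengthVector]:
    """Full scoring path for one subject: ptbNET -> resNET -> ZCC -> STR.

    ``ref`` may be supplied to reuse a precomputed reference network for
    the same control cohort (it is recomputed from ``controls`` otherwise).
    """
    if ref is None:
        ref = partial_corr_network(controls)
    ptb = perturbed_network(controls, subject)
    res = residual_network(ptb, ref, threshold_fraction, mode=threshold_mode)
    zcc = zscore_network(res, ref, n_group=ptb.n_subjects, sqrt_denominator=sqrt_denominator)
    return zcc, node_strength(zcc)
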