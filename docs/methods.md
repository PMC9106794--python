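# Methods

## Model

`petnet` treats the inter-regional covariance of regional SUVs across a healthy
cohort as a normative model, and scores an individual by the perturbation their
scan induces in it. The chain is

```
refNET  (N controls)      partial Pearson correlation, age + sex covariates
ptbNET  (N + 1 subjects)  identical construction, test subject added
resNET = ptbNET − refNET  thresholded
ZCC    = resNET · (N − 1) / (1 − refNET²)   edge-wise abnormality Z-scores
STR_m  = Σ_{i≠m} |ZCC_mi| / (M − 1)          node-level abnormality strength
```

Assumptions worth stating explicitly:

- Regional SUVs are approximately linear in age and sex, with the remaining
  covariance stationary across healthy subjects. The partial correlation is
  computed pairwise — residualize both columns on `[1, age, sex]`, correlate
  residuals — which is well-posed even when regions outnumber subjects
  (M = 18 vs N = 24 in the default design); a precision-matrix route would
  not be.
- The residual-network distribution under the null is symmetric about zero,
  so the Z-score uses mean 0 and the scale `(1 − refNET²)/(N − 1)`. The scale
  is used exactly in that form (no square root); a standard-error-like
  square-root variant is available (`zscore_network(..., sqrt_denominator=True)`)
  for sensitivity analysis and changes only the overall Z calibration, not
  rankings. Null simulations (200 replicates) confirm the symmetric-about-zero
  premise: the grand mean ZCC is statistically indistinguishable from 0.
- Self-edges are never used: every network stores a zero diagonal and all
  vectorized statistics run over the row-major upper triangle (the canonical
  edge ordering, length M(M−1)/2).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_fraction` | 0.30 | resNET entries with magnitude below this fraction of the largest entry are set to exactly 0 |
| `threshold_mode` | `relative` | `absolute` cuts at `|resNET| < threshold_fraction` directly |
| `alpha` | 0.01 | family-wise level for edge significance, Bonferroni-corrected over M(M−1)/2 edges |
| covariates | age, sex | regressed out of every region before correlating |

Threshold semantics was a genuinely open choice: residual entries are
differences of correlations with no fixed scale, so a relative-to-maximum rule
stays meaningful for both mild and severe perturbations; the absolute mode is
kept behind the config switch for users who want a fixed scale. Ties exactly at
the cut are retained (elimination is strict `<`). When `ptbNET == refNET` the
result is the zero matrix for any threshold.

Sex coding direction (`F→0, M→1` by default, remappable in the config) is
immaterial: partial correlations are invariant to affine recoding of
covariates, and the test suite asserts this.

## Cohort analyses

- **Within-group similarity**: Pearson correlation between two networks' edge
  vectors, averaged over all pairs. For control self-scoring, each control is
  scored against a reference built from the other N−1 controls (leave-one-out)
  so that no subject contributes to its own reference; `include_self=True`
  gives the full-cohort reading.
- **Resampling reproducibility** correlates the *correlation* edge vectors of
  reference networks built from random control subsets — no single scored
  subject exists in that comparison, so there are no Z-scores to correlate.
- **Sample-size sensitivity** compares each patient's thresholded residual
  network under a sampled control set of size `s` with the same patient's
  residual network under a fixed reference control set (the first
  `reference_k` rows of the pool), averaging the edge-vector correlations over
  patients and repetitions.
- **Group vs individual**: `Diff_group = (refNET − patNET)/(refNET + patNET)`
  per edge with zero-denominator edges flagged undefined and excluded
  pairwise; `Diff_individual` is the per-edge mean ZCC across patients.
  A sign caveat: with `resNET = ptbNET − refNET`, an edge whose correlation
  the patients *lower* gets a negative mean ZCC but a *positive* `Diff_group`,
  so the two measures are anti-correlated by construction when both are taken
  with the conventions above; on synthetic data the correlation between them
  is negative-to-zero, and additionally shares a component driven by the
  reference network's own sampling error. Users comparing the two measures
  should interpret the magnitude, not the sign.
- **Organ-level validation**: OLS of STR on `|ΔSUV|` across regions
  (`ΔSUV_m` = subject SUV minus control mean). Note `ΔSUV` is in raw SUV
  units, so regions with a large natural SUV scale (brain gray matter)
  dominate it; a perturbation expressed in noise-SD units on a low-SUV organ
  (the default lung target) produces a strong STR signal but a small raw
  `ΔSUV`, and the regression's R² on default synthetic data is accordingly
  modest. On real focal disease, where the affected organ's uptake change
  dominates in absolute terms, the regression is the appropriate check.

## Synthetic data

The generator draws controls from an additive Gaussian model: per-region base
mean (plausible resting FDG SUVs), linear age slopes (mild gray-matter
decline), additive sex offsets (muscle/liver), and correlated noise built by a
Cholesky factor of a two-block target correlation (organs ~0.45 within-block,
brain regions ~0.65, cross-block 0.25; positive-definiteness is verified at
construction). Noise SD defaults to 15% of each region's mean; SUVs are floored
at 0.01 to stay non-negative without breaking the additive structure a linear
covariate model assumes. Ages are uniform on 25–75 years; sex is balanced
within a cohort and a fair coin for a single draw (a balanced assignment is
degenerate at n = 1 and would make a patients-only cohort rank-deficient in
the sex covariate).

Patients are controls plus an organ-localized perturbation: a mean shift in
units of the target region's noise SD (default 5), and partial decorrelation —
the target's correlated noise component is mixed with a fresh independent draw
using variance-preserving weights `sqrt(1−f)` and `sqrt(f)`
(default f = 0.8), so the marginal variance is unchanged while coupling to the
other regions is attenuated by `sqrt(1−f)`. Defaults describe the canonical
study: 24 controls, 18 regions, lung target.

What the simulator does *not* emulate: non-Gaussian and skewed SUV
distributions, scanner/protocol effects, lesion heterogeneity within an organ,
age-dependent covariance (only means shift with age), and multi-organ disease.
Passing tests therefore demonstrate the pipeline's statistical correctness and
its recovery behavior under the assumed model, not clinical performance.

Every simulator output is a pure function of (config, seed); per-patient seeds
are spawned from a root `SeedSequence` so patient draws are independent but
reproducible.

## Numerical choices

- Residualization uses `numpy.linalg.lstsq` on the full SUV matrix (one shared
  design), which is algebraically identical to per-pair residualization and is
  cross-checked against a long-hand normal-equations oracle to 1e-12.
- Correlations are clipped to [−1, 1] to absorb floating-point overshoot, and
  matrices are symmetrized (`(A + Aᵀ)/2`) after a 1e-12 symmetry check.
- A reference edge with |r| = 1 makes the Z-score undefined; it is an error
  naming the offending edge rather than an infinity.
- Degenerate inputs are rejected with named errors: constant region columns
  (for cohorts of ≥ 3), rank-deficient covariate designs, cohorts smaller than
  C + 3, duplicate subject ids, missing regions.
- Leave-one-out scored controls carry `n_group = N`; scored patients carry
  `n_group = N + 1`.

## Problem sizes

Analyses and tests run at the canonical design sizes: 24-control references,
60-subject pools for resampling (24-of-60, 20 repetitions) and for the
control-group-size trend (sizes 10–40, 20 repetitions, 10 patients), 50
patients for perturbation recovery, and 200 replicates for null calibration.
These match the study design the framework targets and keep every analysis in
the seconds-to-a-minute range on one CPU.

## Known limitations

- The 30% threshold's original definition is ambiguous (relative vs absolute,
  and whether it precedes Z-scoring); it is applied to resNET before
  Z-scoring, relative by default, and configurable.
- Under an exchangeable null, leave-one-out abnormality maps of the controls
  behave like per-subject influence vectors that sum to ~0, so their mean
  pairwise similarity sits near −1/(N−1) rather than being high; high control
  self-similarity on real data likely reflects shared shrinkage of overfit
  reference edges, which the Gaussian simulator does not reproduce.
- Summed strength separates perturbed patients from controls in direction,
  but the relative threshold adapts to each subject's own strongest residual,
  which compresses the gap; an absolute threshold widens it at the cost of a
  scale assumption.
- Weight and injected dose are carried as metadata only; SUV normalization is
  assumed done upstream.
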