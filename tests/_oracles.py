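"""Independent scalar-level oracles used to cross-check the vectorised core.

These deliberately avoid the code paths of the package: residualisation is
done edge pair by edge pair via explicit normal equations, and Pearson
correlation via explicit sums.
"""

import numpy as np


def pearson_oracle(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - sum(x) / len(x)
    ym = y - sum(y) / len(y)
    return float(sum(xm * ym) / np.sqrt(sum(xm * xm) * sum(ym * ym)))


def _residualize_oracle(v, covariates):
    """Residuals of v on [1, covariates] by long-hand normal equations."""
    n = len(v)
    design = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    dtd = design.T @ design
    dtv = design.T @ np.asarray(v, dtype=float)
    beta = np.linalg.solve(dtd, dtv)
    return np.asarray(v, dtype=float) - design @ beta


def partial_corr_oracle(suv, covariates) -> np.ndarray:
    """Pairwise residualize-then-Pearson partial correlation matrix, diag 0."""
    suv = np.asarray(suv, dtype=float)
    m = suv.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ri = _residualize_oracle(suv[:, i], covariates)
            rj = _residualize_oracle(suv[:, j], covariates)
            out[i, j] = out[j, i] = pearson_oracle(ri, rj)
    return out


def zcc_oracle(res, ref, n_group) -> np.ndarray:
    """Scalar elementwise Z-score: res_ij * (N-1) / (1 - ref_ij^2)."""
    res = np.asarray(res, dtype=float)
    ref = np.asarray(ref, dtype=float)
    m = res.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                out[i, j] = res[i, j] * (n_group - 1) / (1.0 - ref[i, j] ** 2)
    return out


def simple_regression_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(x * x), sum(x * y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    yhat = slope * x + intercept
    ss_res = sum((y - yhat) ** 2)
    ss_tot = sum((y - sy / n) ** 2)
    return slope, intercept, 1.0 - ss_res / ss_tot
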