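"""Independent brute-force oracles for the MR estimators.

Each function re-derives an estimator from first principles by a different
route than the package uses (explicit normal equations / Cramer's rule /
step-through interpolation), so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def ivw_oracle(bx, by, sey):
    """Weighted through-origin least squares by explicit normal equations."""
    bx, by, sey = map(np.asarray, (bx, by, sey))
    w = 1.0 / sey**2
    b = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return float(b), float(se)


def egger_oracle(bx, by, sey):
    """Weighted regression with intercept via Cramer's rule on the 2x2 system.

    Orientation and the overdispersion floor follow the estimator's
    definition; the linear algebra is independent.
    """
    bx, by, sey = map(np.asarray, (bx, by, sey))
    s = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * s, by * s
    w = 1.0 / sey**2
    S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    det = S * Sxx - Sx**2
    intercept = (Sxx * Sy - Sx * Sxy) / det
    slope = (S * Sxy - Sx * Sy) / det
    resid = y - intercept - slope * x
    scale = max(1.0, float((w * resid**2).sum() / (len(x) - 2)))
    se_slope = np.sqrt(S / det * scale)
    se_int = np.sqrt(Sxx / det * scale)
    return float(intercept), float(slope), float(se_int), float(se_slope)


def weighted_median_oracle(ratios, weights):
    """Interpolated weighted median by an explicit step-through loop."""
    pairs = sorted(zip(map(float, ratios), map(float, weights)))
    total = sum(w for _, w in pairs)
    cum = 0.0
    grid = []
    for val, wt in pairs:
        grid.append(((cum + wt / 2.0) / total, val))
        cum += wt
    if 0.5 <= grid[0][0]:
        return grid[0][1]
    if 0.5 >= grid[-1][0]:
        return grid[-1][1]
    for (p0, v0), (p1, v1) in zip(grid, grid[1:]):
        if p0 <= 0.5 <= p1:
            return v0 + (v1 - v0) * (0.5 - p0) / (p1 - p0)
    raise AssertionError("unreachable")


def mvmr_oracle(X, y, sey):
    """Weighted multiple regression via explicit generalized least squares."""
    X, y, sey = map(np.asarray, (X, y, sey))
    W = np.diag(1.0 / sey**2)
    A = X.T @ W @ X
    theta = np.linalg.solve(A, X.T @ W @ y)
    resid = y - X @ theta
    n, k = X.shape
    scale = max(1.0, float(resid @ W @ resid / (n - k)))
    cov = np.linalg.inv(A) * scale
    return theta, np.sqrt(np.diag(cov))
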