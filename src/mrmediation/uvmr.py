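"""Univariable two-sample MR estimators and diagnostics.

Per-variant Wald ratios r_j = betaY_j / betaX_j (first-order SE
seY_j / |betaX_j|) underlie every estimator:

* IVW: inverse-variance-weighted mean of the ratios, equivalently weighted
  through-origin regression of outcome on exposure effects.  Weights are
  w_j = betaX_j^2 / seY_j^2.  The random-effects variant inflates the fixed
  SE by max(1, sqrt(Q/(n-1))) (multiplicative overdispersion, floored at 1);
  ``mode="auto"`` switches to random effects when Cochran's Q is significant
  at 0.05.
* MR-Egger: weighted regression with an intercept after orienting all
  exposure effects to the positive half-line; a nonzero intercept signals
  directional horizontal pleiotropy.
* Weighted median: the ratio at the 50th percentile of the inverse-variance
  weight distribution, consistent when at least half the weight comes from
  valid instruments; its SE comes from a seeded parametric bootstrap.

P-values are two-sided normal throughout, consistent with large-sample GWAS
summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    ConfigError,
    DegenerateInputError,
    InputError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

__all__ = [
    "MREstimate",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "leave_one_out",
    "to_odds_ratio",
    "scatter_data",
    "funnel_data",
]

Z_95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One causal estimate on the log-odds scale with its diagnostics."""

    method: str
    b: float
    se: float
    p: float
    or_value: float
    or_low: float
    or_high: float
    nsnp: int
    q: float = float("nan")
    q_p: float = float("nan")
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.nsnp,
            "b": self.b,
            "se": self.se,
            "or": self.or_value,
            "ci_low": self.or_low,
            "ci_high": self.or_high,
            "p": self.p,
            "q": self.q,
            "q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


def to_odds_ratio(b: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds slope into OR with a 95% Wald CI."""
    if se < 0:
        raise DegenerateInputError("to_odds_ratio requires se >= 0")
    return (
        float(np.exp(b)),
        float(np.exp(b - Z_95 * se)),
        float(np.exp(b + Z_95 * se)),
    )


def _check_nonzero_exposure(h: HarmonizedSet) -> None:
    zero = np.flatnonzero(h.exposure_beta == 0.0)
    if zero.size:
        raise DegenerateInputError(
            f"zero exposure effect for variant {h.variants[zero[0]]!r}; "
            "Wald ratio undefined"
        )


def ratio_estimates(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratios with first-order standard errors."""
    _check_nonzero_exposure(h)
    ratio = h.outcome_beta / h.exposure_beta
    se = h.outcome_se / np.abs(h.exposure_beta)
    return pd.DataFrame({"variant_id": h.variants, "ratio": ratio, "se": se})


def _ivw_core(bx, by, sey):
    w = bx**2 / sey**2
    r = by / bx
    b = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - b) ** 2))
    return b, se_fixed, q, w


def _two_sided_p(b: float, se: float) -> float:
    if se == 0:
        return 0.0 if b != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(b) / se))


def _finish(method, b, se, nsnp, q=float("nan"), q_p=float("nan"), **kw) -> MREstimate:
    or_v, or_lo, or_hi = to_odds_ratio(b, se)
    return MREstimate(
        method=method,
        b=b,
        se=se,
        p=_two_sided_p(b, se),
        or_value=or_v,
        or_low=or_lo,
        or_high=or_hi,
        nsnp=nsnp,
        q=q,
        q_p=q_p,
        **kw,
    )


def ivw(h: HarmonizedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode`` is ``"fixed"``, ``"random"``, or ``"auto"`` (random effects when
    the heterogeneity p-value falls below 0.05).  A single-instrument set
    degenerates to the Wald ratio with a warning.
    """
    if mode not in {"fixed", "random", "auto"}:
        raise ConfigError(f"unknown IVW mode {mode!r}")
    if h.nsnp == 0:
        raise InputError("ivw called on an empty harmonized set")
    _check_nonzero_exposure(h)
    if h.nsnp == 1:
        warnings.warn(
            "single instrument: IVW degenerates to the Wald ratio",
            UserWarning,
            stacklevel=2,
        )
        b = float(h.outcome_beta[0] / h.exposure_beta[0])
        se = float(h.outcome_se[0] / abs(h.exposure_beta[0]))
        return _finish("IVW", b, se, 1)
    b, se_fixed, q, _ = _ivw_core(h.exposure_beta, h.outcome_beta, h.outcome_se)
    dof = h.nsnp - 1
    q_p = float(stats.chi2.sf(q, dof))
    use_random = mode == "random" or (mode == "auto" and q_p < 0.05)
    if use_random:
        se = se_fixed * max(1.0, float(np.sqrt(q / dof)))
        method = "IVW-random"
    else:
        se = se_fixed
        method = "IVW"
    return _finish(method, b, se, h.nsnp, q=q, q_p=q_p)


def _wls_with_floor(y, X, w):
    """WLS fit whose parameter SEs use multiplicative overdispersion >= 1."""
    res = sm.WLS(y, X, weights=w).fit()
    scale = float(res.scale)  # weighted RSS / dof
    cov_unit = np.asarray(res.normalized_cov_params)  # inv(X' W X)
    se = np.sqrt(np.diag(cov_unit)) * np.sqrt(max(1.0, scale))
    return np.asarray(res.params, dtype=float), se, scale


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression with the intercept test for directional pleiotropy.

    Exposure effects are oriented to the positive half-line (both betas
    negated where needed) so the intercept is interpretable; slope and
    intercept SEs carry the same overdispersion floor as IVW-random.
    """
    if h.nsnp < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {h.nsnp}"
        )
    sign = np.where(h.exposure_beta < 0, -1.0, 1.0)
    bx = h.exposure_beta * sign
    by = h.outcome_beta * sign
    if np.ptp(bx) == 0:
        raise CollinearityError(
            "all oriented exposure effects identical; Egger slope not identifiable"
        )
    w = 1.0 / h.outcome_se**2
    X = sm.add_constant(bx)
    params, ses, _ = _wls_with_floor(by, X, w)
    intercept, slope = params
    se_int, se_slope = ses
    q, q_p = cochran_q(h)
    return _finish(
        "Egger",
        float(slope),
        float(se_slope),
        h.nsnp,
        q=q,
        q_p=q_p,
        egger_intercept=float(intercept),
        egger_intercept_p=_two_sided_p(float(intercept), float(se_int)),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    pos = (cum - 0.5 * w) / cum[-1]
    if 0.5 <= pos[0]:
        return float(v[0])
    if 0.5 >= pos[-1]:
        return float(v[-1])
    return float(np.interp(0.5, pos, v))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, *, seed: int
) -> MREstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE.

    The point estimate interpolates the sorted Wald ratios at the midpoint of
    the normalized inverse-variance weight distribution.  The SE is the
    standard deviation of the estimate over ``n_boot`` parametric draws of
    (betaX_j, betaY_j) from normals centred on the observed values.
    """
    if h.nsnp < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {h.nsnp}"
        )
    if n_boot < 1:
        raise ConfigError("weighted_median requires n_boot >= 1")
    _check_nonzero_exposure(h)
    r = h.outcome_beta / h.exposure_beta
    w = (h.exposure_beta / h.outcome_se) ** 2  # 1 / se(ratio)^2
    est = _weighted_median(r, w)

    rng = np.random.default_rng(seed)
    n = h.nsnp
    bx = h.exposure_beta + rng.normal(size=(n_boot, n)) * h.exposure_se
    by = h.outcome_beta + rng.normal(size=(n_boot, n)) * h.outcome_se
    rb = by / bx
    wb = (bx / h.outcome_se) ** 2
    order = np.argsort(rb, axis=1, kind="stable")
    rs = np.take_along_axis(rb, order, axis=1)
    ws = np.take_along_axis(wb, order, axis=1)
    cum = np.cumsum(ws, axis=1)
    pos = (cum - 0.5 * ws) / cum[:, -1:]
    boot = np.array([np.interp(0.5, pos[i], rs[i]) for i in range(n_boot)])
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    q, q_p = cochran_q(h)
    return _finish("WM", est, se, h.nsnp, q=q, q_p=q_p)


def cochran_q(h: HarmonizedSet) -> tuple[float, float]:
    """Cochran's Q over the Wald ratios, with chi-square(nsnp-1) p-value."""
    if h.nsnp < 2:
        raise DegenerateInputError(
            "Cochran's Q undefined for fewer than 2 instruments"
        )
    _check_nonzero_exposure(h)
    _, _, q, _ = _ivw_core(h.exposure_beta, h.outcome_beta, h.outcome_se)
    return q, float(stats.chi2.sf(q, h.nsnp - 1))


def leave_one_out(h: HarmonizedSet, mode: str = "fixed") -> pd.DataFrame:
    """Per-variant-omitted IVW estimates plus the all-instrument estimate."""
    if h.nsnp < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out requires >= 3 instruments, got {h.nsnp}"
        )
    rows = []
    for i in range(h.nsnp):
        keep = np.ones(h.nsnp, dtype=bool)
        keep[i] = False
        est = ivw(h.subset(keep), mode=mode)
        rows.append(
            {
                "omitted": h.variants[i],
                "nsnp": est.nsnp,
                "b": est.b,
                "se": est.se,
                "p": est.p,
            }
        )
    full = ivw(h, mode=mode)
    rows.append(
        {"omitted": "(none)", "nsnp": full.nsnp, "b": full.b, "se": full.se, "p": full.p}
    )
    return pd.DataFrame(rows)


def scatter_data(h: HarmonizedSet) -> pd.DataFrame:
    """Tidy per-variant effect pairs for scatter plots of betaY on betaX."""
    return pd.DataFrame(
        {
            "variant_id": h.variants,
            "exposure_beta": h.exposure_beta,
            "exposure_se": h.exposure_se,
            "outcome_beta": h.outcome_beta,
            "outcome_se": h.outcome_se,
        }
    )


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant ratio vs precision (1/se) for funnel plots."""
    tab = ratio_estimates(h)
    tab["precision"] = 1.0 / tab["se"]
    return tab
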