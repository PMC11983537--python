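"""MR-PRESSO: residual-sum-of-squares pleiotropy tests.

Three stages share one simulation design.  For each variant the
leave-one-out IVW slope b_{-j} predicts its outcome effect; the squared
standardized residual d_j = (betaY_j - b_{-j}*betaX_j)^2 / seY_j^2 measures
how far the variant departs from the consensus.  Replicate datasets drawn
from the no-pleiotropy model (betaY* ~ N(b_{-j}*betaX_j, seY_j),
betaX* ~ N(betaX_j, seX_j)) give the null distribution of the total RSS
(global test) and of each d_j (per-variant outlier test, Bonferroni
adjusted).  The distortion test compares the IVW slope before and after
outlier removal against slopes from random same-sized removals.

Empirical p-values use the +1 correction, so the smallest attainable global
p is 1/(n_sim+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigError,
    DegenerateInputError,
    InsufficientInstrumentsError,
    UsageError,
)
from .gwas_io import HarmonizedSet

__all__ = [
    "PressoResult",
    "presso_global",
    "presso_outliers",
    "presso_distortion",
    "run_presso",
]

OUTLIER_ALPHA = 0.05


@dataclass
class PressoResult:
    """Global, per-variant, and distortion test results."""

    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    per_snp_p: np.ndarray | None = None
    outliers: list[str] = field(default_factory=list)
    distortion_stat: float = float("nan")
    distortion_p: float = float("nan")
    b_raw: float = float("nan")
    b_corrected: float | None = None

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "per_snp_p": None
            if self.per_snp_p is None
            else [float(p) for p in self.per_snp_p],
            "outliers": list(self.outliers),
            "distortion_stat": self.distortion_stat,
            "distortion_p": self.distortion_p,
            "b_raw": self.b_raw,
            "b_corrected": self.b_corrected,
        }


def _ivw_slope(bx, by, sey) -> float:
    w = bx**2 / sey**2
    return float(np.sum(w * (by / bx)) / np.sum(w))


def _loo_slopes(bx, by, sey) -> np.ndarray:
    """Leave-one-out IVW slopes, one per variant (vectorized, 1-D or 2-D)."""
    w = bx**2 / sey**2
    wr = w * (by / bx)
    s_w = w.sum(axis=-1, keepdims=True)
    s_wr = wr.sum(axis=-1, keepdims=True)
    return (s_wr - wr) / (s_w - w)


def _residuals(bx, by, sey) -> np.ndarray:
    b_loo = _loo_slopes(bx, by, sey)
    return (by - b_loo * bx) ** 2 / sey**2


def _check(h: HarmonizedSet, n_sim: int) -> None:
    if n_sim <= 0:
        raise ConfigError("MR-PRESSO requires n_sim >= 1")
    if h.nsnp < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO requires >= 4 instruments, got {h.nsnp}"
        )
    if np.any(h.exposure_beta == 0.0):
        raise DegenerateInputError("MR-PRESSO requires nonzero exposure effects")


def _simulate(h: HarmonizedSet, n_sim: int, seed: int):
    """Observed residuals plus the simulated residual matrix (n_sim, nsnp)."""
    bx, by, sey = h.exposure_beta, h.outcome_beta, h.outcome_se
    d_obs = _residuals(bx, by, sey)
    rss_obs = float(d_obs.sum())
    b_loo = _loo_slopes(bx, by, sey)
    rng = np.random.default_rng(seed)
    sex = h.exposure_se
    if sex is None or np.any(~np.isfinite(sex)):
        import warnings

        warnings.warn(
            "exposure SEs unavailable; simulating outcome effects only",
            UserWarning,
            stacklevel=3,
        )
        bx_sim = np.broadcast_to(bx, (n_sim, h.nsnp)).copy()
    else:
        bx_sim = bx + rng.normal(size=(n_sim, h.nsnp)) * sex
    by_sim = b_loo * bx + rng.normal(size=(n_sim, h.nsnp)) * sey
    d_sim = _residuals(bx_sim, by_sim, sey)
    return d_obs, rss_obs, d_sim


def presso_global(h: HarmonizedSet, n_sim: int = 1000, *, seed: int) -> PressoResult:
    """Global heterogeneity test: empirical p for the observed total RSS."""
    _check(h, n_sim)
    _, rss_obs, d_sim = _simulate(h, n_sim, seed)
    rss_sim = d_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        seed=seed,
        b_raw=_ivw_slope(h.exposure_beta, h.outcome_beta, h.outcome_se),
    )


def presso_outliers(
    h: HarmonizedSet, n_sim: int = 1000, *, seed: int
) -> tuple[list[str], np.ndarray]:
    """Per-variant outlier test: Bonferroni-adjusted empirical p-values.

    Returns the flagged variant ids (adjusted p < 0.05) and the adjusted
    per-variant p-value array in input order.
    """
    _check(h, n_sim)
    d_obs, _, d_sim = _simulate(h, n_sim, seed)
    p_raw = (d_sim >= d_obs).mean(axis=0)
    p_adj = np.minimum(1.0, p_raw * h.nsnp)
    flagged = [str(v) for v, p in zip(h.variants, p_adj) if p < OUTLIER_ALPHA]
    return flagged, p_adj


def presso_distortion(
    h: HarmonizedSet,
    outliers: list[str],
    n_sim: int = 1000,
    *,
    seed: int,
) -> tuple[float, float, float]:
    """Distortion test for the outlier-corrected IVW estimate.

    Returns ``(distortion_stat, distortion_p, b_corrected)`` where the
    statistic is 100*(b_raw - b_corrected)/|b_corrected| and the p-value is
    the two-sided empirical tail over random outlier-sized removals.
    """
    if not outliers:
        raise UsageError("distortion test requires a nonempty outlier set")
    if n_sim <= 0:
        raise ConfigError("MR-PRESSO requires n_sim >= 1")
    is_out = np.isin(h.variants.astype(str), np.asarray(outliers, dtype=str))
    if is_out.all():
        raise DegenerateInputError("every instrument flagged as an outlier")
    bx, by, sey = h.exposure_beta, h.outcome_beta, h.outcome_se
    b_raw = _ivw_slope(bx, by, sey)
    b_corr = _ivw_slope(bx[~is_out], by[~is_out], sey[~is_out])
    stat = 100.0 * (b_raw - b_corr) / abs(b_corr)
    n_out = int(is_out.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(h.nsnp, size=n_out, replace=False)
        keep = np.ones(h.nsnp, dtype=bool)
        keep[drop] = False
        b_sub = _ivw_slope(bx[keep], by[keep], sey[keep])
        null[i] = 100.0 * (b_raw - b_sub) / abs(b_sub)
    p = float((1 + np.sum(np.abs(null) >= abs(stat))) / (n_sim + 1))
    return float(stat), p, float(b_corr)


def run_presso(h: HarmonizedSet, n_sim: int = 1000, *, seed: int) -> PressoResult:
    """Run global, outlier, and (when outliers exist) distortion tests."""
    result = presso_global(h, n_sim, seed=seed)
    flagged, p_adj = presso_outliers(h, n_sim, seed=seed)
    result.per_snp_p = p_adj
    result.outliers = flagged
    if flagged and len(flagged) < h.nsnp:
        stat, p, b_corr = presso_distortion(h, flagged, n_sim, seed=seed)
        result.distortion_stat = stat
        result.distortion_p = p
        result.b_corrected = b_corr
    return result
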