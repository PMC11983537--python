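"""Two-step MR mediation: product of coefficients with delta-method SE.

Step 1 estimates the exposure-to-mediator effect alpha by univariable IVW.
Step 2 estimates the mediator-to-outcome direct effect beta1 by
multivariable MR adjusting for the exposure.  The indirect (mediated)
effect is alpha*beta1 with first-order delta-method standard error
sqrt(alpha^2*se_beta1^2 + beta1^2*se_alpha^2); the proportion mediated is
100*alpha*beta1/beta_total, with beta_total the univariable exposure-to-
outcome effect, and its CI comes from a seeded parametric bootstrap of the
three estimates.

A mediator is *admitted* only when both the exposure-to-mediator effect and
the adjusted mediator-to-outcome effect are significant at 0.05; failed
admission flags the result rather than raising.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    BootstrapInstabilityError,
    ConfigError,
    DegenerateInputError,
)
from .gwas_io import harmonize_multi, harmonize_pair
from .instruments import InstrumentConfig, LDTable, select_instruments
from .mvmr import mvmr_fit, mvmr_select_instruments
from .uvmr import Z_95, ivw

__all__ = [
    "MediationResult",
    "mediation_effect",
    "delta_se",
    "product_ci",
    "proportion_mediated",
    "bootstrap_proportion_ci",
    "two_step_mediation",
]

ADMISSION_ALPHA = 0.05
#: Bootstrap draws with |beta_total*| below this are rejected and redrawn.
TOTAL_EFFECT_GUARD = 1e-6


def mediation_effect(alpha: float, beta1: float) -> float:
    """Product-of-coefficients indirect effect alpha*beta1."""
    return float(alpha) * float(beta1)


def delta_se(alpha: float, se_alpha: float, beta1: float, se_beta1: float) -> float:
    """First-order delta-method SE of the product (no cross term)."""
    if se_alpha < 0 or se_beta1 < 0:
        raise DegenerateInputError("delta_se requires nonnegative SEs")
    return float(np.sqrt(alpha**2 * se_beta1**2 + beta1**2 * se_alpha**2))


def product_ci(
    alpha: float, se_alpha: float, beta1: float, se_beta1: float
) -> tuple[float, float]:
    """95% normal CI for alpha*beta1 via the delta-method SE."""
    point = mediation_effect(alpha, beta1)
    se = delta_se(alpha, se_alpha, beta1, se_beta1)
    return (point - Z_95 * se, point + Z_95 * se)


def proportion_mediated(indirect: float, beta_total: float) -> float:
    """Indirect effect as a percentage of the total effect.

    A sign mismatch between indirect and total effects (inconsistent
    mediation) yields a negative percentage and a warning.
    """
    if beta_total == 0:
        raise DegenerateInputError(
            "proportion mediated undefined for a zero total effect"
        )
    prop = 100.0 * indirect / beta_total
    if prop < 0:
        warnings.warn(
            "indirect and total effects have opposite signs "
            "(inconsistent mediation); proportion reported as negative",
            UserWarning,
            stacklevel=2,
        )
    return float(prop)


def bootstrap_proportion_ci(
    alpha: float,
    se_alpha: float,
    beta1: float,
    se_beta1: float,
    beta_total: float,
    se_beta_total: float,
    n_boot: int = 1000,
    *,
    seed: int,
    method: str = "normal",
    guard: float = TOTAL_EFFECT_GUARD,
) -> tuple[float, float]:
    """Bootstrap 95% CI for the proportion mediated.

    The three estimates are drawn independently from normals centred on
    their values.  ``method="normal"`` (default) returns the point estimate
    +/- 1.96 times the bootstrap standard deviation — the symmetric interval
    form; ``method="percentile"`` returns the empirical 2.5/97.5 percentiles.
    Draws whose |beta_total*| falls below ``guard`` are rejected and redrawn;
    a rejection fraction above 50% raises an instability error.
    """
    if n_boot < 100:
        raise ConfigError("bootstrap_proportion_ci requires n_boot >= 100")
    if method not in {"normal", "percentile"}:
        raise ConfigError(f"unknown bootstrap CI method {method!r}")
    point = proportion_mediated(mediation_effect(alpha, beta1), beta_total)
    rng = np.random.default_rng(seed)
    props = np.empty(n_boot)
    filled = 0
    attempted = 0
    rejected = 0
    while filled < n_boot:
        m = n_boot - filled
        a = rng.normal(alpha, se_alpha, size=m)
        b = rng.normal(beta1, se_beta1, size=m)
        t = rng.normal(beta_total, se_beta_total, size=m)
        ok = np.abs(t) >= guard
        attempted += m
        rejected += int((~ok).sum())
        good = 100.0 * a[ok] * b[ok] / t[ok]
        props[filled : filled + good.size] = good
        filled += good.size
        if attempted >= 2 * n_boot and rejected / attempted > 0.5:
            raise BootstrapInstabilityError(
                f"{rejected}/{attempted} bootstrap draws rejected by the "
                f"|beta_total| < {guard} guard"
            )
    if rejected:
        warnings.warn(
            f"{rejected} bootstrap draws rejected by the total-effect guard "
            "and redrawn",
            UserWarning,
            stacklevel=2,
        )
    if method == "percentile":
        lo, hi = np.percentile(props, [2.5, 97.5])
        return float(lo), float(hi)
    sd = float(props.std(ddof=1))
    return (point - Z_95 * sd, point + Z_95 * sd)


@dataclass
class MediationResult:
    """One mediator's two-step decomposition (one report-table row)."""

    mediator: str
    alpha: float
    se_alpha: float
    alpha_p: float
    beta1: float
    se_beta1: float
    beta1_p: float
    beta_total: float
    se_beta_total: float
    total_p: float
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    indirect_p: float
    proportion: float
    proportion_ci: tuple[float, float]
    n_boot: int
    seed: int
    admitted: bool
    nsnp_alpha: int = 0
    nsnp_total: int = 0
    nsnp_mvmr: int = 0

    def to_row(self) -> dict:
        return {
            "mediator": self.mediator,
            "mediating_effect": self.indirect,
            "ci_low": self.indirect_ci[0],
            "ci_high": self.indirect_ci[1],
            "p": self.indirect_p,
            "proportion_pct": self.proportion,
            "proportion_ci_low": self.proportion_ci[0],
            "proportion_ci_high": self.proportion_ci[1],
            "admitted": self.admitted,
        }

    def path_row(self) -> dict:
        """Path-diagram data: alpha, beta1, direct = total - indirect."""
        return {
            "mediator": self.mediator,
            "alpha": self.alpha,
            "beta1": self.beta1,
            "indirect": self.indirect,
            "direct": self.beta_total - self.indirect,
            "total": self.beta_total,
        }


def assemble_mediation(
    mediator: str,
    alpha: float,
    se_alpha: float,
    alpha_p: float,
    beta1: float,
    se_beta1: float,
    beta1_p: float,
    beta_total: float,
    se_beta_total: float,
    total_p: float,
    *,
    n_boot: int = 1000,
    seed: int,
    ci_method: str = "normal",
    **counts,
) -> MediationResult:
    """Build a :class:`MediationResult` from the three stage estimates."""
    indirect = mediation_effect(alpha, beta1)
    ise = delta_se(alpha, se_alpha, beta1, se_beta1)
    ci = product_ci(alpha, se_alpha, beta1, se_beta1)
    ip = float(2.0 * stats.norm.sf(abs(indirect) / ise)) if ise > 0 else (
        0.0 if indirect else 1.0
    )
    prop = proportion_mediated(indirect, beta_total)
    prop_ci = bootstrap_proportion_ci(
        alpha,
        se_alpha,
        beta1,
        se_beta1,
        beta_total,
        se_beta_total,
        n_boot,
        seed=seed,
        method=ci_method,
    )
    admitted = alpha_p < ADMISSION_ALPHA and beta1_p < ADMISSION_ALPHA
    return MediationResult(
        mediator=mediator,
        alpha=alpha,
        se_alpha=se_alpha,
        alpha_p=alpha_p,
        beta1=beta1,
        se_beta1=se_beta1,
        beta1_p=beta1_p,
        beta_total=beta_total,
        se_beta_total=se_beta_total,
        total_p=total_p,
        indirect=indirect,
        indirect_se=ise,
        indirect_ci=ci,
        indirect_p=ip,
        proportion=prop,
        proportion_ci=prop_ci,
        n_boot=n_boot,
        seed=seed,
        admitted=admitted,
        **counts,
    )


def two_step_mediation(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    cfg: InstrumentConfig | None = None,
    mediator_label: str = "mediator",
    exposure_label: str = "exposure",
    n_boot: int = 1000,
    seed: int,
    ld: LDTable | None = None,
    palindrome_band: float = 0.08,
) -> MediationResult:
    """Run the full two-step mediation analysis on three summary tables.

    alpha comes from univariable IVW of exposure on mediator, beta1 from the
    mediator coefficient of the exposure-adjusted multivariable fit, and the
    total effect from univariable IVW of exposure on outcome; the indirect
    effect, delta-method CI, proportion mediated, and bootstrap proportion
    CI are assembled from them.
    """
    cfg = cfg or InstrumentConfig()

    # step 1: exposure -> mediator.  The outcome-association exclusion targets
    # the disease outcome; the mediator standing in the outcome slot of this
    # leg is itself causally downstream of the exposure, so screening against
    # it would remove exactly the instruments that carry the signal.
    step1_cfg = dataclasses.replace(cfg, outcome_p_exclude=0.0)
    ins1 = select_instruments(exposure, mediator, step1_cfg, ld=ld)
    h1 = harmonize_pair(ins1.table, mediator, palindrome_band=palindrome_band)
    alpha_est = ivw(h1, mode="auto")

    # total effect: exposure -> outcome
    ins_t = select_instruments(exposure, outcome, cfg, ld=ld)
    h_t = harmonize_pair(ins_t.table, outcome, palindrome_band=palindrome_band)
    total_est = ivw(h_t, mode="auto")

    # step 2: mediator -> outcome adjusted for exposure (MVMR)
    joint = mvmr_select_instruments(
        {mediator_label: mediator, exposure_label: exposure}, outcome, cfg, ld=ld
    )
    ids = set(joint.table["variant_id"].astype(str))
    med_sub = mediator[mediator["variant_id"].astype(str).isin(ids)]
    hm = harmonize_multi(
        med_sub,
        {exposure_label: exposure},
        outcome,
        palindrome_band=palindrome_band,
    )
    fit = mvmr_fit(hm, labels=[mediator_label, exposure_label])
    beta1, se_beta1, beta1_p = fit.coefficient(mediator_label)

    return assemble_mediation(
        mediator_label,
        alpha_est.b,
        alpha_est.se,
        alpha_est.p,
        beta1,
        se_beta1,
        beta1_p,
        total_est.b,
        total_est.se,
        total_est.p,
        n_boot=n_boot,
        seed=seed,
        nsnp_alpha=alpha_est.nsnp,
        nsnp_total=total_est.nsnp,
        nsnp_mvmr=fit.nsnp,
    )
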