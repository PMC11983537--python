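"""Multivariable MR: joint instrument selection and direct-effect estimation.

The multivariable fit regresses outcome effects on two or more aligned
exposure-effect columns without an intercept, weighted by 1/seY^2.  Each
coefficient is that exposure's direct effect conditional on the others; in
two-step mediation the mediator's coefficient adjusted for the exposure is
the second-stage estimate beta1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UsageError,
)
from .gwas_io import HarmonizedSet
from .instruments import (
    InstrumentConfig,
    InstrumentSet,
    LDTable,
    select_instruments,
)
from .uvmr import Z_95, _wls_with_floor

__all__ = ["MvmrFit", "mvmr_select_instruments", "mvmr_fit"]


@dataclass
class MvmrFit:
    """Per-exposure direct effects from a joint weighted regression."""

    exposures: list[str]
    theta: np.ndarray
    theta_se: np.ndarray
    theta_p: np.ndarray
    nsnp: int
    cond_note: str = ""

    def coefficient(self, label: str) -> tuple[float, float, float]:
        """Return ``(theta, se, p)`` for one exposure label."""
        try:
            i = self.exposures.index(label)
        except ValueError:
            raise UsageError(f"no exposure labelled {label!r} in fit") from None
        return float(self.theta[i]), float(self.theta_se[i]), float(self.theta_p[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "b": self.theta,
                "se": self.theta_se,
                "or": np.exp(self.theta),
                "ci_low": np.exp(self.theta - Z_95 * self.theta_se),
                "ci_high": np.exp(self.theta + Z_95 * self.theta_se),
                "p": self.theta_p,
                "nsnp": self.nsnp,
            }
        )


def mvmr_select_instruments(
    exposure_tables: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    cfg: InstrumentConfig | None = None,
    *,
    ld: LDTable | None = None,
) -> InstrumentSet:
    """Joint instrument selection across two or more exposures.

    Candidates are the union of variants genome-wide significant for any
    exposure, restricted to variants present in every exposure table and the
    outcome table.  Each candidate carries its minimum p-value across
    exposures (which drives joint clumping) and the summary row of the
    exposure achieving it; the remaining filters match univariable selection.
    """
    if len(exposure_tables) < 2:
        raise UsageError("multivariable selection requires >= 2 exposures")
    cfg = cfg or InstrumentConfig()
    indexed = {
        label: tab.drop_duplicates("variant_id").set_index("variant_id")
        for label, tab in exposure_tables.items()
    }
    outcome_ids = set(outcome["variant_id"].astype(str))
    common: set[str] = outcome_ids
    for tab in indexed.values():
        common = common & set(tab.index.astype(str))

    seen: list[str] = []
    for tab in exposure_tables.values():
        for vid in tab["variant_id"].astype(str):
            if vid in common and vid not in seen:
                seen.append(vid)

    rows = []
    for vid in seen:
        pvals = {label: float(tab.loc[vid, "pval"]) for label, tab in indexed.items()}
        best = min(pvals, key=lambda k: (pvals[k], k))
        row = indexed[best].loc[vid].to_dict()
        row["variant_id"] = vid
        row["pval"] = pvals[best]
        rows.append(row)
    if not rows:
        from .exceptions import EmptyInstrumentError

        raise EmptyInstrumentError(
            "no variant shared by all exposure tables and the outcome table"
        )
    candidates = pd.DataFrame(rows)
    return select_instruments(candidates, outcome, cfg, ld=ld)


def mvmr_fit(h: HarmonizedSet, labels: Sequence[str] | None = None) -> MvmrFit:
    """Weighted multiple regression of outcome effects on exposure effects.

    No intercept; weights 1/seY^2; coefficient covariance scaled by
    max(1, weighted RSS/(nsnp-K)).  The primary exposure of the harmonized
    set is the first column, followed by ``extra_exposures`` in insertion
    order.  ``labels`` names the columns (default: ``"exposure"`` plus the
    extra-exposure keys).
    """
    columns = [("exposure", h.exposure_beta)] + [
        (k, b) for k, (b, _) in h.extra_exposures.items()
    ]
    if labels is not None:
        if len(labels) != len(columns):
            raise UsageError(
                f"{len(labels)} labels supplied for {len(columns)} exposure columns"
            )
        columns = [(lab, col) for lab, (_, col) in zip(labels, columns)]
    names = [lab for lab, _ in columns]
    X = np.column_stack([col for _, col in columns])
    n, k = X.shape
    if n <= k:
        raise InsufficientInstrumentsError(
            f"multivariable MR needs more instruments ({n}) than exposures ({k})"
        )
    w = 1.0 / h.outcome_se**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < k:
        raise CollinearityError("exposure-effect columns are rank deficient")
    params, se, scale = _wls_with_floor(h.outcome_beta, X, w)
    p = np.array(
        [float(2.0 * stats.norm.sf(abs(b) / s)) if s > 0 else (0.0 if b else 1.0)
         for b, s in zip(params, se)]
    )
    cond = float(np.linalg.cond(Xw))
    note = (
        f"weighted design condition number {cond:.3g}; overdispersion scale "
        f"{scale:.3g} (floored at 1); conditional instrument-strength "
        "diagnostics not computed"
    )
    return MvmrFit(
        exposures=list(names),
        theta=params,
        theta_se=se,
        theta_p=p,
        nsnp=n,
        cond_note=note,
    )
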