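"""Instrumental-variable selection for two-sample MR.

Five filters are applied in a fixed order: genome-wide significance,
minor-allele frequency, greedy LD clumping, exclusion of variants associated
with the outcome, and exclusion of weak instruments by per-SNP F statistic.
Instrument strength uses the standardized-trait approximation
R^2 = 2*maf*(1-maf)*beta^2 and F = R^2*(n-k-1) / (k*(1-R^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, EmptyInstrumentError, InputError

__all__ = [
    "InstrumentConfig",
    "InstrumentSet",
    "LDTable",
    "per_snp_r2",
    "f_statistic",
    "clump",
    "select_instruments",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Selection thresholds; defaults follow standard two-sample MR practice.

    The outcome-association exclusion at p < 0.001 is far more permissive
    than the genome-wide threshold some pipelines use for this step; it is
    applied exactly as configured and is fully adjustable.  Setting
    ``outcome_p_exclude`` to 0 disables that filter.
    """

    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    outcome_p_exclude: float = 1e-3
    f_min: float = 10.0


def per_snp_r2(eaf, beta):
    """Variance in a standardized trait explained by one additive variant.

    Returns ``2*eaf*(1-eaf)*beta**2`` clipped to [0, 1).  This assumes a
    variance-one phenotype and is an approximation; it is what feeds the
    instrument-strength F statistic.
    """
    eaf_arr = np.asarray(eaf, dtype=float)
    beta_arr = np.asarray(beta, dtype=float)
    if np.any((eaf_arr <= 0.0) | (eaf_arr >= 1.0)):
        raise DegenerateInputError("per_snp_r2 requires 0 < eaf < 1")
    r2 = np.clip(2.0 * eaf_arr * (1.0 - eaf_arr) * beta_arr**2, 0.0, 1.0 - 1e-12)
    return float(r2) if np.isscalar(eaf) or eaf_arr.ndim == 0 else r2


def f_statistic(r2, n, k: int = 1):
    """Instrument-strength F = R^2*(n-k-1) / (k*(1-R^2))."""
    r2_arr = np.asarray(r2, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if k < 1:
        raise DegenerateInputError("f_statistic requires k >= 1")
    if np.any(n_arr <= k + 1):
        raise DegenerateInputError("f_statistic requires n > k + 1")
    if np.any((r2_arr < 0) | (r2_arr >= 1)):
        raise DegenerateInputError("f_statistic requires 0 <= r2 < 1")
    f = r2_arr * (n_arr - k - 1) / (k * (1.0 - r2_arr))
    return float(f) if np.isscalar(r2) or r2_arr.ndim == 0 else f


class LDTable:
    """Sparse symmetric pairwise r^2 lookup; absent pairs read as 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self._pairs[self._key(a, b)] = float(r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDTable":
        return cls(
            {
                (str(r.id_a), str(r.id_b)): float(r.r2)
                for r in df.itertuples(index=False)
            }
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        """Read a three-column (id_a, id_b, r2) TSV; symmetric closure applied."""
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)


def clump(
    candidates: pd.DataFrame,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns retained variant ids.

    The variant with the smallest p-value (ties broken lexicographically by
    rsID) is retained and every remaining variant on the same chromosome
    within ``window_kb`` with r^2 above ``r2_max`` is removed; variants
    lacking coordinates are compared by LD alone.  Without LD information
    clumping degrades to a no-op with a warning.
    """
    if candidates.empty:
        raise InputError("clump called on an empty candidate table")
    if ld is None or len(ld) == 0:
        warnings.warn(
            "no LD information supplied; LD clumping degrades to a no-op",
            UserWarning,
            stacklevel=2,
        )
        return [str(v) for v in candidates["variant_id"]]
    cols = ["variant_id", "pval"]
    has_pos = "chrom" in candidates.columns and "pos" in candidates.columns
    if has_pos:
        cols += ["chrom", "pos"]
    work = candidates[cols].copy()
    work["variant_id"] = work["variant_id"].astype(str)
    remaining = list(
        work.sort_values(["pval", "variant_id"], kind="mergesort").to_dict("records")
    )
    window_bp = window_kb * 1000.0

    def in_window(a: dict, b: dict) -> bool:
        if not has_pos:
            return True
        ca, cb = a.get("chrom"), b.get("chrom")
        pa, pb = a.get("pos"), b.get("pos")
        if ca is None or cb is None or pd.isna(pa) or pd.isna(pb):
            return True  # positional information missing: compare by LD only
        return str(ca) == str(cb) and abs(float(pa) - float(pb)) <= window_bp

    retained: list[str] = []
    while remaining:
        top = remaining.pop(0)
        retained.append(top["variant_id"])
        remaining = [
            r
            for r in remaining
            if not (
                in_window(top, r)
                and ld.r2(top["variant_id"], r["variant_id"]) > r2_max
            )
        ]
    return retained


@dataclass
class InstrumentSet:
    """Variants surviving all filters, with per-SNP strength diagnostics."""

    table: pd.DataFrame
    per_snp_r2: np.ndarray
    per_snp_f: np.ndarray
    filter_log: dict[str, int] = field(default_factory=dict)
    aggregate_f: float = float("nan")

    @property
    def nsnp(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["r2"] = self.per_snp_r2
        df["f_stat"] = self.per_snp_f
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    cfg: InstrumentConfig | None = None,
    *,
    ld: LDTable | None = None,
) -> InstrumentSet:
    """Apply the five instrument filters in order and log removals.

    Order: (1) exposure p-value < ``p_threshold``; (2) MAF > ``maf_min``;
    (3) LD clumping at ``clump_r2`` within ``clump_kb``; (4) removal of
    variants associated with the outcome at ``outcome_p_exclude``; (5)
    removal of per-SNP F (k=1) below ``f_min``.  Variants absent from the
    outcome table pass filter 4 (they are dropped later at harmonization).
    """
    cfg = cfg or InstrumentConfig()
    df = exposure.copy()
    log: dict[str, int] = {}

    mask = df["pval"] < cfg.p_threshold
    log["significance"] = int((~mask).sum())
    df = df[mask]

    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    mask = maf > cfg.maf_min
    log["maf"] = int((~mask).sum())
    df = df[mask]

    if df.empty:
        log["clump"] = 0
    else:
        kept = set(clump(df, ld=ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb))
        mask = df["variant_id"].astype(str).isin(kept)
        log["clump"] = int((~mask).sum())
        df = df[mask]

    outcome_p = outcome.drop_duplicates("variant_id").set_index("variant_id")["pval"]
    op = df["variant_id"].map(outcome_p)
    mask = ~(op < cfg.outcome_p_exclude)  # NaN (absent from outcome) passes
    log["outcome_association"] = int((~mask).sum())
    df = df[mask]

    if df.empty:
        log["weak_instrument"] = 0
        raise EmptyInstrumentError(
            f"no instruments survive selection; removals: {log}", filter_log=log
        )
    r2 = per_snp_r2(df["eaf"].to_numpy(), df["beta"].to_numpy())
    f = f_statistic(r2, df["n"].to_numpy(), k=1)
    mask = np.asarray(f >= cfg.f_min)
    log["weak_instrument"] = int((~mask).sum())
    df = df[mask]
    r2, f = np.asarray(r2)[mask], np.asarray(f)[mask]

    if df.empty:
        raise EmptyInstrumentError(
            f"no instruments survive selection; removals: {log}", filter_log=log
        )

    # aggregate F over the retained set (k = nSNP, summed R^2), logged as a
    # complement to the per-SNP values
    r2_sum = float(np.clip(r2.sum(), 0.0, 1.0 - 1e-12))
    n_med = float(np.median(df["n"]))
    k = len(df)
    agg_f = f_statistic(r2_sum, n_med, k=k) if n_med > k + 1 else float("nan")

    return InstrumentSet(
        table=df.reset_index(drop=True),
        per_snp_r2=np.asarray(r2, dtype=float),
        per_snp_f=np.asarray(f, dtype=float),
        filter_log=log,
        aggregate_f=agg_f,
    )
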