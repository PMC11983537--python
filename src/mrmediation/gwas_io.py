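"""GWAS summary-statistics IO and exposure-outcome allele harmonization.

Summary statistics are held as plain :class:`pandas.DataFrame` objects with
canonical column names (see :data:`REQUIRED_COLUMNS`); one row is one
variant-trait association (rsID, alleles, effect-allele frequency, additive
beta on the log-odds scale for binary traits, its SE, p-value, sample size).
Column dialects of common exports are mapped at read time.

Harmonization aligns every shared variant to the exposure study's effect
allele before any causal estimate is formed.  Strand-ambiguous (palindromic)
variants with intermediate allele frequency cannot be oriented from summary
data and are dropped; all other variants are kept, sign-flipped, or
strand-complemented, and every decision is recorded in a per-variant audit
log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError, UsageError

#: Canonical (logical) column names every summary-statistics table must carry.
REQUIRED_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Optional positional columns (1-based base-pair coordinates).
OPTIONAL_COLUMNS = ("chrom", "pos")

#: Column names as used by IEU-OpenGWAS-style flat exports.
IEU_DIALECT: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "chr",
    "pos": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

_BASES = frozenset({"A", "C", "G", "T"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization actions under which a variant stays in the analysis set.
RETAINED_ACTIONS = frozenset({"kept", "flipped", "strand_complemented"})


def validate_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw summary-statistics table into valid records and rejects.

    Checks every per-variant invariant (biallelic single-base alleles,
    positive SE, frequency and p-value ranges, positive sample size, unique
    rsID) and uppercases allele strings.  Returns ``(valid, rejects)`` where
    ``rejects`` carries a per-row ``reason`` column naming the first violated
    invariant.
    """
    df = table.copy().reset_index(drop=True)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        reasons[(reasons == "") & mask.fillna(True)] = reason

    flag(
        ~(df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)),
        "not a biallelic SNP",
    )
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(~np.isfinite(df["beta"]), "non-numeric beta")
    flag(~(df["se"] > 0), "nonpositive SE")
    flag(~df["eaf"].between(0.0, 1.0), "EAF outside [0, 1]")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "p-value outside (0, 1]")
    flag(~(df["n"] > 0), "nonpositive sample size")
    flag(df["variant_id"].duplicated(keep="first"), "duplicate variant_id")

    bad = reasons != ""
    rejects = df.loc[bad].assign(reason=reasons[bad]).reset_index(drop=True)
    valid = df.loc[~bad].reset_index(drop=True)
    if not valid.empty:
        valid["n"] = valid["n"].astype(np.int64)
    return valid, rejects


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    return_rejects: bool = False,
):
    """Read a tab-separated summary-statistics table into canonical form.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Mapping from canonical column names to the file's column names.
        Defaults to the identity mapping; :data:`IEU_DIALECT` covers
        IEU-OpenGWAS-style exports.
    return_rejects
        Also return the table of rejected rows with their reasons.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(dialect or {})
    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = mapping.get(canonical, canonical)
        if source not in raw.columns:
            raise ConfigError(
                f"required column '{source}' (logical '{canonical}') "
                f"missing from {path}"
            )
        rename[source] = canonical
    for canonical in OPTIONAL_COLUMNS:
        source = mapping.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    df = raw.rename(columns=rename)
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep]
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    if df.empty:
        raise InputError(f"empty summary-statistics table: {path}")
    valid, rejects = validate_table(df)
    if valid.empty:
        raise InputError(
            f"no valid records in {path} ({len(rejects)} rows rejected)"
        )
    if return_rejects:
        return valid, rejects
    return valid


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical summary-statistics table as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class Alignment:
    """Outcome-side result of aligning one variant to the exposure's alleles."""

    action: str
    outcome_beta: float
    outcome_eaf: float


def align_alleles(
    exposure: Mapping, outcome: Mapping, palindrome_band: float = 0.08
) -> Alignment:
    """Align one outcome record to the exposure record's effect allele.

    Identical allele pairs are kept as-is, swapped pairs have the outcome beta
    negated (eaf -> 1-eaf), strand-complement pairs are complemented first.
    Palindromic pairs (A/T, C/G) cannot be resolved from allele labels: they
    are dropped when either study's effect-allele frequency lies within
    ``palindrome_band`` of 0.5, and otherwise oriented by whether the two
    frequencies fall on the same side of 0.5.  Anything else is incompatible.
    """
    if str(exposure["variant_id"]) != str(outcome["variant_id"]):
        raise UsageError(
            "align_alleles called on different variants: "
            f"{exposure['variant_id']!r} vs {outcome['variant_id']!r}"
        )
    ea_x = str(exposure["effect_allele"]).upper()
    oa_x = str(exposure["other_allele"]).upper()
    ea_y = str(outcome["effect_allele"]).upper()
    oa_y = str(outcome["other_allele"]).upper()
    beta = float(outcome["beta"])
    eaf = float(outcome["eaf"])

    if not ({ea_x, oa_x} <= _BASES and {ea_y, oa_y} <= _BASES):
        return Alignment("dropped_incompatible", beta, eaf)

    if _COMPLEMENT[ea_x] == oa_x:  # palindromic pair
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return Alignment("dropped_incompatible", beta, eaf)
        lo, hi = 0.5 - palindrome_band, 0.5 + palindrome_band
        eaf_x = float(exposure["eaf"])
        if lo < eaf_x < hi or lo < eaf < hi:
            return Alignment("dropped_palindromic", beta, eaf)
        if (eaf_x - 0.5) * (eaf - 0.5) > 0:
            return Alignment("kept", beta, eaf)
        return Alignment("flipped", -beta, 1.0 - eaf)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return Alignment("kept", beta, eaf)
    if (ea_y, oa_y) == (oa_x, ea_x):
        return Alignment("flipped", -beta, 1.0 - eaf)
    comp = (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])
    if comp == (ea_x, oa_x):
        return Alignment("strand_complemented", beta, eaf)
    if comp == (oa_x, ea_x):
        return Alignment("strand_complemented", -beta, 1.0 - eaf)
    return Alignment("dropped_incompatible", beta, eaf)


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    All per-variant arrays share one length and ordering (the exposure input
    order).  ``extra_exposures`` holds additional aligned effect columns for
    multivariable MR, keyed by exposure label.  ``actions`` is the per-variant
    audit log over *all* input variants, including dropped ones.
    """

    variants: np.ndarray
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    exposure_eaf: np.ndarray | None = None
    extra_exposures: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    actions: pd.DataFrame | None = None

    @property
    def nsnp(self) -> int:
        return len(self.variants)

    def subset(self, keep) -> "HarmonizedSet":
        """Return the harmonized set restricted to a boolean/index mask."""
        keep = np.asarray(keep)
        return replace(
            self,
            variants=self.variants[keep],
            exposure_beta=self.exposure_beta[keep],
            exposure_se=self.exposure_se[keep],
            outcome_beta=self.outcome_beta[keep],
            outcome_se=self.outcome_se[keep],
            exposure_eaf=None if self.exposure_eaf is None else self.exposure_eaf[keep],
            extra_exposures={
                k: (b[keep], s[keep]) for k, (b, s) in self.extra_exposures.items()
            },
            actions=None
            if self.actions is None
            else self.actions[
                self.actions["variant_id"].isin(self.variants[keep])
                | ~self.actions["action"].isin(RETAINED_ACTIONS)
            ].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variants,
                "exposure_beta": self.exposure_beta,
                "exposure_se": self.exposure_se,
                "outcome_beta": self.outcome_beta,
                "outcome_se": self.outcome_se,
            }
        )
        for label, (b, s) in self.extra_exposures.items():
            df[f"beta_{label}"] = b
            df[f"se_{label}"] = s
        return df


def _records(table: pd.DataFrame) -> dict[str, dict]:
    return {r["variant_id"]: r for r in table.to_dict("records")}


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    palindrome_band: float = 0.08,
) -> HarmonizedSet:
    """Inner-join two summary tables on rsID and align alleles per variant.

    Dropped variants are excluded from the effect arrays but appear in the
    ``actions`` audit log with a reason.  Ordering follows the exposure table.
    Raises :class:`InputError` when the tables share no variant.
    """
    out_by_id = _records(outcome)
    shared = [v for v in exposure["variant_id"] if v in out_by_id]
    if not shared:
        raise InputError(
            "no shared variants between exposure and outcome tables "
            f"({len(exposure)} vs {len(outcome)} records)"
        )
    ids, bx, sx, by, sy, fx = [], [], [], [], [], []
    log_rows = []
    for row in exposure.to_dict("records"):
        vid = row["variant_id"]
        if vid not in out_by_id:
            log_rows.append((vid, "dropped_unmatched", "absent from outcome table"))
            continue
        al = align_alleles(row, out_by_id[vid], palindrome_band)
        if al.action in RETAINED_ACTIONS:
            ids.append(vid)
            bx.append(float(row["beta"]))
            sx.append(float(row["se"]))
            fx.append(float(row["eaf"]))
            by.append(al.outcome_beta)
            sy.append(float(out_by_id[vid]["se"]))
            log_rows.append((vid, al.action, ""))
        elif al.action == "dropped_palindromic":
            log_rows.append((vid, al.action, "palindromic with intermediate EAF"))
        else:
            log_rows.append((vid, al.action, "incompatible allele configuration"))
    actions = pd.DataFrame(log_rows, columns=["variant_id", "action", "reason"])
    return HarmonizedSet(
        variants=np.asarray(ids, dtype=object),
        exposure_beta=np.asarray(bx, dtype=float),
        exposure_se=np.asarray(sx, dtype=float),
        outcome_beta=np.asarray(by, dtype=float),
        outcome_se=np.asarray(sy, dtype=float),
        exposure_eaf=np.asarray(fx, dtype=float),
        actions=actions,
    )


def harmonize_multi(
    primary: pd.DataFrame,
    extras: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    *,
    palindrome_band: float = 0.08,
) -> HarmonizedSet:
    """Harmonize a primary exposure, extra exposures, and the outcome jointly.

    The primary exposure's effect allele defines the orientation.  Variants
    missing from, or unalignable in, any extra exposure table are dropped so
    the multivariable design matrix is complete.
    """
    h = harmonize_pair(primary, outcome, palindrome_band=palindrome_band)
    prim_by_id = _records(primary)
    keep = np.ones(h.nsnp, dtype=bool)
    extra_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, table in extras.items():
        tab_by_id = _records(table)
        betas = np.full(h.nsnp, np.nan)
        ses = np.full(h.nsnp, np.nan)
        for i, vid in enumerate(h.variants):
            if not keep[i]:
                continue
            rec = tab_by_id.get(vid)
            if rec is None:
                keep[i] = False
                continue
            al = align_alleles(prim_by_id[vid], rec, palindrome_band)
            if al.action not in RETAINED_ACTIONS:
                keep[i] = False
                continue
            betas[i] = al.outcome_beta
            ses[i] = float(rec["se"])
        extra_cols[label] = (betas, ses)
    h.extra_exposures = extra_cols
    return h.subset(keep)


def write_harmonization_audit(h: HarmonizedSet, path: str | Path) -> None:
    """Write the per-variant harmonization audit log as TSV."""
    if h.actions is None:
        raise UsageError("harmonized set carries no audit log")
    h.actions.to_csv(path, sep="\t", index=False)
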