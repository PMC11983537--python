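"""Synthetic GWAS summary statistics from a known structural model.

The generator works at the summary-statistic level: no individual genotypes
are drawn.  A linear structural model links three traits,

    exposure  --alpha-->  mediator  --beta1-->  outcome
         \\________________tau_____________________/

with three classes of independent biallelic instruments: exposure
instruments (per-SNP effect gamma_j), mediator-specific instruments
(delta_m, giving the mediator variation of its own so the multivariable
direct effect is identifiable), and optional outcome-specific instruments
(eta_k, the "disease loci" a reverse-direction analysis draws on).  True
marginal effects are

    exposure: gamma_j
    mediator: alpha*gamma_j + delta_j
    outcome : (tau + alpha*beta1)*gamma_j + beta1*delta_j + eta_j + pi_j

where pi_j is per-SNP horizontal pleiotropy (none, balanced, directional,
or correlated with gamma to break the InSIDE assumption).  Observed betas
add normal noise with the standard GWAS standard error
se = (2*n*maf*(1-maf))^(-1/2); for the binary outcome the SE carries the
case-fraction factor (phi*(1-phi))^(-1/2) of a logistic GWAS.  Per study
and per SNP the reported effect allele is chosen at random, so
harmonization is exercised end to end.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .gwas_io import write_summary_stats

__all__ = [
    "Pleiotropy",
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_study",
    "reference_mediation_inputs",
]

_NONPALINDROMIC = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Pleiotropy:
    """Per-SNP horizontal-pleiotropy model for the outcome GWAS."""

    kind: str = "none"  # none | balanced | directional | inside_violation
    mean: float = 0.0
    sd: float = 0.0
    correlation: float = 0.0

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls(kind="balanced", sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls(kind="directional", mean=mean, sd=sd)

    @classmethod
    def inside_violation(cls, correlation: float, sd: float) -> "Pleiotropy":
        """Pleiotropy correlated with instrument strength (InSIDE broken)."""
        return cls(kind="inside_violation", sd=sd, correlation=correlation)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one synthetic three-trait study.

    Defaults describe a well-powered European-biobank-scale design: 100
    exposure and 100 mediator instruments, 100k samples per GWAS, moderate
    per-SNP instrument effects (SD 0.05 on a standardized trait), a binary
    outcome with the case fraction of a large nephropathy meta-analysis
    (~3.3%), and a mediation structure alpha=-0.2, beta1=0.5, tau=-0.7
    whose true proportion mediated is 12.5%.
    """

    n_snps: int = 100
    n_mediator_snps: int = 100
    n_outcome_snps: int = 0
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    alpha_true: float = -0.2
    beta1_true: float = 0.5
    tau_true: float = -0.7
    gamma_sd: float = 0.05
    delta_sd: float = 0.05
    eta_sd: float = 0.05
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    maf_range: tuple[float, float] = (0.05, 0.5)
    outcome_case_fraction: float | None = 0.0326
    palindromic_fraction: float = 0.0
    ld_blocks: tuple[int, float] | None = None  # (block size, within-block r2)
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_snps < 4:
            bad.append("n_snps must be >= 4")
        if self.n_mediator_snps < 0 or self.n_outcome_snps < 0:
            bad.append("instrument counts must be nonnegative")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                bad.append(f"{name} must be >= 100")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            bad.append("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.gamma_sd <= 0:
            bad.append("gamma_sd must be positive")
        if self.pleiotropy.kind not in {
            "none",
            "balanced",
            "directional",
            "inside_violation",
        }:
            bad.append(f"unknown pleiotropy kind {self.pleiotropy.kind!r}")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            bad.append("palindromic_fraction must lie in [0, 1]")
        if self.outcome_case_fraction is not None and not (
            0.0 < self.outcome_case_fraction < 1.0
        ):
            bad.append("outcome_case_fraction must lie in (0, 1)")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 2 or not 0.0 <= r2 <= 1.0:
                bad.append("ld_blocks must be (size >= 2, r2 in [0, 1])")
        if bad:
            raise ConfigError("invalid SimConfig: " + "; ".join(bad))


@dataclass
class SimTruth:
    """Generating parameters plus derived totals, for recovery tests."""

    alpha_true: float
    beta1_true: float
    tau_true: float
    total_effect: float
    proportion_true: float
    variant_ids: list[str]
    roles: list[str]
    gamma: np.ndarray
    delta: np.ndarray
    eta: np.ndarray
    pleio: np.ndarray
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha_true": self.alpha_true,
            "beta1_true": self.beta1_true,
            "tau_true": self.tau_true,
            "total_effect": self.total_effect,
            "proportion_true": self.proportion_true,
            "variant_ids": self.variant_ids,
            "roles": self.roles,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "eta": self.eta.tolist(),
            "pleio": self.pleio.tolist(),
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimStudy:
    """Three simulated summary-statistics tables plus the generating truth."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    truth: SimTruth
    ld: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("exposure", "mediator", "outcome"):
            paths[name] = outdir / f"{name}.tsv"
            write_summary_stats(getattr(self, name), paths[name])
        paths["truth"] = outdir / "truth.json"
        self.truth.to_json(paths["truth"])
        if self.ld is not None:
            paths["ld"] = outdir / "ld.tsv"
            self.ld.to_csv(paths["ld"], sep="\t", index=False)
        return paths


def _pleiotropy_draw(cfg: SimConfig, gamma: np.ndarray, rng) -> np.ndarray:
    p = cfg.pleiotropy
    m = gamma.size
    if p.kind == "none":
        return np.zeros(m)
    if p.kind == "balanced":
        return rng.normal(0.0, p.sd, size=m)
    if p.kind == "directional":
        return rng.normal(p.mean, p.sd, size=m)
    # inside_violation: correlate with instrument strength
    z = rng.normal(size=m)
    scaled = gamma / cfg.gamma_sd
    return p.sd * (p.correlation * scaled + np.sqrt(1 - p.correlation**2) * z)


def _layout(cfg: SimConfig, roles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome/position layout; LD blocks sit contiguously within 100 kb."""
    m = roles.size
    idx = np.arange(m)
    chrom = (idx % 22) + 1
    pos = 1_000_000 + (idx // 22) * 20_000_000  # 20 Mb apart: outside any clump window
    if cfg.ld_blocks is not None:
        size, _ = cfg.ld_blocks
        exp_idx = np.flatnonzero(roles == "exposure")
        block = np.arange(exp_idx.size) // size
        within = np.arange(exp_idx.size) % size
        chrom[exp_idx] = (block % 22) + 1
        pos[exp_idx] = 1_000_000 + (block // 22) * 20_000_000 + within * 10_000
        other = np.flatnonzero(roles != "exposure")
        pos[other] = 500_000_000 + (np.arange(other.size) // 22) * 20_000_000
    return chrom, pos


def simulate_study(cfg: SimConfig | None = None) -> SimStudy:
    """Draw one synthetic exposure/mediator/outcome study from ``cfg``."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    m = cfg.n_snps + cfg.n_mediator_snps + cfg.n_outcome_snps
    roles = np.array(
        ["exposure"] * cfg.n_snps
        + ["mediator"] * cfg.n_mediator_snps
        + ["outcome"] * cfg.n_outcome_snps
    )
    ids = [f"rs{1_000_001 + i}" for i in range(m)]
    maf = rng.uniform(*cfg.maf_range, size=m)
    chrom, pos = _layout(cfg, roles)

    is_pal = rng.random(m) < cfg.palindromic_fraction
    pair_idx = rng.integers(0, 8, size=m)
    pal_idx = rng.integers(0, 4, size=m)
    ea = np.where(
        is_pal,
        [_PALINDROMIC[i][0] for i in pal_idx],
        [_NONPALINDROMIC[i][0] for i in pair_idx],
    )
    oa = np.where(
        is_pal,
        [_PALINDROMIC[i][1] for i in pal_idx],
        [_NONPALINDROMIC[i][1] for i in pair_idx],
    )

    gamma = np.zeros(m)
    gamma[roles == "exposure"] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snps)
    delta = np.zeros(m)
    delta[roles == "mediator"] = rng.normal(
        0.0, cfg.delta_sd, size=cfg.n_mediator_snps
    )
    eta = np.zeros(m)
    eta[roles == "outcome"] = rng.normal(0.0, cfg.eta_sd, size=cfg.n_outcome_snps)
    # pleiotropy acts in the exposure-increasing allele frame: a directional
    # mean shift defined against arbitrary allele coding would cancel out
    pleio = _pleiotropy_draw(cfg, gamma, rng) * np.where(gamma < 0, -1.0, 1.0)

    total = cfg.tau_true + cfg.alpha_true * cfg.beta1_true
    true_effects = {
        "exposure": gamma,
        "mediator": cfg.alpha_true * gamma + delta,
        "outcome": total * gamma + cfg.beta1_true * delta + eta + pleio,
    }
    sizes = {
        "exposure": cfg.n_exposure,
        "mediator": cfg.n_mediator,
        "outcome": cfg.n_outcome,
    }

    def emit(study: str) -> pd.DataFrame:
        n = sizes[study]
        se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
        if study == "outcome" and cfg.outcome_case_fraction is not None:
            phi = cfg.outcome_case_fraction
            se = se / np.sqrt(phi * (1.0 - phi))
        beta = true_effects[study] + rng.normal(size=m) * se
        flip = rng.random(m) < 0.5  # reported effect allele is arbitrary
        eaf = np.where(flip, 1.0 - maf, maf)
        beta = np.where(flip, -beta, beta)
        pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": np.where(flip, oa, ea),
                "other_allele": np.where(flip, ea, oa),
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n,
            }
        )

    tables = {s: emit(s) for s in ("exposure", "mediator", "outcome")}

    ld_df = None
    if cfg.ld_blocks is not None:
        size, r2 = cfg.ld_blocks
        rows = []
        exp_ids = [ids[i] for i in np.flatnonzero(roles == "exposure")]
        for start in range(0, len(exp_ids), size):
            block = exp_ids[start : start + size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    rows.append((block[i], block[j], r2))
        ld_df = pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])

    truth = SimTruth(
        alpha_true=cfg.alpha_true,
        beta1_true=cfg.beta1_true,
        tau_true=cfg.tau_true,
        total_effect=total,
        proportion_true=(
            100.0 * cfg.alpha_true * cfg.beta1_true / total
            if total != 0
            else float("nan")
        ),
        variant_ids=ids,
        roles=list(roles),
        gamma=gamma,
        delta=delta,
        eta=eta,
        pleio=pleio,
        config=cfg,
    )
    return SimStudy(
        exposure=tables["exposure"],
        mediator=tables["mediator"],
        outcome=tables["outcome"],
        truth=truth,
        ld=ld_df,
    )


def reference_mediation_inputs() -> pd.DataFrame:
    """Published two-step estimates for the educational-attainment pathway.

    Log-odds estimates and SEs from a published two-sample MR study of
    educational attainment and IgA nephropathy: the IVW effect of education
    on each mediator (``alpha``), the education-adjusted multivariable
    effect of each mediator on IgAN (``beta1``), and the univariable total
    effect of education on IgAN (``beta_total`` = log 0.433, its SE
    back-derived from the reported 95% CI 0.334-0.560).  Used as direct
    inputs to the mediation arithmetic in regression tests; no genotype or
    per-variant data are involved.
    """
    beta_total = float(np.log(0.433))
    se_total = float((np.log(0.560) - np.log(0.334)) / (2 * 1.959963984540054))
    rows = [
        ("insomnia", -0.195, 0.028, 0.506, 0.185),
        ("body_mass_index", -0.686, 0.065, 0.127, 0.041),
        ("waist_circumference", -0.505, 0.054, 0.155, 0.052),
    ]
    return pd.DataFrame(
        [
            {
                "mediator": name,
                "alpha": a,
                "se_alpha": sa,
                "beta1": b,
                "se_beta1": sb,
                "beta_total": beta_total,
                "se_beta_total": se_total,
            }
            for name, a, sa, b, sb in rows
        ]
    )
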