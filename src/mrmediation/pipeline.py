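"""Run orchestration: forward/reverse MR pairs, sensitivity battery, mediation screen.

A :class:`RunConfig` (usually loaded from YAML) names the summary-statistics
tables and their roles, the selection thresholds, and the analysis flags.
``run_pair`` executes the full univariable battery for one exposure-outcome
pair (selection, harmonization, IVW/Egger/weighted-median, Cochran's Q,
leave-one-out, optional MR-PRESSO) and writes tidy TSV report tables plus a
JSON run log sufficient to replay the run.  ``run_bidirectional`` runs a
pair in both directions; ``run_mediation_screen`` runs the two-step
mediation analysis over a list of candidate mediators.

Every stochastic stage derives its seed deterministically from the run seed
and a stage tag, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import uvmr
from .exceptions import ConfigError, EmptyInstrumentError, MRError
from .gwas_io import (
    IEU_DIALECT,
    HarmonizedSet,
    harmonize_pair,
    read_summary_stats,
)
from .instruments import InstrumentConfig, InstrumentSet, LDTable, select_instruments
from .mediation import MediationResult, two_step_mediation
from .presso import PressoResult, run_presso

logger = logging.getLogger("mrmediation")

__all__ = [
    "StudySpec",
    "RunConfig",
    "ReportBundle",
    "run_pair",
    "run_bidirectional",
    "run_mediation_screen",
]

_DIALECTS = {"canonical": None, "ieu": IEU_DIALECT}


def derive_seed(base: int, *tags: int) -> int:
    """Deterministic per-stage seed below 2^31 derived from the run seed."""
    state = np.random.SeedSequence([int(base), *[int(t) for t in tags]])
    return int(state.generate_state(1)[0] % (2**31))


@dataclass
class StudySpec:
    path: Path
    role: str  # exposure | mediator | outcome


@dataclass
class RunConfig:
    """Validated run configuration for the pipeline entry points."""

    studies: dict[str, StudySpec]
    thresholds: InstrumentConfig = field(default_factory=InstrumentConfig)
    presso: bool = True
    presso_nsim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    out_dir: Path = Path("mr_results")
    ld_path: Path | None = None
    dialect: str = "canonical"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "studies" not in raw:
            raise ConfigError(f"run config {path} must define a 'studies' mapping")
        base = Path(path).parent
        studies = {}
        for label, spec in raw["studies"].items():
            p = Path(spec["path"])
            if not p.is_absolute():
                p = base / p
            studies[label] = StudySpec(path=p, role=spec["role"])
        thresholds = InstrumentConfig(**raw.get("thresholds", {}))
        ld = raw.get("ld")
        ld_path = None
        if ld:
            ld_path = Path(ld)
            if not ld_path.is_absolute():
                ld_path = base / ld_path
        out = Path(raw.get("out_dir", "mr_results"))
        if not out.is_absolute():
            out = base / out
        cfg = cls(
            studies=studies,
            thresholds=thresholds,
            presso=bool(raw.get("presso", True)),
            presso_nsim=int(raw.get("presso_nsim", 1000)),
            n_boot=int(raw.get("n_boot", 1000)),
            seed=int(raw.get("seed", 0)),
            out_dir=out,
            ld_path=ld_path,
            dialect=str(raw.get("dialect", "canonical")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        roles = [s.role for s in self.studies.values()]
        for label, spec in self.studies.items():
            if spec.role not in {"exposure", "mediator", "outcome"}:
                problems.append(f"study {label!r} has unknown role {spec.role!r}")
            if not Path(spec.path).exists():
                problems.append(f"study {label!r}: file not found: {spec.path}")
        if roles.count("outcome") != 1:
            problems.append("exactly one study must have role 'outcome'")
        if self.dialect not in _DIALECTS:
            problems.append(f"unknown dialect {self.dialect!r}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            problems.append(f"LD file not found: {self.ld_path}")
        if problems:
            raise ConfigError("invalid run config: " + "; ".join(problems))

    def load(self, label: str) -> pd.DataFrame:
        if label not in self.studies:
            raise ConfigError(f"no study labelled {label!r} in config")
        return read_summary_stats(
            self.studies[label].path, dialect=_DIALECTS[self.dialect]
        )

    def ld_table(self) -> LDTable | None:
        return LDTable.from_tsv(self.ld_path) if self.ld_path else None


@dataclass
class ReportBundle:
    """Everything one exposure-outcome run produced, plus where it went."""

    exposure: str
    outcome: str
    estimates: dict[str, uvmr.MREstimate] = field(default_factory=dict)
    instruments: InstrumentSet | None = None
    harmonized: HarmonizedSet | None = None
    leave_one_out: pd.DataFrame | None = None
    presso: PressoResult | None = None
    out_dir: Path | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return "error" in self.diagnostics

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates.values():
            row = {"exposure": self.exposure, "outcome": self.outcome}
            row.update(est.to_row())
            rows.append(row)
        return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pair(
    cfg: RunConfig, exposure_label: str, outcome_label: str
) -> ReportBundle:
    """Full univariable battery for one exposure-outcome pair.

    Raises :class:`EmptyInstrumentError` (with the filter log attached) when
    selection empties the candidate set; estimators needing more instruments
    than available are skipped and noted in the diagnostics.
    """
    logger.info("run_pair start exposure=%s outcome=%s", exposure_label, outcome_label)
    exposure = cfg.load(exposure_label)
    outcome = cfg.load(outcome_label)
    ld = cfg.ld_table()

    ins = select_instruments(exposure, outcome, cfg.thresholds, ld=ld)
    logger.info("instruments selected nsnp=%d log=%s", ins.nsnp, ins.filter_log)
    h = harmonize_pair(ins.table, outcome)
    logger.info("harmonized nsnp=%d", h.nsnp)
    if h.nsnp == 0:
        raise EmptyInstrumentError(
            "all selected instruments dropped at harmonization",
            filter_log=ins.filter_log,
        )

    bundle = ReportBundle(
        exposure=exposure_label, outcome=outcome_label, instruments=ins, harmonized=h
    )
    bundle.estimates["ivw"] = uvmr.ivw(h, mode="auto")
    if h.nsnp >= 3:
        bundle.estimates["egger"] = uvmr.egger(h)
        bundle.estimates["wm"] = uvmr.weighted_median(
            h, cfg.n_boot, seed=derive_seed(cfg.seed, 1)
        )
        bundle.leave_one_out = uvmr.leave_one_out(h)
    else:
        bundle.diagnostics["sensitivity"] = (
            f"only {h.nsnp} instruments: Egger/WM/leave-one-out skipped"
        )
    if cfg.presso and h.nsnp >= 4:
        bundle.presso = run_presso(
            h, cfg.presso_nsim, seed=derive_seed(cfg.seed, 2)
        )
    elif cfg.presso:
        bundle.diagnostics["presso"] = f"only {h.nsnp} instruments: MR-PRESSO skipped"

    out = Path(cfg.out_dir) / f"{exposure_label}__vs__{outcome_label}"
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.results_frame(), out / "results.tsv")
    ins.write_tsv(out / "instruments.tsv")
    h.actions.to_csv(out / "harmonization.tsv", sep="\t", index=False)
    _write_tsv(uvmr.scatter_data(h), out / "scatter.tsv")
    _write_tsv(uvmr.funnel_data(h), out / "funnel.tsv")
    if bundle.leave_one_out is not None:
        _write_tsv(bundle.leave_one_out, out / "leave_one_out.tsv")
    if bundle.presso is not None:
        (out / "presso.json").write_text(json.dumps(bundle.presso.to_dict(), indent=1))
    run_log = {
        "exposure": exposure_label,
        "outcome": outcome_label,
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "presso": cfg.presso,
        "presso_nsim": cfg.presso_nsim,
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "nsnp": h.nsnp,
        "filter_log": ins.filter_log,
        "aggregate_f": ins.aggregate_f,
        "diagnostics": bundle.diagnostics,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    bundle.out_dir = out
    logger.info("run_pair done exposure=%s outcome=%s", exposure_label, outcome_label)
    return bundle


def run_bidirectional(
    cfg: RunConfig, a_label: str, b_label: str
) -> tuple[ReportBundle, ReportBundle]:
    """Run a pair in both directions; failures are isolated per direction."""
    bundles = []
    for x, y in ((a_label, b_label), (b_label, a_label)):
        try:
            bundles.append(run_pair(cfg, x, y))
        except MRError as err:
            logger.warning("direction %s->%s failed: %s", x, y, err)
            bundle = ReportBundle(exposure=x, outcome=y)
            bundle.diagnostics["error"] = str(err)
            if isinstance(err, EmptyInstrumentError):
                bundle.diagnostics["filter_log"] = err.filter_log
            bundles.append(bundle)
    fwd, rev = bundles

    def _sig(b: ReportBundle) -> bool:
        return (not b.failed) and b.estimates["ivw"].p < 0.05

    summary = pd.DataFrame(
        [
            {
                "direction": f"{b.exposure}->{b.outcome}",
                "nsnp": 0 if b.failed else b.estimates["ivw"].nsnp,
                "b": float("nan") if b.failed else b.estimates["ivw"].b,
                "p": float("nan") if b.failed else b.estimates["ivw"].p,
                "significant": _sig(b),
                "note": b.diagnostics.get("error", ""),
            }
            for b in bundles
        ]
    )
    summary["both_directions_significant"] = bool(_sig(fwd) and _sig(rev))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(summary, out / f"bidirectional__{a_label}__{b_label}.tsv")
    return fwd, rev


def run_mediation_screen(
    cfg: RunConfig,
    exposure_label: str,
    mediator_labels: list[str],
    outcome_label: str,
) -> tuple[pd.DataFrame, list[MediationResult | None]]:
    """Two-step mediation over candidate mediators; failures recorded inline."""
    exposure = cfg.load(exposure_label)
    outcome = cfg.load(outcome_label)
    ld = cfg.ld_table()
    rows, results = [], []
    for i, label in enumerate(mediator_labels):
        logger.info("mediation screen mediator=%s", label)
        try:
            res = two_step_mediation(
                exposure,
                cfg.load(label),
                outcome,
                cfg=cfg.thresholds,
                mediator_label=label,
                exposure_label=exposure_label,
                n_boot=cfg.n_boot,
                seed=derive_seed(cfg.seed, 3, i),
                ld=ld,
            )
            results.append(res)
            row = res.to_row()
            row["note"] = "" if res.admitted else "not admitted"
            rows.append(row)
        except MRError as err:
            logger.warning("mediator %s failed: %s", label, err)
            results.append(None)
            rows.append({"mediator": label, "note": f"error: {err}"})
    table = pd.DataFrame(rows)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, out / "mediation.tsv")
    path_rows = [r.path_row() for r in results if r is not None]
    if path_rows:
        _write_tsv(pd.DataFrame(path_rows), out / "path_diagram.tsv")
    return table, results
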