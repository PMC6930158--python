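"""End-to-end screening pipeline.

Composes the full analysis on one cohort: join -> responder labels ->
per-gene ROC screen -> per-gene cutoff scans -> combination search ->
signature survival -> multivariate Cox -> pCR check, writing a stable
directory of TSV report tables.  Identical config + seed produce
byte-identical report files; wall-clock information goes only to the
side log (run.log), which is outside the determinism contract.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import join_cohort, load_clinical, load_expression
from .errors import StageError, ValidationError
from .roc import (
    RocResult,
    analyze_pcr,
    derive_responder_labels,
    roc_table,
    screen_genes,
)
from .signatures import (
    CombinationRecord,
    SignatureDefinition,
    builtin_signatures,
    combination_table,
    enumerate_combinations,
    multivariate_cox,
    signature_outcome,
)
from .simulate import SimulationConfig, reference_scenarios, simulate_cohort
from .survival import CutoffScanResult, outcome_screen, outcome_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration with study-condition defaults.

    Either ``preset`` (a reference scenario name) or both input paths
    must be given.  ``max_combo_genes`` caps the candidate list for the
    exhaustive combination search at the genes with the smallest ROC
    p-values.
    """

    preset: str | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    subtype_filter: str | None = None
    treatment_filter: str | None = None
    seed: int = 0
    horizon: float = 60.0
    fdr_level: float = 0.10
    combo_mode: str = "exhaustive"
    combo_min_size: int = 2
    max_combo_genes: int = 10
    fdr_scope: str = "within_gene"

    def __post_init__(self):
        if self.preset is None and (self.expression_path is None or self.clinical_path is None):
            raise ValidationError("config needs a preset or both input paths")
        if self.preset is not None and self.preset not in reference_scenarios():
            raise ValidationError(
                f"unknown preset {self.preset!r}; choices: {sorted(reference_scenarios())}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    """All pipeline outputs for one run, as DataFrames plus metadata."""

    cohort_summary: dict
    gene_roc: pd.DataFrame
    gene_outcome: pd.DataFrame
    combinations: pd.DataFrame
    signature_outcomes: pd.DataFrame
    multivariate: pd.DataFrame
    pcr_roc: pd.DataFrame
    metadata: dict
    roc_results: list[RocResult] = field(default_factory=list, repr=False)
    scan_results: list[CutoffScanResult] = field(default_factory=list, repr=False)
    combination_records: list[CombinationRecord] = field(default_factory=list, repr=False)

    _TABLES = (
        "gene_roc", "gene_outcome", "combinations",
        "signature_outcomes", "multivariate", "pcr_roc",
    )

    def write(self, outdir) -> None:
        """Write the report directory atomically (stage then rename)."""
        outdir = Path(outdir)
        staging = outdir.with_name(outdir.name + ".staging")
        if staging.exists():
            shutil.rmtree(staging)
        staging.mkdir(parents=True)
        try:
            for name in self._TABLES:
                getattr(self, name).to_csv(
                    staging / f"{name}.tsv", sep="\t", index=False, na_rep="NA"
                )
            with open(staging / "report.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {"cohort_summary": self.cohort_summary, "metadata": self.metadata},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
        except BaseException:
            shutil.rmtree(staging, ignore_errors=True)
            raise
        if outdir.exists():
            shutil.rmtree(outdir)
        staging.rename(outdir)


def _stage(name):
    """Wrap stage execution so failures carry the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _signature_row(name, genes, scan: CutoffScanResult) -> dict:
    return {
        "signature": name,
        "genes": "+".join(genes),
        "best_cutoff": scan.best_cutoff,
        "n_low": scan.n_low,
        "n_high": scan.n_high,
        "min_p": scan.min_p,
        "hr": scan.hr,
        "ci_low": scan.ci_low,
        "ci_high": scan.ci_high,
        "fdr_q": scan.best_q,
        "significant": int(bool(scan.significant)),
    }


def run_screen(config: RunConfig) -> ScreenReport:
    """Execute the full screen and return the assembled report.

    Stage order: cohort -> responder labels -> gene ROC -> gene outcome
    scans -> combination search -> signature survival -> multivariate
    Cox -> pCR screen.  Any stage failure raises StageError naming the
    stage.
    """
    with _stage("cohort"):
        if config.preset is not None:
            sim = dataclasses.replace(reference_scenarios()[config.preset],
                                      seed=config.seed)
            expr, clin = simulate_cohort(sim)
        else:
            expr = load_expression(config.expression_path)
            clin = load_clinical(config.clinical_path)
        expr, clin = join_cohort(expr, clin, config.subtype_filter,
                                 config.treatment_filter)
        surv = clin.survival()

    with _stage("responder_labels"):
        labels = derive_responder_labels(surv, horizon=config.horizon)

    with _stage("gene_roc"):
        roc_results = screen_genes(expr, labels, fdr_level=config.fdr_level)
        gene_roc = roc_table(roc_results)

    with _stage("gene_outcome"):
        scan_results = outcome_screen(
            expr, surv, fdr_level=config.fdr_level, fdr_scope=config.fdr_scope
        )
        gene_outcome = outcome_table(scan_results)

    with _stage("combinations"):
        # combinations are built only over individually significant genes,
        # mirroring the screen's selection rule; under a global null the
        # combination stage therefore (correctly) produces no records
        sig_genes = [r.name for r in roc_results if r.significant]
        combo_genes = sig_genes[: config.max_combo_genes]
        if len(combo_genes) >= 2:
            combo_records = enumerate_combinations(
                combo_genes, expr, labels,
                mode=config.combo_mode,
                min_size=config.combo_min_size,
                fdr_level=config.fdr_level,
            )
        else:
            combo_records = []
        combos = combination_table(combo_records)

    with _stage("signature_outcome"):
        rows = []
        evaluated: list[tuple[str, SignatureDefinition]] = []
        present = set(expr.genes)
        for sig in builtin_signatures():
            if set(sig.genes) <= present:
                evaluated.append((sig.name, sig))
            else:
                logger.info("skipping builtin signature %s (genes absent)", sig.name)
        if combo_records:
            top = combo_records[0]
            evaluated.append(
                ("top_combination", SignatureDefinition("top_combination", top.genes))
            )
        for name, sig in evaluated:
            scan = signature_outcome(expr, sig, surv, fdr_level=config.fdr_level)
            rows.append(_signature_row(name, sig.genes, scan))
        signature_outcomes = pd.DataFrame(
            rows, columns=["signature", "genes", "best_cutoff", "n_low", "n_high",
                           "min_p", "hr", "ci_low", "ci_high", "fdr_q", "significant"]
        )

    with _stage("multivariate_cox"):
        mv_rows = []
        target: SignatureDefinition | None = None
        headline = next(s for s in builtin_signatures() if s.name == "headline")
        if set(headline.genes) <= present:
            target = headline
        elif combo_records:
            target = SignatureDefinition("top_combination", combo_records[0].genes)
        if target is not None:
            usable = tuple(
                c for c in ("nodal_status", "grade", "age")
                if pd.to_numeric(clin.data[c], errors="coerce").notna().sum() > 0
                and pd.to_numeric(clin.data[c], errors="coerce").nunique() > 1
            )
            if usable:
                fit = multivariate_cox(expr, target, surv, clin, covariates=usable)
                for i, cov in enumerate(fit.covariates):
                    mv_rows.append({
                        "signature": target.name,
                        "covariate": cov,
                        "coef": fit.coef[i],
                        "hr": fit.hr[i],
                        "ci_low": fit.ci_low[i],
                        "ci_high": fit.ci_high[i],
                        "wald_p": fit.wald_p[i],
                        "n": fit.n,
                        "n_events": fit.n_events,
                    })
        multivariate = pd.DataFrame(
            mv_rows, columns=["signature", "covariate", "coef", "hr", "ci_low",
                              "ci_high", "wald_p", "n", "n_events"]
        )

    with _stage("pcr"):
        try:
            pcr_results = analyze_pcr(expr, clin, fdr_level=config.fdr_level)
            pcr_roc = roc_table(pcr_results)
        except ValidationError as exc:
            logger.info("pCR analysis skipped: %s", exc)
            pcr_roc = roc_table([])

    summary = {
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "n_events": surv.n_events,
        "n_responder": labels.n_responder,
        "n_nonresponder": labels.n_nonresponder,
        "n_excluded": labels.n_excluded,
    }
    metadata = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    return ScreenReport(
        cohort_summary=summary,
        gene_roc=gene_roc,
        gene_outcome=gene_outcome,
        combinations=combos,
        signature_outcomes=signature_outcomes,
        multivariate=multivariate,
        pcr_roc=pcr_roc,
        metadata=metadata,
        roc_results=roc_results,
        scan_results=scan_results,
        combination_records=combo_records,
    )


def run_screen_to_dir(config: RunConfig, outdir) -> ScreenReport:
    """Run the screen and write the report directory plus run.log."""
    t0 = _time.time()
    report = run_screen(config)
    report.write(outdir)
    with open(Path(outdir) / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"config_hash: {report.metadata['config_hash']}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"elapsed_seconds: {_time.time() - t0:.2f}\n")
        fh.write(f"finished_at_unix: {_time.time():.0f}\n")
    return report
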