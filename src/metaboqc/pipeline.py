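"""End-to-end pipeline: validate, normalize, flag, correct, score, export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import QCConfig
from .correction import (CorrectedTable, CorrectionModel, apply_between_batch,
                         fit_between_batch, within_batch_correct)
from .io import StudyTable, ValidationReport, read_input
from .metrics import CompoundMetrics, compute_metrics
from .normalization import RatioTable, compute_ratios
from .outliers import OutlierFlags, combine_flags, flag_qc_outliers, \
    flag_sample_outliers


class ValidationError(RuntimeError):
    """Raised when the input fails fatal validation checks."""

    def __init__(self, report: ValidationReport):
        super().__init__("; ".join(report.errors))
        self.report = report


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    table: StudyTable
    report: ValidationReport
    ratios: RatioTable
    flags: OutlierFlags
    model: CorrectionModel
    corrected: CorrectedTable
    metrics: CompoundMetrics


def run_pipeline(table: StudyTable, report: ValidationReport | None = None,
                 config: QCConfig | None = None,
                 batch_correction: bool = True) -> PipelineResult:
    """Run the full QC pipeline on a validated study table.

    Order of operations: IS ratios -> QC and study-sample outlier tests ->
    between-batch median correction (QC outliers excluded) -> optional
    within-batch detrending (``config.within_batch_correction``) ->
    per-compound metrics and confidence tiers. With ``batch_correction``
    False the corrected ratios equal the raw ratios (pass-through).
    """
    config = config or QCConfig()
    report = report or ValidationReport()

    ratios = compute_ratios(table)
    qc_flags = flag_qc_outliers(table, ratios, config)
    sample_flags = flag_sample_outliers(table, config)
    flags = combine_flags(qc_flags, sample_flags)

    if batch_correction:
        model = fit_between_batch(table, ratios, flags, config)
        corrected = apply_between_batch(table, ratios, model)
        if config.within_batch_correction:
            corrected = within_batch_correct(table, corrected, flags, config,
                                             model=model)
    else:
        model = CorrectionModel(factors=pd.DataFrame(
            columns=["compound", "batch", "batch_median", "grand_median",
                     "factor"]))
        frame = ratios.frame.rename(columns={"ratio": "corrected_ratio"})
        frame = frame[["aliquot", "compound", "corrected_ratio"]].copy()
        frame["correction_applied"] = "none"
        corrected = CorrectedTable(frame=frame)

    metrics = compute_metrics(table, ratios, corrected, flags, config)
    return PipelineResult(table=table, report=report, ratios=ratios,
                          flags=flags, model=model, corrected=corrected,
                          metrics=metrics)


def run_file(path: str | Path, config: QCConfig | None = None,
             outdir: str | Path | None = None,
             batch_correction: bool = True,
             plots: bool = True) -> PipelineResult:
    """Read an input file, run the pipeline, optionally export results.

    Raises :class:`ValidationError` when the input has fatal problems.
    """
    config = config or QCConfig()
    table, report = read_input(path, config)
    if table is None or not report.ok:
        raise ValidationError(report)
    result = run_pipeline(table, report, config,
                          batch_correction=batch_correction)
    if outdir is not None:
        from .reporting import export_report
        export_report(result.table, result.ratios, result.corrected,
                      result.metrics, result.flags, result.model,
                      result.report, config, outdir, plots=plots)
    return result
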