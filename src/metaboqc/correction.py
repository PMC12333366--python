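"""Between-batch and within-batch correction of area ratios.

Between batches, technical shifts (mobile-phase changes, column swaps,
sensitivity drift over weeks) scale every ratio of a compound within a batch
by an approximately constant factor. Because the correction QCs are
replicate injections of one pool, the per-batch QC median of a compound
estimates that factor, and dividing the pooled (all-batch) QC median by it
gives a multiplicative correction::

    f(compound, batch) = grand QC median / batch QC median
    corrected ratio    = f(compound, batch) x ratio

After correction every batch's QC median equals the grand median, so the
compound is on one common scale across batches. With a single batch all
factors are 1 (nothing to align).

Within a batch, gradual sensitivity loss shows up as a linear trend of the
QC ratios against injection order. The optional within-batch step fits a
first-order regression to the QC ratios per (compound, batch), divides each
aliquot's ratio by the fitted trend at its injection index, and rescales by
the batch QC median so the between-batch alignment is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCConfig
from .io import StudyTable
from .normalization import RatioTable
from .outliers import OutlierFlags


@dataclass
class CorrectionModel:
    """Fitted per-(compound, batch) correction factors.

    ``factors`` has columns ``compound, batch, batch_median, grand_median,
    factor``; the factor is missing when the batch median is non-positive or
    no usable QC ratio exists. ``drift_fits`` (filled by
    :func:`within_batch_correct`) has columns ``compound, batch,
    drift_slope, drift_intercept``.
    """

    factors: pd.DataFrame
    drift_fits: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Exportable table, one row per (compound, batch)."""
        out = self.factors.copy()
        if self.drift_fits is not None and not self.drift_fits.empty:
            out = out.merge(self.drift_fits, on=["compound", "batch"],
                            how="left")
        else:
            out["drift_slope"] = np.nan
            out["drift_intercept"] = np.nan
        return out


@dataclass
class CorrectedTable:
    """Per-(aliquot, compound) corrected ratios.

    ``frame`` columns: ``aliquot, compound, corrected_ratio,
    correction_applied`` with the latter one of ``none``, ``between``,
    ``between+within``.
    """

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def matrix(self) -> pd.DataFrame:
        return self.frame.pivot(index="aliquot", columns="compound",
                                values="corrected_ratio")


def usable_qc_ratios(table: StudyTable, ratios: RatioTable,
                     flags: OutlierFlags | None) -> pd.DataFrame:
    """Correction-QC ratio rows with auto-excluded aliquots removed."""
    qc = set(table.qc_aliquots)
    if flags is not None:
        qc -= flags.excluded_aliquots
    f = ratios.frame
    out = f[f["aliquot"].isin(qc) & f["ratio"].notna()].copy()
    out["batch"] = out["aliquot"].map(table.aliquots["batch"])
    return out


def fit_between_batch(table: StudyTable, ratios: RatioTable,
                      flags: OutlierFlags | None = None,
                      config: QCConfig | None = None) -> CorrectionModel:
    """Fit per-(compound, batch) median correction factors.

    The batch median is taken over that compound's ratios in the
    non-excluded correction QCs of the batch; the grand median pools the
    same ratios over all batches (or takes the median of batch medians when
    ``config.pooled_grand_median`` is False). Single-batch studies get
    factor 1 for every compound. Non-positive or missing batch medians
    leave the factor undefined.
    """
    config = config or QCConfig()
    warnings: list[str] = []
    batches = table.batches
    compounds = table.compounds
    qc = usable_qc_ratios(table, ratios, flags)

    grid = pd.MultiIndex.from_product([compounds, batches],
                                      names=["compound", "batch"])
    if len(batches) <= 1:
        factors = pd.DataFrame(index=grid).reset_index()
        factors["batch_median"] = np.nan
        factors["grand_median"] = np.nan
        factors["factor"] = 1.0
        if not qc.empty:
            bm = qc.groupby(["compound", "batch"])["ratio"].median()
            factors["batch_median"] = bm.reindex(grid).to_numpy()
            factors["grand_median"] = factors["batch_median"]
        return CorrectionModel(factors=factors, warnings=warnings)

    batch_median = (qc.groupby(["compound", "batch"])["ratio"].median()
                    .reindex(grid))
    if config.pooled_grand_median:
        grand = qc.groupby("compound")["ratio"].median()
    else:
        grand = batch_median.groupby("compound").median()
    grand = grand.reindex(compounds)

    factors = pd.DataFrame(index=grid).reset_index()
    factors["batch_median"] = batch_median.to_numpy()
    factors["grand_median"] = factors["compound"].map(grand).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = factors["grand_median"] / factors["batch_median"]
    f[factors["batch_median"] <= 0] = np.nan
    factors["factor"] = f

    no_signal = grand.index[grand.isna()]
    for compound in no_signal:
        warnings.append(f"compound '{compound}': no usable QC ratio in any "
                        "batch; correction factors undefined")
    return CorrectionModel(factors=factors, warnings=warnings)


def apply_between_batch(table: StudyTable, ratios: RatioTable,
                        model: CorrectionModel) -> CorrectedTable:
    """Multiply every ratio by its (compound, batch) correction factor.

    Applied to every sample type. Missing ratios and undefined factors
    propagate to missing corrected ratios (the latter with a warning).
    """
    f = ratios.frame.copy()
    f["batch"] = f["aliquot"].map(table.aliquots["batch"])
    factors = model.factors.set_index(["compound", "batch"])["factor"]
    fac = factors.reindex(pd.MultiIndex.from_frame(f[["compound", "batch"]]))
    corrected = f["ratio"].to_numpy() * fac.to_numpy()

    warnings = []
    undefined = fac.isna().to_numpy() & f["ratio"].notna().to_numpy()
    if undefined.any():
        for compound in sorted(f.loc[undefined, "compound"].unique()):
            warnings.append(f"compound '{compound}': correction factor "
                            "undefined for some batches; ratios dropped")
    frame = pd.DataFrame({
        "aliquot": f["aliquot"],
        "compound": f["compound"],
        "corrected_ratio": corrected,
        "correction_applied": "between",
    })
    return CorrectedTable(frame=frame, warnings=warnings)


def within_batch_correct(table: StudyTable, corrected: CorrectedTable,
                         flags: OutlierFlags | None = None,
                         config: QCConfig | None = None,
                         compounds: list[str] | None = None,
                         model: CorrectionModel | None = None) -> CorrectedTable:
    """Remove linear within-batch drift, preserving each batch's QC median.

    Per (compound, batch) with at least ``config.min_qc_for_drift`` usable
    correction QCs, an ordinary least-squares line of QC corrected ratios
    against injection index is fitted; every aliquot's ratio is then
    multiplied by ``batch QC median / trend(injection index)``. Batches
    where the fitted trend is non-positive anywhere are left untouched
    (extrapolation invalid) with a warning. ``compounds`` limits the
    correction to a subset (per-compound opt-in); when ``model`` is given
    its ``drift_fits`` table is filled in.
    """
    config = config or QCConfig()
    warnings: list[str] = []
    qc = set(table.qc_aliquots)
    if flags is not None:
        qc -= flags.excluded_aliquots

    f = corrected.frame.copy()
    f["batch"] = f["aliquot"].map(table.aliquots["batch"])
    f["injection_index"] = f["aliquot"].map(table.aliquots["injection_index"])
    f["is_qc"] = f["aliquot"].isin(qc)

    target = set(compounds) if compounds is not None else None
    out = f["corrected_ratio"].to_numpy(copy=True)
    applied = f["correction_applied"].to_numpy(copy=True).astype(object)
    fits: list[dict] = []

    for (compound, batch), idx in f.groupby(["compound", "batch"]).groups.items():
        if target is not None and compound not in target:
            continue
        rows = f.loc[idx]
        qc_rows = rows[rows["is_qc"] & rows["corrected_ratio"].notna()]
        if len(qc_rows) < config.min_qc_for_drift:
            continue
        slope, intercept = np.polyfit(qc_rows["injection_index"],
                                      qc_rows["corrected_ratio"], deg=1)
        trend = slope * rows["injection_index"].to_numpy() + intercept
        if np.any(trend <= 0):
            warnings.append(
                f"compound '{compound}', batch {batch}: fitted drift trend "
                "non-positive within the batch; within-batch correction skipped")
            continue
        m_b = qc_rows["corrected_ratio"].median()
        pos = f.index.get_indexer(idx)
        out[pos] = out[pos] * m_b / trend
        applied[pos] = np.where(f.loc[idx, "corrected_ratio"].notna(),
                                "between+within", applied[pos])
        fits.append({"compound": compound, "batch": batch,
                     "drift_slope": slope, "drift_intercept": intercept})

    frame = pd.DataFrame({
        "aliquot": f["aliquot"],
        "compound": f["compound"],
        "corrected_ratio": out,
        "correction_applied": applied,
    })
    if model is not None:
        model.drift_fits = pd.DataFrame(
            fits, columns=["compound", "batch", "drift_slope", "drift_intercept"])
    return CorrectedTable(frame=frame,
                          warnings=corrected.warnings + warnings)
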