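"""Per-compound quality metrics and confidence classification.

Three metrics summarise how trustworthy a compound's measurements are:

* **RSDqc** — relative standard deviation (%) of the compound's corrected
  ratios over all pooled correction-QC injections: ``sd / mean x 100``
  (sample standard deviation, n-1). Because the QCs are replicates, RSDqc
  is a direct estimate of the technical precision. It is computed both
  before and after batch correction to show the correction's benefit.
* **Background signal** — mean peak area in blank injections divided by the
  median peak area in study samples, as a percentage. High background means
  the measured signal is not biological.
* **QC detection rate** — percentage of QC injections in which the compound
  was detected (area present and positive).

Compounds are then classified: RSDqc below 15% (default) is "high
confidence"; RSDqc above 30% or background above 40% is "low signal to
noise"; the rest is "with caution". A compound undetected in every QC is
not reported at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import QCConfig
from .correction import CorrectedTable
from .io import StudyTable
from .normalization import RatioTable
from .outliers import OutlierFlags


class Tier(str, Enum):
    """Confidence tier of a compound."""

    HIGH_CONFIDENCE = "high_confidence"
    WITH_CAUTION = "with_caution"
    LOW_SIGNAL_TO_NOISE = "low_signal_to_noise"
    NOT_REPORTED = "not_reported"


#: Report-workbook tab names per tier (not-reported compounds get no tab).
TAB_NAMES = {
    Tier.HIGH_CONFIDENCE: "High confidence",
    Tier.WITH_CAUTION: "With Caution",
    Tier.LOW_SIGNAL_TO_NOISE: "Low Signal to Noise",
}


@dataclass
class CompoundMetrics:
    """Quality metrics for every compound.

    ``frame`` is indexed by compound with columns ``is_used, rsdqc_pre,
    rsdqc_post, background, qc_detection, tier``.
    """

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def tier_counts(self) -> pd.Series:
        return self.frame["tier"].value_counts()


def _rsd_percent(values: pd.Series) -> float:
    """sd/mean x 100 with the sample (n-1) standard deviation."""
    values = values.dropna()
    if len(values) < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1) / mean * 100.0)


def compute_rsdqc(values: pd.DataFrame, table: StudyTable,
                  flags: OutlierFlags | None = None,
                  config: QCConfig | None = None,
                  value_col: str = "corrected_ratio") -> pd.Series:
    """Per-compound RSDqc (%) over pooled non-excluded correction QCs.

    ``values`` is a long frame with aliquot/compound/value columns (a
    ratio or corrected-ratio frame). Compounds with fewer than two usable
    QC values, or a zero mean, get NaN.
    """
    config = config or QCConfig()
    qc = set(table.qc_aliquots)
    if flags is not None:
        qc -= flags.excluded_aliquots
    sub = values[values["aliquot"].isin(qc)]
    rsd = sub.groupby("compound")[value_col].apply(_rsd_percent)
    return rsd.reindex(table.compounds).rename("rsdqc")


def compute_background(table: StudyTable, config: QCConfig | None = None
                       ) -> tuple[pd.Series, list[str]]:
    """Per-compound background signal (%): mean blank area / median study area.

    Blank set is BLANK-type aliquots (optionally plus PROC via config).
    Missing when there are no blanks, no study samples, or the study
    median is zero for the compound.
    """
    config = config or QCConfig()
    warnings: list[str] = []
    blank_types = ["BLANK"] + (["PROC"] if config.include_proc_in_blanks else [])
    blanks = table.aliquots_of_type(*blank_types)
    samples = table.sample_aliquots
    compounds = table.compounds
    if len(blanks) == 0:
        warnings.append("no blank injections: background signal unavailable")
        return pd.Series(np.nan, index=compounds, name="background"), warnings
    if len(samples) == 0:
        warnings.append("no study samples: background signal unavailable")
        return pd.Series(np.nan, index=compounds, name="background"), warnings

    d = table.data
    blank_mean = (d[d["aliquot"].isin(blanks)]
                  .groupby("compound")["area"].mean())
    study_median = (d[d["aliquot"].isin(samples)]
                    .groupby("compound")["area"].median())
    with np.errstate(divide="ignore", invalid="ignore"):
        bg = blank_mean / study_median * 100.0
    bg[study_median == 0] = np.nan
    zero_median = study_median.index[study_median == 0]
    for compound in zero_median:
        warnings.append(f"compound '{compound}': study-sample median area is "
                        "zero; background signal undefined")
    return bg.reindex(compounds).rename("background"), warnings


def compute_qc_detection(table: StudyTable, config: QCConfig | None = None
                         ) -> pd.Series:
    """Percentage of QC injections (SQC and LQC) detecting each compound.

    "Detected" means a present, strictly positive peak area.
    """
    qcs = table.aliquots_of_type("SQC", "LQC")
    compounds = table.compounds
    if len(qcs) == 0:
        return pd.Series(np.nan, index=compounds, name="qc_detection")
    d = table.data[table.data["aliquot"].isin(qcs)]
    detected = d["area"].notna() & (d["area"] > 0)
    rate = detected.groupby(d["compound"]).mean() * 100.0
    return rate.reindex(compounds).rename("qc_detection")


def classify_compound(rsdqc_post: float, background: float,
                      detected_in_qc: bool = True,
                      config: QCConfig | None = None) -> Tier:
    """Assign a confidence tier from RSDqc (post-correction) and background.

    Low signal-to-noise when RSDqc exceeds ``rsd_caution_max`` or background
    exceeds ``background_max`` (both strict); high confidence when RSDqc is
    strictly below ``rsd_high_max`` and not low; with caution otherwise —
    values exactly at the 15/30/40 boundaries land in "with caution" /
    not-low. A compound undetected in every QC, or without a defined
    RSDqc, is not reported.
    """
    config = config or QCConfig()
    if not detected_in_qc or rsdqc_post is None or not np.isfinite(rsdqc_post):
        return Tier.NOT_REPORTED
    background_low = np.isfinite(background) and background > config.background_max
    if rsdqc_post > config.rsd_caution_max or background_low:
        return Tier.LOW_SIGNAL_TO_NOISE
    if rsdqc_post < config.rsd_high_max:
        return Tier.HIGH_CONFIDENCE
    return Tier.WITH_CAUTION


def compute_metrics(table: StudyTable, ratios: RatioTable,
                    corrected: CorrectedTable,
                    flags: OutlierFlags | None = None,
                    config: QCConfig | None = None) -> CompoundMetrics:
    """Assemble the full per-compound metrics table and classify tiers."""
    config = config or QCConfig()
    rsd_pre = compute_rsdqc(ratios.frame, table, flags, config,
                            value_col="ratio")
    rsd_post = compute_rsdqc(corrected.frame, table, flags, config,
                             value_col="corrected_ratio")
    background, bg_warnings = compute_background(table, config)
    detection = compute_qc_detection(table, config)

    is_used = (ratios.frame.groupby("compound")["is_used"].first()
               .reindex(table.compounds))
    frame = pd.DataFrame({
        "is_used": is_used,
        "rsdqc_pre": rsd_pre.to_numpy(),
        "rsdqc_post": rsd_post.to_numpy(),
        "background": background.to_numpy(),
        "qc_detection": detection.to_numpy(),
    }, index=pd.Index(table.compounds, name="compound"))

    detected = frame["qc_detection"].fillna(0) > 0
    frame["tier"] = [
        classify_compound(row.rsdqc_post, row.background,
                          detected_in_qc=det, config=config).value
        for row, det in zip(frame.itertuples(), detected)
    ]
    return CompoundMetrics(frame=frame, warnings=bg_warnings)
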