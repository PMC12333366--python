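"""Pipeline configuration.

All thresholds and test parameters used anywhere in the pipeline live in
:class:`QCConfig`, so a single object documents (and lets the user override)
every tunable. Defaults follow common practice for targeted LC-MS quality
control: an RSDqc acceptance threshold of 30% with a 15% high-confidence
band, a 40% ceiling on blank background signal, a minimum of four QC
injections per batch with at most 15 study samples between consecutive QCs,
and at least two blank injections per batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

#: Sample-type labels with fixed meaning. Calibration series (CAL1, CAL2, ...
#: in matrix; ACAL1, ... in water) are recognised by prefix, see
#: :func:`metaboqc.io.parse_sample_type`.
KNOWN_TYPES = frozenset({"SQC", "LQC", "BLANK", "PROC", "SAMPLE", "SST"})

#: QC types usable as the replicated reference for correction and RSDqc.
QC_TYPES = frozenset({"SQC", "LQC"})


@dataclass
class QCConfig:
    """Thresholds and parameters for the QC pipeline.

    Attributes
    ----------
    rsd_high_max:
        RSDqc (%) strictly below which a compound is "High confidence".
    rsd_caution_max:
        RSDqc (%) strictly above which a compound is "Low Signal to Noise";
        values in ``[rsd_high_max, rsd_caution_max]`` are "With Caution".
    background_max:
        Background signal (%) strictly above which a compound is
        "Low Signal to Noise" regardless of its RSDqc.
    min_qc_per_batch:
        Minimum number of correction-QC injections expected per batch.
    max_samples_between_qc:
        Maximum number of consecutive study samples allowed between two
        correction-QC injections before a spacing warning is raised.
    min_blank_injections:
        Minimum number of BLANK injections expected per batch.
    correction_qc_type:
        QC sample type used for batch correction and RSDqc ("SQC" or
        "LQC"). When no sample of this type exists the pipeline falls back
        to the other QC type with a warning.
    pooled_grand_median:
        When True (default) the grand median in the between-batch factor is
        the median over all pooled QC ratios; when False it is the median
        of the per-batch medians.
    esd_alpha:
        Two-sided significance level for the generalized ESD outlier test.
    esd_max_k_fraction:
        Upper bound on the number of outliers tested, as a fraction of n
        (``max_k = max(1, floor(n * esd_max_k_fraction))``).
    min_n_for_esd:
        Below this sample size the ESD test is skipped (returns no flags).
    pool_esd_across_batches:
        Run the QC outlier test on QCs pooled over batches (default) or
        per batch.
    min_qc_for_drift:
        Minimum usable QCs per (compound, batch) for within-batch
        drift fitting.
    within_batch_correction:
        Global toggle for within-batch first-order detrending (off by
        default; drift correction is opt-in).
    is_min_qc_presence:
        Minimum fraction of QC samples in which a candidate internal
        standard must be measured for it to enter IS suggestions.
    include_proc_in_blanks:
        Include PROC (procedure blank) aliquots in the background-signal
        blank set in addition to BLANK.
    datetime_format:
        Required strptime format of the input datetime column.
    """

    # classification
    rsd_high_max: float = 15.0
    rsd_caution_max: float = 30.0
    background_max: float = 40.0
    # batch design
    min_qc_per_batch: int = 4
    max_samples_between_qc: int = 15
    min_blank_injections: int = 2
    # correction
    correction_qc_type: str = "SQC"
    pooled_grand_median: bool = True
    min_qc_for_drift: int = 4
    within_batch_correction: bool = False
    # outlier testing
    esd_alpha: float = 0.05
    esd_max_k_fraction: float = 0.2
    min_n_for_esd: int = 10
    pool_esd_across_batches: bool = True
    # IS suggestions
    is_min_qc_presence: float = 0.8
    # metrics
    include_proc_in_blanks: bool = False
    # parsing
    datetime_format: str = "%Y-%m-%d %H:%M:%S"

    def __post_init__(self) -> None:
        if not 0 < self.rsd_high_max < self.rsd_caution_max:
            raise ValueError(
                "require 0 < rsd_high_max < rsd_caution_max, got "
                f"{self.rsd_high_max} and {self.rsd_caution_max}"
            )
        if self.background_max <= 0:
            raise ValueError("background_max must be positive")
        if self.correction_qc_type not in QC_TYPES:
            raise ValueError(f"correction_qc_type must be one of {sorted(QC_TYPES)}")
        if not 0 < self.esd_alpha < 1:
            raise ValueError("esd_alpha must be in (0, 1)")

    def esd_max_k(self, n: int) -> int:
        """Maximum outlier count tested by the ESD procedure for n points."""
        return max(1, int(n * self.esd_max_k_fraction))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "QCConfig":
        """Build a config from a (possibly partial) key-value mapping.

        Unknown keys raise ``ValueError`` so configuration typos fail fast.
        """
        valid = {f.name for f in fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
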