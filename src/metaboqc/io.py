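"""Reading, validating and structuring the peak-area input table.

The expected input is a long-format, tab-separated table with one row per
(aliquot, compound) observation and the header columns::

    aliquot  type  batch  compound  area  [compound_is  area_is]  datetime

``area``/``area_is`` cells are decimal numbers, the literal ``NA``, or empty
(the latter two mark missing data). ``datetime`` must follow
``year-month-day hours:minutes:seconds``. ``batch`` is optional; when absent
every aliquot is assigned batch "1" and a warning is recorded. Any extra
columns (retention time, replicate, ...) are carried along untouched for
plotting.

Validation completes the aliquot x compound grid — every aliquot gets a row
for every compound, inserting missing areas where the file had none — and
derives the injection order from the datetime column (stable sort, ties keep
file order).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import KNOWN_TYPES, QC_TYPES, QCConfig

REQUIRED_COLUMNS = ("aliquot", "type", "compound", "area", "datetime")
CORE_COLUMNS = ("aliquot", "type", "batch", "compound", "area",
                "compound_is", "area_is", "datetime")

_CAL_RE = re.compile(r"^(ACAL|CAL)(\d+)$")
_MISSING = {"", "NA"}


def parse_sample_type(label: str) -> tuple[str, int | None]:
    """Split a sample-type label into (code, calibration level).

    ``"CAL3"`` -> ``("CAL", 3)``; ``"SQC"`` -> ``("SQC", None)``. Labels that
    are neither a known type nor a calibration label are returned unchanged
    with level ``None`` (the caller decides how to treat them).
    """
    m = _CAL_RE.match(label)
    if m:
        return m.group(1), int(m.group(2))
    return label, None


def is_known_type(label: str) -> bool:
    code, level = parse_sample_type(label)
    if code in KNOWN_TYPES:
        return True
    return code in {"CAL", "ACAL"} and level is not None and level >= 1


def is_calibration(label: str) -> bool:
    code, level = parse_sample_type(label)
    return code in {"CAL", "ACAL"} and level is not None


@dataclass
class ValidationReport:
    """Findings from input validation and batch-design checks.

    ``errors`` are fatal (the pipeline refuses to proceed), ``warnings`` are
    advisory. ``counts`` tallies aliquots per (batch, type).
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, msg: str) -> None:
        self.errors.append(msg)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)

    def to_text(self) -> str:
        lines: list[str] = []
        for e in self.errors:
            lines.append(f"ERROR\t{e}")
        for w in self.warnings:
            lines.append(f"WARNING\t{w}")
        if self.counts is not None:
            for row in self.counts.itertuples():
                lines.append(f"COUNT\t{row.batch}\t{row.type}\t{row.n}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_dict(self) -> dict:
        d = {"errors": list(self.errors), "warnings": list(self.warnings)}
        if self.counts is not None:
            d["counts"] = self.counts.to_dict(orient="records")
        return d


@dataclass
class StudyTable:
    """A validated study: complete measurement grid plus per-aliquot facts.

    Attributes
    ----------
    data:
        Long-format frame with one row per (aliquot, compound), columns
        ``aliquot, type, batch, compound, area, compound_is, area_is,
        datetime`` plus any extra input columns. The grid is complete:
        ``len(data) == n_aliquots * n_compounds``.
    aliquots:
        Per-aliquot frame indexed by aliquot id with columns ``type, batch,
        datetime, injection_index``; the injection index is a 1-based rank
        by ascending datetime (ties keep input order).
    qc_type_for_correction:
        The QC sample type ("SQC" or "LQC") used as the replicated
        reference downstream.
    """

    data: pd.DataFrame
    aliquots: pd.DataFrame
    qc_type_for_correction: str = "SQC"

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound"].unique())

    @property
    def batches(self) -> list:
        """Batch labels ordered by first appearance in injection order."""
        ordered = self.aliquots.sort_values("injection_index")
        return list(dict.fromkeys(ordered["batch"]))

    def aliquots_of_type(self, *types: str) -> pd.Index:
        mask = self.aliquots["type"].isin(types)
        return self.aliquots.index[mask]

    @property
    def qc_aliquots(self) -> pd.Index:
        return self.aliquots_of_type(self.qc_type_for_correction)

    @property
    def sample_aliquots(self) -> pd.Index:
        return self.aliquots_of_type("SAMPLE")

    def is_area_matrix(self) -> pd.DataFrame:
        """Aliquot x internal-standard matrix of IS peak areas.

        Built from the (compound_is, area_is) pairs of the long table; when
        several compounds share an IS the first non-missing area per
        (aliquot, IS) wins (they are replicate reports of one measurement).
        """
        d = self.data.dropna(subset=["compound_is"])
        d = d.dropna(subset=["area_is"])
        if d.empty:
            return pd.DataFrame(index=self.aliquots.index)
        mat = d.pivot_table(index="aliquot", columns="compound_is",
                            values="area_is", aggfunc="first")
        return mat.reindex(self.aliquots.index)


def _parse_numeric(raw: pd.Series, column: str, report: ValidationReport) -> pd.Series:
    """Parse a text column into floats; 'NA'/'' become NaN, junk is fatal."""
    stripped = raw.astype(str).str.strip()
    missing = stripped.isin(_MISSING)
    parsed = pd.to_numeric(stripped.where(~missing), errors="coerce")
    bad = parsed.isna() & ~missing
    if bad.any():
        rows = [str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:5]]
        report.error(
            f"column '{column}' contains non-numeric, non-NA values "
            f"(file line(s) {', '.join(rows)})"
        )
    negative = parsed < 0
    if negative.any():
        rows = [str(i + 2) for i in np.flatnonzero(negative.to_numpy())[:5]]
        report.error(
            f"column '{column}' contains negative values "
            f"(file line(s) {', '.join(rows)})"
        )
    return parsed.astype(float)


def derive_injection_order(aliquots: "pd.DataFrame | StudyTable"):
    """Assign a 1-based injection index by ascending datetime.

    Stable: aliquots sharing a timestamp keep their relative input order.
    Accepts either the per-aliquot frame or a whole :class:`StudyTable`;
    returns the same kind with ``injection_index`` (re)assigned.
    """
    if isinstance(aliquots, StudyTable):
        return StudyTable(data=aliquots.data,
                          aliquots=derive_injection_order(aliquots.aliquots),
                          qc_type_for_correction=aliquots.qc_type_for_correction)
    out = aliquots.copy()
    order = out["datetime"].to_numpy().argsort(kind="stable")
    idx = np.empty(len(out), dtype=int)
    idx[order] = np.arange(1, len(out) + 1)
    out["injection_index"] = idx
    return out


def read_input(path: str | Path, config: QCConfig | None = None
               ) -> tuple[StudyTable | None, ValidationReport]:
    """Read and validate a tab-separated peak-area table.

    Returns the validated :class:`StudyTable` (or ``None`` when fatal errors
    were found) together with a :class:`ValidationReport`.
    """
    config = config or QCConfig()
    report = ValidationReport()
    path = Path(path)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      encoding="utf-8")
    raw.columns = [c.strip() for c in raw.columns]

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        report.error(f"required column(s) absent: {', '.join(missing_cols)}")
        return None, report
    if ("compound_is" in raw.columns) != ("area_is" in raw.columns):
        report.error("columns 'compound_is' and 'area_is' must be present together")
        return None, report

    if "batch" not in raw.columns:
        raw = raw.assign(batch="1")
        report.warn("no 'batch' column: all aliquots assigned to batch 1")
    raw["batch"] = raw["batch"].astype(str).str.strip()

    # numeric columns
    raw["area"] = _parse_numeric(raw["area"], "area", report)
    if "area_is" in raw.columns:
        raw["area_is"] = _parse_numeric(raw["area_is"], "area_is", report)
        stripped_is = raw["compound_is"].astype(str).str.strip()
        raw["compound_is"] = stripped_is.where(~stripped_is.isin(_MISSING))
    else:
        raw["compound_is"] = np.nan
        raw["area_is"] = np.nan

    # datetime under the declared format only
    try:
        raw["datetime"] = pd.to_datetime(raw["datetime"].str.strip(),
                                         format=config.datetime_format)
    except ValueError as exc:
        report.error(f"datetime column does not match format "
                     f"'{config.datetime_format}': {exc}")
        return None, report

    for col in ("aliquot", "type", "compound"):
        raw[col] = raw[col].astype(str).str.strip()

    # duplicate observations are ambiguous, not averaged
    dup = raw.duplicated(subset=["aliquot", "compound"], keep=False)
    if dup.any():
        pairs = raw.loc[dup, ["aliquot", "compound"]].drop_duplicates()
        shown = "; ".join(f"({a}, {c})" for a, c in pairs.head(5).itertuples(index=False))
        report.error(f"duplicate (aliquot, compound) rows: {shown}")

    # each aliquot must carry a single type/batch/datetime
    per_aliquot = raw.groupby("aliquot", sort=False)[["type", "batch", "datetime"]].nunique()
    inconsistent = per_aliquot[(per_aliquot > 1).any(axis=1)]
    for aliquot in inconsistent.index[:5]:
        report.error(f"aliquot '{aliquot}' has conflicting type/batch/datetime values")

    unknown = sorted({t for t in raw["type"].unique() if not is_known_type(t)})
    if unknown:
        report.warn(
            f"unknown sample type label(s) {', '.join(unknown)}: treated as "
            "study samples for plotting, excluded from QC/blank computations"
        )

    qc_type = config.correction_qc_type
    present_types = set(raw["type"].unique())
    if qc_type not in present_types:
        fallback = next(iter(QC_TYPES - {qc_type}))
        if fallback in present_types:
            report.warn(f"no {qc_type} samples found: falling back to "
                        f"{fallback} for batch correction")
            qc_type = fallback
        else:
            report.warn("no QC samples (SQC/LQC) found: batch correction and "
                        "RSDqc will be unavailable")

    if not report.ok:
        return None, report

    # per-aliquot facts + injection order
    aliquots = (raw.groupby("aliquot", sort=False)[["type", "batch", "datetime"]]
                .first())
    aliquots = derive_injection_order(aliquots)

    # complete the aliquot x compound grid
    compounds = list(dict.fromkeys(raw["compound"]))
    full = pd.MultiIndex.from_product([aliquots.index, compounds],
                                      names=["aliquot", "compound"])
    n_missing = len(full) - len(raw)
    if n_missing:
        report.warn(f"{n_missing} missing (aliquot, compound) observation(s) "
                    "inserted as NA")
    data = raw.set_index(["aliquot", "compound"]).reindex(full).reset_index()
    # fill per-aliquot columns on inserted rows
    for col in ("type", "batch", "datetime"):
        data[col] = data["aliquot"].map(aliquots[col])
    # fill the IS link on inserted rows from the compound -> IS mapping
    is_map = (raw.dropna(subset=["compound_is"])
              .groupby("compound")["compound_is"].agg(lambda s: s.iloc[0]))
    inserted = data["area"].isna() & data["compound_is"].isna()
    data.loc[inserted, "compound_is"] = data.loc[inserted, "compound"].map(is_map)

    counts = (aliquots.groupby(["batch", "type"], sort=False).size()
              .rename("n").reset_index())
    report.counts = counts

    table = StudyTable(data=data, aliquots=aliquots,
                       qc_type_for_correction=qc_type)
    report.extend(validate_batch_design(table, config))
    return table, report


def write_table(table: StudyTable, path: str | Path) -> None:
    """Write a StudyTable back to the tab-separated input dialect.

    Missing numeric cells become the literal ``NA``; re-reading the file
    yields an identical grid.
    """
    out = table.data.copy()
    out["datetime"] = out["datetime"].dt.strftime("%Y-%m-%d %H:%M:%S")
    cols = [c for c in CORE_COLUMNS if c in out.columns]
    extras = [c for c in out.columns if c not in cols]
    out = out[cols + extras]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def validate_batch_design(table: StudyTable, config: QCConfig | None = None
                          ) -> ValidationReport:
    """Check each batch against the recommended injection design.

    Advisory only — emits warnings, never errors, when a batch has fewer
    correction-QC injections than ``min_qc_per_batch``, more than
    ``max_samples_between_qc`` study samples between consecutive QCs, fewer
    than ``min_blank_injections`` BLANK injections, or no SST at its start.
    """
    config = config or QCConfig()
    report = ValidationReport()
    qc_type = table.qc_type_for_correction
    ordered = table.aliquots.sort_values("injection_index")

    for batch in table.batches:
        sub = ordered[ordered["batch"] == batch]
        types = sub["type"].tolist()

        n_qc = sum(t == qc_type for t in types)
        if n_qc < config.min_qc_per_batch:
            report.warn(f"batch {batch}: only {n_qc} {qc_type} injection(s), "
                        f"recommended minimum is {config.min_qc_per_batch}")

        n_blank = sum(t == "BLANK" for t in types)
        if n_blank < config.min_blank_injections:
            report.warn(f"batch {batch}: only {n_blank} BLANK injection(s), "
                        f"recommended minimum is {config.min_blank_injections}")

        if not types or types[0] != "SST":
            report.warn(f"batch {batch}: does not start with an SST injection")

        # study samples between consecutive QCs
        gap = 0
        seen_qc = False
        worst = 0
        for t in types:
            if t == qc_type:
                if seen_qc:
                    worst = max(worst, gap)
                seen_qc = True
                gap = 0
            elif t == "SAMPLE":
                gap += 1
        if worst > config.max_samples_between_qc:
            report.warn(
                f"batch {batch}: {worst} consecutive study samples between "
                f"{qc_type} injections exceeds the recommended maximum of "
                f"{config.max_samples_between_qc}")

    return report
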