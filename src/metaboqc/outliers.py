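"""Outlier detection with the generalized extreme studentized deviate test.

The generalized ESD (Rosner) procedure extends Grubbs' test to up to
``max_k`` outliers: at step i it computes R_i = max|x - mean| / sd over the
points still in play, removes the most deviant point, and compares R_i with
a critical value lambda_i derived from the Student t distribution. The
declared outliers are the first i* removed points, where i* is the LARGEST
step with R_i > lambda_i — this ordering makes the test resistant to
masking, where one extreme point hides another.

Two applications:

* QC aliquots are replicate injections of the same pool, so their median
  compound/IS ratio should be constant; an aliquot whose median ratio is
  extreme is flagged and automatically excluded from batch-correction
  medians and RSDqc.
* Study samples vary biologically in their compounds but not in their
  internal standards; an aliquot whose median IS area is extreme is likely
  a misinjection. Such samples are flagged but never excluded
  automatically — the analyst decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCConfig
from .io import StudyTable
from .normalization import RatioTable


@dataclass
class OutlierFlags:
    """Per-aliquot outlier verdicts.

    ``frame`` has one row per tested aliquot with columns ``aliquot, type,
    batch, basis, statistic, flagged, auto_excluded``; ``basis`` is
    ``qc_median_ratio`` or ``sample_is_area``. Only QC-basis flags carry
    ``auto_excluded = True``.
    """

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def excluded_aliquots(self) -> set:
        if self.frame.empty:
            return set()
        f = self.frame
        return set(f.loc[f["flagged"] & f["auto_excluded"], "aliquot"])

    @property
    def flagged_aliquots(self) -> set:
        if self.frame.empty:
            return set()
        return set(self.frame.loc[self.frame["flagged"], "aliquot"])


_FLAG_COLUMNS = ["aliquot", "type", "batch", "basis", "statistic",
                 "flagged", "auto_excluded"]


def esd_critical_value(n: int, i: int, alpha: float) -> float:
    """Two-sided critical value lambda_i of the generalized ESD test.

    ``i`` is the 1-based removal step; lambda_i uses the t quantile at
    p = 1 - alpha / (2 (n - i + 1)) with n - i - 1 degrees of freedom.
    """
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    df = n - i - 1
    t = stats.t.ppf(p, df)
    return (n - i) * t / np.sqrt((df + t * t) * (n - i + 1))


def rosner_esd(values, alpha: float = 0.05, max_k: int | None = None,
               min_n: int = 10) -> tuple[set[int], np.ndarray]:
    """Generalized ESD test; returns (outlier positions, per-point statistics).

    Positions index into ``values``. The statistics array holds, for each
    point, the studentized deviation at the step where it was examined:
    removed points carry their R_i, remaining points their deviation from
    the final retained mean/sd. Inputs shorter than ``min_n`` or with zero
    variance yield no outliers. Non-finite values raise ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("rosner_esd requires finite values")
    stat = np.zeros(n)
    if n >= 3:
        sd0 = x.std(ddof=1)
        if sd0 > 0:
            stat = np.abs(x - x.mean()) / sd0
    if n < min_n:
        return set(), stat
    if max_k is None:
        max_k = max(1, n // 5)
    max_k = min(max_k, n - 2)

    remaining = np.arange(n)
    removed: list[int] = []
    exceed_up_to = 0
    for i in range(1, max_k + 1):
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean()) / sd
        j = int(np.argmax(dev))
        r_i = dev[j]
        pos = remaining[j]
        stat[pos] = r_i
        removed.append(pos)
        if r_i > esd_critical_value(n, i, alpha):
            exceed_up_to = i
        remaining = np.delete(remaining, j)

    if remaining.size >= 3:
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd > 0:
            stat[remaining] = np.abs(sub - sub.mean()) / sd
    return set(removed[:exceed_up_to]), stat


def _run_flagging(table: StudyTable, medians: pd.Series, basis: str,
                  auto_exclude: bool, config: QCConfig,
                  warnings: list[str]) -> pd.DataFrame:
    """Run the ESD test on per-aliquot medians, pooled or per batch."""
    medians = medians.dropna()
    rows: list[pd.DataFrame] = []
    if config.pool_esd_across_batches:
        groups = [(None, medians)]
    else:
        batch = table.aliquots.loc[medians.index, "batch"]
        groups = [(b, medians[batch == b]) for b in table.batches]
    for label, vals in groups:
        if len(vals) == 0:
            continue
        if len(vals) < config.min_n_for_esd:
            where = "pooled" if label is None else f"batch {label}"
            warnings.append(
                f"{basis}: only {len(vals)} aliquot(s) ({where}), fewer than "
                f"min_n_for_esd={config.min_n_for_esd}; no outlier test run")
            flagged_pos: set[int] = set()
            stat = np.zeros(len(vals))
        else:
            flagged_pos, stat = rosner_esd(
                vals.to_numpy(), alpha=config.esd_alpha,
                max_k=config.esd_max_k(len(vals)),
                min_n=config.min_n_for_esd)
        flagged = np.zeros(len(vals), dtype=bool)
        flagged[list(flagged_pos)] = True
        rows.append(pd.DataFrame({
            "aliquot": vals.index,
            "type": table.aliquots.loc[vals.index, "type"].to_numpy(),
            "batch": table.aliquots.loc[vals.index, "batch"].to_numpy(),
            "basis": basis,
            "statistic": stat,
            "flagged": flagged,
            "auto_excluded": flagged & auto_exclude,
        }))
    if not rows:
        return pd.DataFrame(columns=_FLAG_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def flag_qc_outliers(table: StudyTable, ratios: RatioTable,
                     config: QCConfig | None = None) -> OutlierFlags:
    """Flag correction-QC aliquots whose median compound/IS ratio is extreme.

    The median is taken across compounds per QC aliquot (missing ratios
    skipped); the ESD test runs on these medians pooled over batches (or per
    batch via config). Flagged QCs are auto-excluded from batch-correction
    medians and RSDqc.
    """
    config = config or QCConfig()
    warnings: list[str] = []
    qc = table.qc_aliquots
    medians = (ratios.frame[ratios.frame["aliquot"].isin(qc)]
               .groupby("aliquot", sort=False)["ratio"].median()
               .reindex(qc))
    frame = _run_flagging(table, medians, "qc_median_ratio", True, config,
                          warnings)
    return OutlierFlags(frame=frame, warnings=warnings)


def flag_sample_outliers(table: StudyTable, config: QCConfig | None = None
                         ) -> OutlierFlags:
    """Flag study samples whose median IS area suggests a misinjection.

    The median is taken across internal standards per SAMPLE aliquot.
    Flagged samples are reported but stay in every computation until the
    analyst excludes them.
    """
    config = config or QCConfig()
    warnings: list[str] = []
    is_mat = table.is_area_matrix()
    samples = table.sample_aliquots
    if is_mat.shape[1] == 0:
        warnings.append("no internal standards in the data: study-sample "
                        "misinjection test skipped")
        return OutlierFlags(frame=pd.DataFrame(columns=_FLAG_COLUMNS),
                            warnings=warnings)
    medians = is_mat.reindex(samples).median(axis=1)
    frame = _run_flagging(table, medians, "sample_is_area", False, config,
                          warnings)
    return OutlierFlags(frame=frame, warnings=warnings)


def combine_flags(*flag_sets: OutlierFlags) -> OutlierFlags:
    """Concatenate flag tables from several tests into one."""
    frames = [f.frame for f in flag_sets if not f.frame.empty]
    warnings = [w for f in flag_sets for w in f.warnings]
    if not frames:
        return OutlierFlags(frame=pd.DataFrame(columns=_FLAG_COLUMNS),
                            warnings=warnings)
    return OutlierFlags(frame=pd.concat(frames, ignore_index=True),
                        warnings=warnings)
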