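"""Internal-standard ratio normalization and IS suggestions.

Each compound area is divided by the peak area of its assigned
stable-isotope-labeled internal standard (IS) measured in the same
injection::

    ratio = area_compound / area_IS

Because compound and IS co-experience injection and ionisation variation,
the ratio cancels a large part of the technical noise. When a compound has
no IS assigned, the IS area is taken as 1, so the ratio equals the raw area.
A zero IS area leaves the ratio undefined (missing) rather than infinite.

The module can also rank alternative ISs for every compound: each candidate
is evaluated by recomputing ratios against it, applying between-batch
correction, and measuring the RSDqc that results — the candidate giving the
lowest post-correction RSDqc ranks first. Suggestions are advisory; the
assigned IS stays in force unless the user reassigns it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCConfig
from .io import StudyTable

#: Sentinel recorded in ``is_used`` when no IS is assigned (IS area = 1).
NO_IS = "none"


@dataclass
class RatioTable:
    """Per-(aliquot, compound) area ratios.

    ``frame`` has columns ``aliquot, compound, ratio, is_used``; ``ratio``
    is missing exactly when the compound area is missing or the IS area is
    zero or missing. ``warnings`` lists zero-IS cells encountered.
    """

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def matrix(self) -> pd.DataFrame:
        """Aliquot x compound matrix of ratios."""
        return self.frame.pivot(index="aliquot", columns="compound",
                                values="ratio")


@dataclass
class ISSuggestion:
    """Candidate internal standards for one compound, best first.

    ``ranked_is`` is a list of (IS name, post-correction RSDqc %) sorted
    ascending by RSDqc, ties broken alphabetically by IS name.
    """

    compound: str
    ranked_is: list[tuple[str, float]]


def compute_ratios(table: StudyTable) -> RatioTable:
    """Compute compound/IS area ratios for every (aliquot, compound).

    Rows without an IS measurement — no IS assigned, or an aliquot where
    the IS was not spiked (blanks) — keep ``ratio = area`` (IS area
    defaults to 1) and record ``is_used = "none"``. Missing areas give
    missing ratios; IS areas of exactly zero give missing ratios plus a
    warning.
    """
    d = table.data
    has_is = d["compound_is"].notna() & d["area_is"].notna()
    zero_is = has_is & (d["area_is"] == 0)

    ratio = np.where(has_is, d["area"] / d["area_is"].where(d["area_is"] != 0),
                     d["area"])
    frame = pd.DataFrame({
        "aliquot": d["aliquot"],
        "compound": d["compound"],
        "ratio": ratio,
        "is_used": d["compound_is"].where(has_is).fillna(NO_IS),
    })
    warnings = [
        f"IS area is zero for aliquot '{a}', compound '{c}': ratio set to NA"
        for a, c in d.loc[zero_is, ["aliquot", "compound"]].itertuples(index=False)
    ]
    return RatioTable(frame=frame, warnings=warnings)


def _qc_rsd_for_candidate(areas: pd.Series, is_areas: pd.Series,
                          batches: pd.Series, config: QCConfig) -> float:
    """Post-correction RSDqc (%) of one compound against one candidate IS.

    Operates on QC-sample vectors only: ratios are formed, between-batch
    median factors applied, then RSD = sd/mean x 100 over the pooled
    corrected ratios. Returns NaN when fewer than two usable ratios exist.
    """
    ratio = areas / is_areas.where(is_areas != 0)
    ok = ratio.notna()
    ratio, b = ratio[ok], batches[ok]
    if len(ratio) < 2:
        return float("nan")
    batch_medians = ratio.groupby(b).median()
    if (batch_medians <= 0).any():
        return float("nan")
    if len(batch_medians) > 1:
        grand = (ratio.median() if config.pooled_grand_median
                 else batch_medians.median())
        corrected = ratio * (grand / batch_medians).reindex(b).to_numpy()
    else:
        corrected = ratio
    mean = corrected.mean()
    if mean == 0:
        return float("nan")
    return float(corrected.std(ddof=1) / mean * 100.0)


def suggest_internal_standards(table: StudyTable, config: QCConfig | None = None
                               ) -> list[ISSuggestion]:
    """Rank every measured IS as a normalizer for every compound.

    For each (compound, candidate IS) pair the QC-sample ratios are
    recomputed, between-batch correction applied, and the resulting RSDqc
    used as the ranking criterion (ascending; alphabetical tie-break).
    Candidates must be measured in at least ``config.is_min_qc_presence`` of
    the QC samples. Compounds absent from every QC yield no suggestion.
    """
    config = config or QCConfig()
    qc = table.qc_aliquots
    if len(qc) < 2:
        return []
    is_mat = table.is_area_matrix().reindex(qc)
    if is_mat.shape[1] == 0:
        return []
    presence = is_mat.notna().mean()
    candidates = sorted(presence.index[presence >= config.is_min_qc_presence])
    if not candidates:
        return []

    area_mat = (table.data.pivot(index="aliquot", columns="compound",
                                 values="area").reindex(qc))
    batches = table.aliquots.loc[qc, "batch"]

    suggestions = []
    for compound in sorted(area_mat.columns):
        areas = area_mat[compound]
        if areas.notna().sum() == 0:
            continue
        scored = []
        for cand in candidates:
            rsd = _qc_rsd_for_candidate(areas, is_mat[cand], batches, config)
            if np.isfinite(rsd):
                scored.append((cand, rsd))
        if scored:
            scored.sort(key=lambda t: (t[1], t[0]))
            suggestions.append(ISSuggestion(compound=compound, ranked_is=scored))
    return suggestions


def suggestions_to_frame(suggestions: list[ISSuggestion]) -> pd.DataFrame:
    """Flatten suggestions to a table: compound, rank, is_name, rsdqc_percent."""
    rows = [
        {"compound": s.compound, "rank": i + 1, "is_name": name,
         "rsdqc_percent": rsd}
        for s in suggestions
        for i, (name, rsd) in enumerate(s.ranked_is)
    ]
    return pd.DataFrame(rows, columns=["compound", "rank", "is_name",
                                       "rsdqc_percent"])
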