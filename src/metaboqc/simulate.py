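"""Synthetic targeted LC-MS studies with known ground truth.

The generator emits a peak-area table in the exact input dialect of
:mod:`metaboqc.io` — long format, tab separated, one row per
(aliquot, compound) — following the recommended batch design: each batch
opens with a system suitability test (SST) and a water blank, then a
procedure blank (PROC), an optional calibration ramp, and alternating
blocks of correction QCs and study samples, closing with a QC and a blank.

The signal model is multiplicative, as is standard for MS peak areas:

* every compound has a lognormal baseline area (around 1e5 counts);
* a per-batch, compound-level multiplicative factor ``g_b`` plants the
  between-batch effect (compound-specific sensitivity shifts; internal
  standards are spiked at constant amount and do not carry ``g_b``, so the
  effect survives IS normalization — which is why batch correction exists);
* an optional linear within-batch drift ``1 + slope * position`` on
  compound areas;
* lognormal noise with overall coefficient of variation ``noise_cv``, a
  configurable fraction of whose log-variance is shared between a
  compound and the internal standards of the same injection (injection
  volume and ionisation variation affect both, which is what makes the
  area ratio more precise than the raw area);
* study samples additionally get lognormal biological variation;
* blanks carry ``blank_fraction`` of the study-median signal and no IS.

Ground truth (batch factors, drift slopes, planted outlier aliquots,
baselines) is returned alongside and can be written as a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QCConfig
from .io import StudyTable, read_input


@dataclass
class SimSpec:
    """Parameters of a synthetic study.

    ``batch_factors`` and ``drift_slopes`` take one value per batch; when
    ``None``, batch factors are drawn lognormally (log-sd 0.2, a typical
    batch-to-batch spread) and drift slopes are zero. ``is_shared_noise``
    is the fraction of area log-variance shared between compound and IS in
    the same injection (stable-isotope-labeled ISs track their analytes
    closely, hence the high default). ``planted_outliers`` lists
    (kind, magnitude) pairs with kind ``"qc"`` (one QC's compound areas
    scaled — a sample-handling fault) or ``"sample_is"`` (one study
    sample's compound and IS areas scaled — a misinjection).
    """

    n_batches: int = 3
    samples_per_batch: int = 30
    qcs_per_batch: int = 4
    blanks_per_batch: int = 2
    procs_per_batch: int = 1
    n_compounds: int = 5
    n_is: int = 2
    cal_levels: int = 0
    batch_factors: tuple[float, ...] | None = None
    drift_slopes: tuple[float, ...] | None = None
    noise_cv: float = 0.05
    is_shared_noise: float = 0.95
    bio_log_sd: float = 0.4
    blank_fraction: float = 0.05
    planted_outliers: list[tuple[str, float]] = field(default_factory=list)
    qc_type: str = "SQC"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_batches", "samples_per_batch", "qcs_per_batch",
                     "blanks_per_batch", "n_compounds", "n_is"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.is_shared_noise <= 1:
            raise ValueError("is_shared_noise must be in [0, 1]")
        if self.qcs_per_batch < 2 and self.samples_per_batch > 0:
            raise ValueError("need at least 2 QCs per batch to bracket the "
                             "study samples")
        if self.batch_factors is not None and len(self.batch_factors) != self.n_batches:
            raise ValueError("batch_factors must have one entry per batch")
        if self.drift_slopes is not None and len(self.drift_slopes) != self.n_batches:
            raise ValueError("drift_slopes must have one entry per batch")


def _batch_layout(spec: SimSpec, batch: int) -> list[tuple[str, str]]:
    """Ordered (aliquot id, type) pairs for one batch."""
    b = batch + 1
    seq: list[tuple[str, str]] = [(f"B{b}_SST", "SST")]
    n_lead_blanks = max(0, spec.blanks_per_batch - 1)
    for i in range(n_lead_blanks):
        seq.append((f"B{b}_BLANK{i + 1}", "BLANK"))
    for i in range(spec.procs_per_batch):
        seq.append((f"B{b}_PROC{i + 1}", "PROC"))
    for k in range(1, spec.cal_levels + 1):
        seq.append((f"B{b}_CAL{k}", f"CAL{k}"))

    # QC-bracketed sample blocks: q QCs enclosing q-1 even sample chunks
    q = spec.qcs_per_batch
    chunks = np.array_split(np.arange(spec.samples_per_batch), q - 1)
    sample_no = 0
    for i in range(q):
        seq.append((f"B{b}_{spec.qc_type}{i + 1}", spec.qc_type))
        if i < q - 1:
            for _ in chunks[i]:
                sample_no += 1
                seq.append((f"B{b}_S{sample_no:03d}", "SAMPLE"))
    seq.append((f"B{b}_BLANK{n_lead_blanks + 1}", "BLANK"))
    return seq


def generate_study(spec: SimSpec, path: str | Path | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic study table and its ground truth.

    Returns the long-format table (input dialect) and a ground-truth dict.
    When ``path`` is given the table is written there as TSV and the
    ground truth as a ``<path>.truth.json`` sidecar. Identical specs
    (including seed) produce byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    compounds = [f"compound_{i + 1:02d}" for i in range(spec.n_compounds)]
    standards = [f"IS_{i + 1:02d}" for i in range(spec.n_is)]
    is_of = {c: standards[i % spec.n_is] for i, c in enumerate(compounds)}

    base_c = np.exp(rng.normal(np.log(1e5), 0.8, spec.n_compounds))
    base_is = np.exp(rng.normal(np.log(1e5), 0.3, spec.n_is))
    if spec.batch_factors is None:
        g = np.exp(rng.normal(0.0, 0.2, spec.n_batches))
    else:
        g = np.asarray(spec.batch_factors, dtype=float)
    slopes = (np.zeros(spec.n_batches) if spec.drift_slopes is None
              else np.asarray(spec.drift_slopes, dtype=float))

    sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))
    sd_shared = sigma * np.sqrt(spec.is_shared_noise)
    sd_indep = sigma * np.sqrt(1.0 - spec.is_shared_noise)

    rows: list[dict] = []
    truth = {"batch_factors": g.tolist(), "drift_slopes": slopes.tolist(),
             "baselines": dict(zip(compounds, base_c.tolist())),
             "is_baselines": dict(zip(standards, base_is.tolist())),
             "is_of": is_of, "outliers": []}

    t0 = datetime(2024, 1, 1, 8, 0, 0)
    injection = 0
    qc_aliquots: list[str] = []
    sample_aliquots: list[str] = []

    for b in range(spec.n_batches):
        layout = _batch_layout(spec, b)
        drift0 = 1.0  # trend normalised to 1 at batch start
        for pos, (aliquot, stype) in enumerate(layout):
            ts = t0 + timedelta(days=b, minutes=5 * injection)
            injection += 1
            drift = drift0 + slopes[b] * pos
            shared = rng.normal(0.0, sd_shared) if sd_shared > 0 else 0.0
            is_noise = rng.normal(0.0, sd_indep, spec.n_is) if sd_indep > 0 else np.zeros(spec.n_is)
            c_noise = rng.normal(0.0, sd_indep, spec.n_compounds) if sd_indep > 0 else np.zeros(spec.n_compounds)
            bio = (rng.normal(0.0, spec.bio_log_sd, spec.n_compounds)
                   if stype == "SAMPLE" and spec.bio_log_sd > 0
                   else np.zeros(spec.n_compounds))

            has_is = stype != "BLANK"
            is_areas = base_is * np.exp(shared + is_noise)

            if stype in ("BLANK", "PROC"):
                areas = spec.blank_fraction * base_c * np.exp(shared + c_noise)
            elif stype.startswith("CAL") or stype.startswith("ACAL"):
                level = int("".join(ch for ch in stype if ch.isdigit()) or 1)
                scale = level / max(1, spec.cal_levels)
                areas = scale * base_c * g[b] * np.exp(shared + c_noise)
            else:  # SST, QC, SAMPLE
                areas = base_c * g[b] * drift * np.exp(shared + c_noise + bio)

            if stype == spec.qc_type:
                qc_aliquots.append(aliquot)
            if stype == "SAMPLE":
                sample_aliquots.append(aliquot)

            for ci, compound in enumerate(compounds):
                row = {
                    "aliquot": aliquot, "type": stype, "batch": str(b + 1),
                    "compound": compound, "area": areas[ci],
                    "compound_is": is_of[compound] if has_is else "NA",
                    "area_is": (is_areas[standards.index(is_of[compound])]
                                if has_is else "NA"),
                    "datetime": ts.strftime("%Y-%m-%d %H:%M:%S"),
                }
                rows.append(row)

    df = pd.DataFrame(rows)

    # plant outliers on deterministic mid-run aliquots
    for kind, magnitude in spec.planted_outliers:
        if kind == "qc":
            target = qc_aliquots[len(qc_aliquots) // 2]
            mask = df["aliquot"] == target
            df.loc[mask, "area"] = df.loc[mask, "area"].astype(float) * magnitude
        elif kind == "sample_is":
            target = sample_aliquots[len(sample_aliquots) // 2]
            mask = df["aliquot"] == target
            df.loc[mask, "area"] = df.loc[mask, "area"].astype(float) * magnitude
            with_is = mask & (df["area_is"] != "NA")
            df.loc[with_is, "area_is"] = (
                df.loc[with_is, "area_is"].astype(float) * magnitude)
        else:
            raise ValueError(f"unknown planted outlier kind: {kind!r}")
        truth["outliers"].append({"kind": kind, "aliquot": target,
                                  "magnitude": magnitude})

    for col in ("area", "area_is"):
        df[col] = df[col].map(lambda v: v if isinstance(v, str)
                              else format(float(v), ".6f"))

    if path is not None:
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return df, truth


def generate_study_table(spec: SimSpec, config: QCConfig | None = None,
                         tmpdir: str | Path | None = None) -> tuple[StudyTable, dict]:
    """Generate a study and immediately read it back as a StudyTable.

    Round-trips through the on-disk dialect so the generated data exercise
    the same parsing path as user data.
    """
    import tempfile

    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        path = Path(d) / "study.tsv"
        _, truth = generate_study(spec, path)
        table, report = read_input(path, config or QCConfig())
    if table is None:
        raise RuntimeError(f"generated study failed validation: {report.errors}")
    return table, truth
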