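"""Plot frames, rendered figures and the three-tab report workbook.

Every figure is computed first as a tidy :class:`PlotFrame` (pure data:
rows of x, y, group, ...) and only then rendered with matplotlib, so plots
are reproducible functions of exported data and testable without touching a
rendering backend.

Available views:

* **aliquot plot** — per-injection box-whisker summaries of compound areas,
  IS areas and ratios, in injection order, to spot drifting or failed
  injections at a glance;
* **PCA plot** — scores of study samples and QCs on the first two principal
  components of the log-transformed, autoscaled ratio matrix, with 95%
  confidence ellipses per group; tight QC clustering inside the study cloud
  indicates representative QCs and successful correction;
* **QC violin plot** — the per-QC-aliquot distribution of log2 ratios
  before/after correction; aligned violins across batches mean the batch
  effect is gone;
* **compound plot** — any per-compound quantity (area, IS area, ratio,
  corrected ratio, or an extra column such as retention time) against
  injection index, coloured by sample type.

The report workbook has exactly three tabs — "High confidence", "With
Caution", "Low Signal to Noise" — each holding a metrics header block and a
wide aliquot x compound matrix of corrected ratios for the compounds in
that tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCConfig
from .correction import CorrectedTable, CorrectionModel
from .io import StudyTable, ValidationReport
from .metrics import CompoundMetrics, TAB_NAMES, Tier
from .normalization import RatioTable

QUANTITIES = ("area", "area_is", "ratio", "corrected_ratio")


@dataclass
class PlotFrame:
    """Tidy, render-ready data for one plot."""

    plot_kind: str
    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _box_stats(values: pd.Series) -> dict | None:
    """Tukey box-whisker summary: linear-interpolation quartiles,
    whiskers at the most extreme points within 1.5 x IQR, rest outliers."""
    v = values.dropna().to_numpy()
    if v.size == 0:
        return None
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {"median": med, "q1": q1, "q3": q3,
            "whisker_lo": inside.min(), "whisker_hi": inside.max(),
            "outliers": outliers.tolist()}


def aliquot_plot_frame(table: StudyTable, ratios: RatioTable,
                       corrected: CorrectedTable | None = None) -> PlotFrame:
    """Box-whisker summaries per aliquot of areas, IS areas and ratios.

    One record per (aliquot, panel) with panel in {area, area_is, ratio};
    x is the injection index, groups are sample types. Aliquots with no
    finite values in a panel are omitted and listed in the metadata.
    """
    d = table.data.merge(ratios.frame[["aliquot", "compound", "ratio"]],
                         on=["aliquot", "compound"])
    records = []
    omitted = []
    for aliquot, sub in d.groupby("aliquot", sort=False):
        info = table.aliquots.loc[aliquot]
        for panel in ("area", "area_is", "ratio"):
            st = _box_stats(sub[panel])
            if st is None:
                omitted.append((aliquot, panel))
                continue
            records.append({"x": info["injection_index"], "panel": panel,
                            "aliquot": aliquot, "sample_type": info["type"],
                            "batch": info["batch"], **st})
    frame = pd.DataFrame(records).sort_values(["panel", "x"]).reset_index(drop=True)
    return PlotFrame("aliquot", frame,
                     {"x_label": "injection order", "omitted": omitted})


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> dict:
    """Mean, covariance and chi-square scaling of a 2-D confidence ellipse."""
    mean = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    return {"mean": mean, "cov": cov,
            "chi2_scale": float(stats.chi2.ppf(level, df=2))}


def point_in_ellipse(point: np.ndarray, ellipse: dict) -> bool:
    """Whether a point lies inside a confidence ellipse (Mahalanobis test)."""
    diff = np.asarray(point) - ellipse["mean"]
    inv = np.linalg.inv(ellipse["cov"])
    return float(diff @ inv @ diff) <= ellipse["chi2_scale"]


def pca_frame(values: CorrectedTable | RatioTable, table: StudyTable,
              batches: list | None = None) -> PlotFrame:
    """PC1/PC2 scores of study samples and correction QCs.

    The aliquot x compound matrix is log2-transformed (offset: half the
    smallest positive value per compound), median-imputed, autoscaled per
    compound, and decomposed with PCA. Constant compounds are dropped with
    a note. Component signs are fixed so the loading of the alphabetically
    first retained compound is non-negative. Metadata carries 95%
    confidence ellipses per sample type.
    """
    from sklearn.decomposition import PCA

    mat = values.matrix()
    keep = table.aliquots_of_type("SAMPLE", table.qc_type_for_correction)
    if batches is not None:
        in_scope = table.aliquots["batch"].isin([str(b) for b in batches])
        keep = keep.intersection(table.aliquots.index[in_scope])
    mat = mat.reindex(keep).sort_index()

    dropped = []
    cols = []
    X = []
    for compound in sorted(mat.columns):
        col = mat[compound].astype(float)
        pos = col[col > 0]
        eps = (pos.min() / 2.0) if len(pos) else 1.0
        logged = np.log2(col.clip(lower=0) + eps)
        logged = logged.fillna(logged.median())
        if logged.std(ddof=0) == 0 or logged.isna().any():
            dropped.append(compound)
            continue
        cols.append(compound)
        X.append((logged - logged.mean()) / logged.std(ddof=0))
    if len(cols) < 2 or mat.shape[0] < 3:
        raise ValueError("PCA needs at least 3 aliquots and 2 varying compounds")
    X = np.column_stack(X)

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(2):
        if pca.components_[k, 0] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1

    records = pd.DataFrame({
        "aliquot": mat.index,
        "x": scores[:, 0], "y": scores[:, 1],
        "sample_type": table.aliquots.loc[mat.index, "type"].to_numpy(),
        "batch": table.aliquots.loc[mat.index, "batch"].to_numpy(),
    })
    ellipses = {}
    for stype, sub in records.groupby("sample_type"):
        if len(sub) >= 3:
            ellipses[stype] = confidence_ellipse(sub[["x", "y"]].to_numpy())
    meta = {"explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
            "dropped_compounds": dropped, "ellipses": ellipses,
            "x_label": "PC1", "y_label": "PC2"}
    return PlotFrame("pca", records, meta)


def violin_frame(values: CorrectedTable | RatioTable, table: StudyTable,
                 flags=None, batches: list | None = None) -> PlotFrame:
    """Per-QC-aliquot distributions of log2 ratios (one violin per QC).

    Auto-excluded QC aliquots are omitted. One record per (QC aliquot,
    compound) with the log2-transformed value; zero/negative values are
    dropped (logged in metadata).
    """
    qc = table.qc_aliquots
    if flags is not None:
        qc = qc.difference(pd.Index(flags.excluded_aliquots))
    if batches is not None:
        in_scope = table.aliquots["batch"].isin([str(b) for b in batches])
        qc = qc.intersection(table.aliquots.index[in_scope])
    f = values.frame
    value_col = "corrected_ratio" if "corrected_ratio" in f.columns else "ratio"
    sub = f[f["aliquot"].isin(qc)].dropna(subset=[value_col])
    nonpos = int((sub[value_col] <= 0).sum())
    sub = sub[sub[value_col] > 0]
    records = pd.DataFrame({
        "aliquot": sub["aliquot"],
        "compound": sub["compound"],
        "y": np.log2(sub[value_col]),
        "batch": sub["aliquot"].map(table.aliquots["batch"]),
        "x": sub["aliquot"].map(table.aliquots["injection_index"]),
    }).sort_values(["x"]).reset_index(drop=True)
    return PlotFrame("violin", records,
                     {"y_label": f"log2 {value_col}", "dropped_nonpositive": nonpos})


def compound_frame(compound: str, table: StudyTable,
                   ratios: RatioTable | None = None,
                   corrected: CorrectedTable | None = None,
                   quantity: str = "corrected_ratio") -> PlotFrame:
    """One compound's chosen quantity against injection index.

    ``quantity`` is one of area, area_is, ratio, corrected_ratio, or the
    name of an extra input column (e.g. retention time). Ratio-like
    quantities are log2-transformed; missing values simply produce no
    point.
    """
    d = table.data[table.data["compound"] == compound]
    if d.empty:
        raise ValueError(f"unknown compound: {compound!r}")
    if quantity in ("area", "area_is"):
        vals = d.set_index("aliquot")[quantity]
    elif quantity == "ratio":
        if ratios is None:
            raise ValueError("ratio quantity requires a RatioTable")
        f = ratios.frame
        vals = f[f["compound"] == compound].set_index("aliquot")["ratio"]
    elif quantity == "corrected_ratio":
        if corrected is None:
            raise ValueError("corrected_ratio quantity requires a CorrectedTable")
        f = corrected.frame
        vals = f[f["compound"] == compound].set_index("aliquot")["corrected_ratio"]
    elif quantity in d.columns:
        vals = pd.to_numeric(d.set_index("aliquot")[quantity], errors="coerce")
    else:
        raise ValueError(f"unknown quantity: {quantity!r}")

    log_transform = quantity in ("ratio", "corrected_ratio")
    vals = vals.dropna()
    if log_transform:
        vals = vals[vals > 0]
        y = np.log2(vals)
        y_label = f"log2 {quantity}"
    else:
        y = vals
        y_label = quantity
    records = pd.DataFrame({
        "aliquot": y.index,
        "x": table.aliquots.loc[y.index, "injection_index"].to_numpy(),
        "y": y.to_numpy(),
        "sample_type": table.aliquots.loc[y.index, "type"].to_numpy(),
        "batch": table.aliquots.loc[y.index, "batch"].to_numpy(),
    }).sort_values("x").reset_index(drop=True)
    return PlotFrame("compound", records,
                     {"compound": compound, "quantity": quantity,
                      "x_label": "injection order", "y_label": y_label,
                      "log2": log_transform})


# ---------------------------------------------------------------- rendering

def render_plot(frame: PlotFrame, path: str | Path) -> None:
    """Render a PlotFrame to an image file with matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(8, 4.5))
    r = frame.records
    if frame.plot_kind == "aliquot":
        for panel, sub in r.groupby("panel"):
            ax.errorbar(sub["x"], sub["median"],
                        yerr=[sub["median"] - sub["q1"], sub["q3"] - sub["median"]],
                        fmt="o", ms=3, label=panel, alpha=0.7)
        ax.set_yscale("log")
        ax.legend()
    elif frame.plot_kind == "pca":
        for stype, sub in r.groupby("sample_type"):
            ax.scatter(sub["x"], sub["y"], s=14, label=stype)
        for stype, ell in frame.metadata.get("ellipses", {}).items():
            vals, vecs = np.linalg.eigh(ell["cov"])
            angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
            width, height = 2 * np.sqrt(vals[::-1] * ell["chi2_scale"])
            ax.add_patch(Ellipse(ell["mean"], width, height, angle=angle,
                                 fill=False, ls="--"))
        ax.legend()
    elif frame.plot_kind == "violin":
        groups = [sub["y"].to_numpy() for _, sub in r.groupby("x")]
        positions = sorted(r["x"].unique())
        if groups:
            ax.violinplot(groups, positions=positions, widths=0.8)
    else:  # compound / generic scatter
        for stype, sub in r.groupby("sample_type"):
            ax.scatter(sub["x"], sub["y"], s=14, label=stype)
        ax.legend()
    ax.set_xlabel(frame.metadata.get("x_label", ""))
    ax.set_ylabel(frame.metadata.get("y_label", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ------------------------------------------------------------------ export

def long_export(table: StudyTable, ratios: RatioTable,
                corrected: CorrectedTable, metrics: CompoundMetrics,
                flags=None) -> pd.DataFrame:
    """Tidy long table: one row per (aliquot, compound) with everything
    downstream statistics needs."""
    d = table.data[["aliquot", "type", "batch", "compound", "area",
                    "compound_is", "area_is", "datetime"]].copy()
    d["injection_index"] = d["aliquot"].map(table.aliquots["injection_index"])
    d = d.merge(ratios.frame[["aliquot", "compound", "ratio", "is_used"]],
                on=["aliquot", "compound"])
    d = d.merge(corrected.frame[["aliquot", "compound", "corrected_ratio",
                                 "correction_applied"]],
                on=["aliquot", "compound"])
    d["tier"] = d["compound"].map(metrics.frame["tier"])
    flagged, excluded = set(), set()
    if flags is not None:
        flagged = flags.flagged_aliquots
        excluded = flags.excluded_aliquots
    d["outlier_flagged"] = d["aliquot"].isin(flagged)
    d["auto_excluded"] = d["aliquot"].isin(excluded)
    return d.sort_values(["injection_index", "compound"]).reset_index(drop=True)


def export_report(table: StudyTable, ratios: RatioTable,
                  corrected: CorrectedTable, metrics: CompoundMetrics,
                  flags=None, model: CorrectionModel | None = None,
                  report: ValidationReport | None = None,
                  config: QCConfig | None = None,
                  outdir: str | Path = ".", plots: bool = True) -> Path:
    """Write the full result set to ``outdir``.

    Produces ``report.xlsx`` (three tabs by confidence tier, each with a
    metrics header and a wide aliquot x compound corrected-ratio matrix),
    ``long_table.tsv``, ``compound_metrics.tsv``, ``outlier_flags.tsv``,
    ``correction_model.tsv``, ``validation_log.txt`` and one image per
    plot kind. Returns the workbook path.
    """
    config = config or QCConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    long_df = long_export(table, ratios, corrected, metrics, flags)
    long_df.to_csv(outdir / "long_table.tsv", sep="\t", index=False,
                   na_rep="NA", date_format="%Y-%m-%d %H:%M:%S")
    metrics.frame.to_csv(outdir / "compound_metrics.tsv", sep="\t",
                         na_rep="NA")
    if flags is not None and not flags.frame.empty:
        flags.frame.to_csv(outdir / "outlier_flags.tsv", sep="\t", index=False)
    if model is not None:
        model.to_frame().to_csv(outdir / "correction_model.tsv", sep="\t",
                                index=False, na_rep="NA")
    log_lines = []
    if report is not None:
        log_lines.append(report.to_text())
    for obj in (ratios, corrected, metrics):
        log_lines.extend(getattr(obj, "warnings", []))
    (outdir / "validation_log.txt").write_text(
        "\n".join(line for line in log_lines if line))

    # workbook
    wide = corrected.matrix()
    wb_path = outdir / "report.xlsx"
    with pd.ExcelWriter(wb_path, engine="openpyxl") as writer:
        for tier, tab in TAB_NAMES.items():
            cols = metrics.frame.index[metrics.frame["tier"] == tier.value]
            header = metrics.frame.loc[cols, ["is_used", "rsdqc_pre",
                                              "rsdqc_post", "background",
                                              "qc_detection"]].T
            block = pd.concat([header, wide.reindex(columns=cols)])
            block.index.name = "aliquot"
            block.to_excel(writer, sheet_name=tab)

    if plots:
        render_plot(aliquot_plot_frame(table, ratios, corrected),
                    outdir / "aliquot_plot.png")
        try:
            render_plot(pca_frame(corrected, table), outdir / "pca_plot.png")
        except ValueError:
            pass
        render_plot(violin_frame(corrected, table, flags),
                    outdir / "violin_plot.png")
        reported = metrics.frame.index[metrics.frame["tier"] != Tier.NOT_REPORTED.value]
        for compound in list(reported)[:10]:
            frame = compound_frame(compound, table, ratios, corrected,
                                   "corrected_ratio")
            render_plot(frame, outdir / f"compound_{compound}.png")
    return wb_path
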