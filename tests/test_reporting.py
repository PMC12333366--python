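"""Plot frames, PCA behaviour, workbook and long-table export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaboqc import QCConfig, Tier, compute_ratios, run_pipeline
from metaboqc.reporting import (aliquot_plot_frame, compound_frame,
                                confidence_ellipse, export_report,
                                long_export, pca_frame, point_in_ellipse,
                                violin_frame, _box_stats)
from metaboqc.simulate import SimSpec, generate_study_table

from conftest import study_rows, timestamp


class TestBoxStats:
    def test_hand_checked_quartiles_and_outlier(self):
        st = _box_stats(pd.Series([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert st["median"] == 3.0 and st["q1"] == 2.0 and st["q3"] == 4.0
        assert st["outliers"] == [100.0]
        assert st["whisker_lo"] == 1.0 and st["whisker_hi"] == 4.0

    def test_empty_series_is_none(self):
        assert _box_stats(pd.Series([np.nan])) is None


class TestAliquotFrame:
    def test_blank_ratio_panel_equals_area_panel(self, read):
        rows = [f"BL1\tBLANK\t1\tcmp{i}\t{10 * (i + 1)}\tNA\tNA\t{timestamp(0)}"
                for i in range(4)]
        rows += [f"Q1\tSQC\t1\tcmp{i}\t{20 * (i + 1)}\tIS1\t2\t{timestamp(1)}"
                 for i in range(4)]
        table, _ = read(rows)
        frame = aliquot_plot_frame(table, compute_ratios(table)).records
        blank = frame[frame["aliquot"] == "BL1"].set_index("panel")
        assert blank.loc["ratio", "median"] == blank.loc["area", "median"]
        # the QC with IS area 2 has ratio = area / 2
        qc = frame[frame["aliquot"] == "Q1"].set_index("panel")
        assert qc.loc["ratio", "median"] == pytest.approx(qc.loc["area", "median"] / 2)

    def test_all_missing_aliquot_listed_in_metadata(self, read):
        rows = [f"A1\tSQC\t1\tcmpA\tNA\tNA\tNA\t{timestamp(0)}",
                f"A2\tSQC\t1\tcmpA\t5\tIS1\t1\t{timestamp(1)}"]
        table, _ = read(rows)
        frame = aliquot_plot_frame(table, compute_ratios(table))
        assert ("A1", "area") in frame.metadata["omitted"]
        assert "A1" not in set(frame.records["aliquot"])


@pytest.fixture(scope="module")
def shifted_study():
    """Two batches with a strong planted shift; correction removes it."""
    spec = SimSpec(n_batches=2, samples_per_batch=20, qcs_per_batch=5,
                   n_compounds=6, n_is=2, batch_factors=(1.0, 3.0),
                   noise_cv=0.05, bio_log_sd=0.3, seed=17)
    table, truth = generate_study_table(spec)
    result = run_pipeline(table)
    return table, result


class TestPCA:
    def _centroid_sep(self, records):
        cents = records.groupby("batch")[["x", "y"]].mean()
        return float(np.linalg.norm(cents.iloc[0] - cents.iloc[1]))

    def test_correction_shrinks_batch_separation(self, shifted_study):
        table, result = shifted_study
        pre = pca_frame(result.ratios, table)
        post = pca_frame(result.corrected, table)
        assert self._centroid_sep(post.records) < self._centroid_sep(pre.records)

    def test_qc_centroid_inside_study_ellipse_after_correction(self, shifted_study):
        table, result = shifted_study
        post = pca_frame(result.corrected, table)
        r = post.records
        qc_centroid = r[r["sample_type"] == "SQC"][["x", "y"]].mean().to_numpy()
        assert point_in_ellipse(qc_centroid, post.metadata["ellipses"]["SAMPLE"])

    def test_scores_invariant_to_row_order(self, shifted_study):
        table, result = shifted_study
        a = pca_frame(result.corrected, table)
        shuffled = result.corrected
        shuffled.frame = shuffled.frame.sample(frac=1.0, random_state=0)
        b = pca_frame(shuffled, table)
        left = a.records.set_index("aliquot")[["x", "y"]].sort_index()
        right = b.records.set_index("aliquot")[["x", "y"]].sort_index()
        pd.testing.assert_frame_equal(left, right, check_exact=False, atol=1e-9)

    def test_duplicated_aliquots_get_identical_scores(self, read):
        rows = []
        for i in range(6):
            for c in ("cmpA", "cmpB", "cmpC"):
                area = {"cmpA": 10, "cmpB": 30, "cmpC": 90}[c] * (1 + 0.1 * (i % 3))
                rows.append(f"S{i}\tSAMPLE\t1\t{c}\t{area}\tIS1\t2\t{timestamp(i)}")
        table, _ = read(rows)
        frame = pca_frame(compute_ratios(table), table)
        scores = frame.records.set_index("aliquot")[["x", "y"]]
        # S0/S3, S1/S4, S2/S5 are identical by construction
        for a, b in (("S0", "S3"), ("S1", "S4"), ("S2", "S5")):
            np.testing.assert_allclose(scores.loc[a], scores.loc[b], atol=1e-9)


class TestViolin:
    def test_correction_aligns_qc_medians_across_batches(self, shifted_study):
        table, result = shifted_study
        pre = violin_frame(result.ratios, table).records
        post = violin_frame(result.corrected, table).records
        spread = lambda r: np.ptp(r.groupby("batch")["y"].median().to_numpy())
        assert spread(post) < spread(pre)

    def test_auto_excluded_qc_absent(self, shifted_study):
        table, result = shifted_study
        some_qc = table.qc_aliquots[0]

        class FakeFlags:
            excluded_aliquots = {some_qc}

        frame = violin_frame(result.corrected, table, FakeFlags())
        assert some_qc not in set(frame.records["aliquot"])

    def test_single_qc_single_violin(self, read):
        rows = [f"Q1\tSQC\t1\tcmp{i}\t{10 * (i + 1)}\tIS1\t2\t{timestamp(0)}"
                for i in range(3)]
        table, _ = read(rows)
        frame = violin_frame(compute_ratios(table), table)
        assert frame.records["aliquot"].nunique() == 1


class TestCompoundFrame:
    def test_missing_value_has_no_point(self, read):
        rows = [f"A{i}\tSAMPLE\t1\tcmpA\t{'NA' if i == 2 else 10}\tIS1\t2\t"
                f"{timestamp(i)}" for i in range(5)]
        table, _ = read(rows)
        frame = compound_frame("cmpA", table, compute_ratios(table),
                               quantity="ratio")
        missing_x = table.aliquots.loc["A2", "injection_index"]
        assert missing_x not in set(frame.records["x"])

    def test_extra_column_passes_through(self, tmp_path):
        from conftest import write_tsv
        header = ("aliquot\ttype\tbatch\tcompound\tarea\tcompound_is\t"
                  "area_is\tdatetime\trt")
        rows = [f"A{i}\tSAMPLE\t1\tcmpA\t10\tIS1\t2\t{timestamp(i)}\t{1.5 + i}"
                for i in range(3)]
        from metaboqc import read_input
        table, _ = read_input(write_tsv(tmp_path / "rt.tsv", rows, header))
        frame = compound_frame("cmpA", table, quantity="rt")
        assert list(frame.records["y"]) == [1.5, 2.5, 3.5]

    def test_unknown_quantity_errors(self, shifted_study):
        table, result = shifted_study
        with pytest.raises(ValueError, match="quantity"):
            compound_frame(table.compounds[0], table, result.ratios,
                           result.corrected, quantity="nope")


class TestExport:
    def test_workbook_tabs_and_partition(self, shifted_study, tmp_path):
        import openpyxl
        table, result = shifted_study
        wb_path = export_report(table, result.ratios, result.corrected,
                                result.metrics, result.flags, result.model,
                                result.report, QCConfig(), tmp_path,
                                plots=False)
        wb = openpyxl.load_workbook(wb_path)
        assert wb.sheetnames == ["High confidence", "With Caution",
                                 "Low Signal to Noise"]
        m = result.metrics.frame
        reported = m[m["tier"] != Tier.NOT_REPORTED.value]
        n_in_tabs = sum(ws.max_column - 1 for ws in wb.worksheets)
        assert n_in_tabs == len(reported)

    def test_long_table_rerun_is_byte_identical(self, shifted_study, tmp_path):
        table, result = shifted_study
        for d in ("a", "b"):
            export_report(table, result.ratios, result.corrected,
                          result.metrics, result.flags, result.model,
                          result.report, QCConfig(), tmp_path / d, plots=False)
        a = (tmp_path / "a" / "long_table.tsv").read_bytes()
        b = (tmp_path / "b" / "long_table.tsv").read_bytes()
        assert a == b

    def test_plot_files_written(self, shifted_study, tmp_path):
        table, result = shifted_study
        export_report(table, result.ratios, result.corrected, result.metrics,
                      result.flags, result.model, result.report, QCConfig(),
                      tmp_path, plots=True)
        for name in ("aliquot_plot.png", "pca_plot.png", "violin_plot.png"):
            assert (tmp_path / name).stat().st_size > 0

    def test_long_export_columns(self, shifted_study):
        table, result = shifted_study
        long_df = long_export(table, result.ratios, result.corrected,
                              result.metrics, result.flags)
        assert {"aliquot", "compound", "area", "area_is", "ratio",
                "corrected_ratio", "tier", "outlier_flagged"} <= set(long_df.columns)
        assert len(long_df) == len(table.data)
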