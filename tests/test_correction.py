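"""Between-batch median correction and within-batch detrending."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaboqc import (QCConfig, apply_between_batch, compute_ratios,
                      fit_between_batch, within_batch_correct)
from metaboqc.simulate import SimSpec, generate_study_table

from conftest import study_rows, timestamp


def factor(model, compound, batch):
    f = model.factors
    return f[(f["compound"] == compound) & (f["batch"] == batch)]["factor"].iloc[0]


class TestBetweenBatch:
    def test_two_batch_hand_oracle(self, two_batch_study):
        """QC medians 2 and 4 -> grand median 3, factors 1.5 and 0.75."""
        table = two_batch_study
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios, None, QCConfig())
        assert factor(model, "cmpA", "1") == pytest.approx(1.5)
        assert factor(model, "cmpA", "2") == pytest.approx(0.75)
        assert model.factors["grand_median"].iloc[0] == pytest.approx(3.0)

    def test_post_correction_batch_medians_equal_grand(self, two_batch_study):
        table = two_batch_study
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios, None, QCConfig())
        corrected = apply_between_batch(table, ratios, model)
        f = corrected.frame.copy()
        f["batch"] = f["aliquot"].map(table.aliquots["batch"])
        qc = f[f["aliquot"].isin(table.qc_aliquots)]
        medians = qc.groupby("batch")["corrected_ratio"].median()
        np.testing.assert_allclose(medians.to_numpy(), 3.0, rtol=1e-10)

    def test_identical_batches_give_unit_factors(self, read):
        aliquots = [(f"B{b}_Q{i}", "SQC", str(b)) for b in (1, 2)
                    for i in range(3)]
        areas = {"cmpA": {name: 5.0 for name, _, _ in aliquots}}
        table, _ = read(study_rows(aliquots, areas))
        model = fit_between_batch(table, compute_ratios(table))
        assert (model.factors["factor"] == 1.0).all()

    def test_single_batch_factor_is_one(self, read):
        aliquots = [(f"Q{i}", "SQC", "1") for i in range(4)]
        areas = {"cmpA": {f"Q{i}": 2.0 + i for i in range(4)}}
        table, _ = read(study_rows(aliquots, areas))
        model = fit_between_batch(table, compute_ratios(table))
        assert (model.factors["factor"] == 1.0).all()

    def test_missing_ratio_stays_missing(self, two_batch_study):
        table = two_batch_study
        ratios = compute_ratios(table)
        ratios.frame.loc[0, "ratio"] = np.nan
        model = fit_between_batch(table, ratios)
        corrected = apply_between_batch(table, ratios, model)
        assert np.isnan(corrected.frame.loc[0, "corrected_ratio"])

    def test_compound_without_qc_signal_has_undefined_factors(self, read):
        aliquots = ([(f"B1_Q{i}", "SQC", "1") for i in range(3)]
                    + [(f"B2_Q{i}", "SQC", "2") for i in range(3)])
        areas = {"good": {name: 4.0 for name, _, _ in aliquots},
                 "silent": {}}
        rows = study_rows(aliquots, areas)
        # add explicit NA rows for the silent compound
        rows += [f"{name}\tSQC\t{batch}\tsilent\tNA\tIS1\t1\t{timestamp(i)}"
                 for i, (name, _, batch) in enumerate(aliquots)]
        table, _ = read(rows)
        model = fit_between_batch(table, compute_ratios(table))
        silent = model.factors[model.factors["compound"] == "silent"]
        assert silent["factor"].isna().all()
        assert any("silent" in w for w in model.warnings)

    def test_idempotence_correcting_corrected_gives_unit_factors(self, two_batch_study):
        from metaboqc.normalization import RatioTable
        table = two_batch_study
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios)
        corrected = apply_between_batch(table, ratios, model)
        again = RatioTable(frame=corrected.frame.rename(
            columns={"corrected_ratio": "ratio"}))
        model2 = fit_between_batch(table, again)
        np.testing.assert_allclose(
            model2.factors["factor"].to_numpy(), 1.0, rtol=1e-12)

    def test_recovers_planted_factors_on_synthetic_data(self, small_study):
        table, truth = small_study
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios)
        g = np.array(truth["batch_factors"])
        for compound in table.compounds:
            f = (model.factors[model.factors["compound"] == compound]
                 .set_index("batch")["factor"]
                 .reindex([str(b + 1) for b in range(3)]).to_numpy())
            c = f * g
            assert np.ptp(c) / np.median(c) < 0.05  # tight check in acceptance


def drift_rows(slope, n_qc=6, n_sample=6, intercept=10.0):
    """Single batch whose QC ratios follow intercept + slope * injection."""
    aliquots, areas = [], {"cmpA": {}}
    order, q, s = [], n_qc, n_sample
    while q or s:  # alternate, QCs first, until each count is exhausted
        if q:
            order.append("SQC")
            q -= 1
        if s:
            order.append("SAMPLE")
            s -= 1
    for i, stype in enumerate(order):
        name = f"{stype}{i}"
        aliquots.append((name, stype, "1"))
        areas["cmpA"][name] = intercept + slope * (i + 1)
    return study_rows(aliquots, areas)


class TestWithinBatch:
    def _corrected(self, read, rows, config=None):
        table, _ = read(rows)
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios, None, config)
        corrected = apply_between_batch(table, ratios, model)
        return table, within_batch_correct(table, corrected, None, config,
                                           model=model), model

    def test_noiseless_linear_drift_removed(self, read):
        table, corrected, model = self._corrected(read, drift_rows(-0.1))
        f = corrected.frame.copy()
        f["x"] = f["aliquot"].map(table.aliquots["injection_index"])
        qc = f[f["aliquot"].isin(table.qc_aliquots)]
        slope = np.polyfit(qc["x"], qc["corrected_ratio"], 1)[0]
        assert abs(slope) < 1e-8
        assert not model.drift_fits.empty

    def test_batch_median_preserved(self, read):
        table, _, _ = self._corrected(read, drift_rows(-0.1))
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios)
        before = apply_between_batch(table, ratios, model)
        after = within_batch_correct(table, before)
        qc = table.qc_aliquots
        med = lambda c: (c.frame[c.frame["aliquot"].isin(qc)]
                         ["corrected_ratio"].median())
        assert med(after) == pytest.approx(med(before), rel=1e-10)

    def test_zero_slope_is_identity(self, read):
        table, corrected, _ = self._corrected(read, drift_rows(0.0))
        ratios = compute_ratios(table)
        np.testing.assert_allclose(
            corrected.frame["corrected_ratio"].to_numpy(),
            ratios.frame["ratio"].to_numpy(), rtol=1e-12)

    def test_guard_too_few_qcs(self, read):
        rows = drift_rows(-0.1, n_qc=3, n_sample=6)
        table, corrected, model = self._corrected(read, rows)
        ratios = compute_ratios(table)
        np.testing.assert_allclose(
            corrected.frame["corrected_ratio"].to_numpy(),
            ratios.frame["ratio"].to_numpy())
        assert model.drift_fits.empty

    def test_nonpositive_trend_skips_with_warning(self, read):
        # steeply decaying QCs at the batch start: the fitted line is
        # negative by the time it reaches the trailing study samples
        aliquots = [(f"Q{i}", "SQC", "1") for i in range(4)]
        aliquots += [(f"S{i}", "SAMPLE", "1") for i in range(8)]
        areas = {"cmpA": {f"Q{i}": 10.0 - 3.0 * i for i in range(4)}}
        areas["cmpA"].update({f"S{i}": 5.0 for i in range(8)})
        rows = study_rows(aliquots, areas)
        table, _ = read(rows)
        ratios = compute_ratios(table)
        model = fit_between_batch(table, ratios)
        before = apply_between_batch(table, ratios, model)
        after = within_batch_correct(table, before)
        np.testing.assert_allclose(
            after.frame["corrected_ratio"].to_numpy(),
            before.frame["corrected_ratio"].to_numpy())
        assert any("skipped" in w for w in after.warnings)
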