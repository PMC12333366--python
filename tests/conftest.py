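"""Shared fixtures: hand-built study tables and small synthetic studies."""

from __future__ import annotations

from pathlib import Path

import pytest

from metaboqc import QCConfig, read_input
from metaboqc.simulate import SimSpec, generate_study_table

HEADER = "aliquot\ttype\tbatch\tcompound\tarea\tcompound_is\tarea_is\tdatetime"


def write_tsv(path: Path, rows: list[str], header: str = HEADER) -> Path:
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def timestamp(i: int) -> str:
    """Evenly spaced timestamps in injection order."""
    return f"2024-01-01 {8 + i // 60:02d}:{i % 60:02d}:00"


def study_rows(aliquots: list[tuple[str, str, str]],
               compounds: dict[str, dict[str, float | str]],
               is_name: str = "IS1",
               is_area: float = 1.0) -> list[str]:
    """Rows for aliquots [(name, type, batch), ...] x compounds
    {compound: {aliquot: area}}; missing aliquot entries are skipped."""
    rows = []
    for i, (name, stype, batch) in enumerate(aliquots):
        for compound, areas in compounds.items():
            if name not in areas:
                continue
            rows.append(f"{name}\t{stype}\t{batch}\t{compound}\t"
                        f"{areas[name]}\t{is_name}\t{is_area}\t{timestamp(i)}")
    return rows


@pytest.fixture
def read(tmp_path):
    """Write rows to a TSV and read them back through the validator."""

    def _read(rows: list[str], header: str = HEADER, config: QCConfig | None = None):
        path = write_tsv(tmp_path / "input.tsv", rows, header)
        return read_input(path, config or QCConfig())

    return _read


@pytest.fixture
def two_batch_study(read):
    """Two batches of 3 QCs each, unit IS areas, QC ratios 2 and 4.

    The hand-computable between-batch example: batch medians 2 and 4,
    grand median 3, factors 1.5 and 0.75. Includes a couple of study
    samples and blanks so downstream metrics have inputs.
    """
    aliquots = (
        [(f"B1_QC{i}", "SQC", "1") for i in range(1, 4)]
        + [("B1_S1", "SAMPLE", "1"), ("B1_BL", "BLANK", "1")]
        + [(f"B2_QC{i}", "SQC", "2") for i in range(1, 4)]
        + [("B2_S1", "SAMPLE", "2"), ("B2_BL", "BLANK", "2")]
    )
    areas = {"cmpA": {}}
    for name, stype, batch in aliquots:
        if stype == "SQC":
            areas["cmpA"][name] = 2.0 if batch == "1" else 4.0
        elif stype == "SAMPLE":
            areas["cmpA"][name] = 3.0
        else:
            areas["cmpA"][name] = 0.3
    table, report = read(study_rows(aliquots, areas))
    assert table is not None and report.ok
    return table


@pytest.fixture(scope="session")
def small_study():
    """A 3-batch synthetic study with planted batch factors, read from disk."""
    spec = SimSpec(n_batches=3, samples_per_batch=15, qcs_per_batch=4,
                   n_compounds=4, n_is=2, batch_factors=(1.0, 1.6, 0.7),
                   noise_cv=0.05, seed=11)
    table, truth = generate_study_table(spec)
    return table, truth
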