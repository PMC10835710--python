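import numpy as np
import pytest

from phenocompare import RepeatedMeasuresTable, load_pefr


@pytest.fixture(scope="session")
def pefr():
    """The 17-subject, 2-meter, 2-replicate peak-flow table."""
    return load_pefr()


@pytest.fixture
def two_method_table():
    """Tiny well-formed table: 3 subjects, 2 methods, 2 replicates."""
    records = []
    values = {
        ("s1", "A"): (10.0, 10.2),
        ("s1", "B"): (10.1, 10.3),
        ("s2", "A"): (20.0, 19.8),
        ("s2", "B"): (20.4, 20.2),
        ("s3", "A"): (30.5, 30.1),
        ("s3", "B"): (30.0, 30.6),
    }
    for (s, m), vals in values.items():
        for i, v in enumerate(vals, 1):
            records.append((s, m, i, v))
    return RepeatedMeasuresTable.from_records(records, units_label="u")


def table_from_subject_values(values_by_subject_method, units_label=""):
    """Build a table from {(subject, method): [replicate values]}."""
    records = []
    for (s, m), vals in values_by_subject_method.items():
        for i, v in enumerate(vals, 1):
            records.append((s, m, i, float(v)))
    return RepeatedMeasuresTable.from_records(records, units_label=units_label)
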