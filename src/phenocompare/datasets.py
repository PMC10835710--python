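"""Bundled datasets.

Currently one: the classic peak expiratory flow rate (PEFR) method-comparison
table of Bland & Altman (1986, Lancet i:307-310) — 17 subjects measured twice
each with a Wright peak flow meter (method ``"wright"``) and twice with a
mini-Wright meter (method ``"mini"``), in l/min.
"""

from __future__ import annotations

from importlib.resources import files

from .data_model import RepeatedMeasuresTable, read_repeated_measures_csv

PEFR_UNITS = "l/min"
PEFR_WRIGHT = "wright"
PEFR_MINI = "mini"


def pefr_csv_path():
    """Path to the bundled long-format PEFR CSV."""
    return files("phenocompare").joinpath("data/pefr.csv")


def load_pefr() -> RepeatedMeasuresTable:
    """The Bland & Altman (1986) PEFR table: 17 subjects x 2 meters x 2 replicates."""
    with pefr_csv_path().open("rb") as fh:
        return read_repeated_measures_csv(fh, units_label=PEFR_UNITS)
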