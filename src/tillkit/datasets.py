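"""Packaged datasets: the published Red Setter tomato TILLING screen.

These are transcriptions of the published summary tables for the EMS-
mutagenized Red Setter collection (two doses, 0.7% and 1% EMS; seven
fruit-quality genes screened by mismatch cleavage in eightfold M3 pools).
They serve as worked-example inputs and as fixtures for reproducing the
published density and spectrum figures.
"""

from __future__ import annotations

from importlib import resources

from .screen_data import (CohortScreen, PopulationLedger, read_population_ledger,
                          read_screen_table)


def _data_path(name: str):
    return resources.files("tillkit.data").joinpath(name)


def red_setter_screen() -> list[CohortScreen]:
    """The seven-gene screen summary: amplicon sizes, families screened and
    mutation counts per dose (0.7% EMS and 1% EMS cohorts)."""
    with resources.as_file(_data_path("red_setter_screen.tsv")) as p:
        return read_screen_table(p)


def red_setter_ledger() -> PopulationLedger:
    """Population development counts per dose: seeds treated, M1 plants
    transplanted, M2 and M3 seed families."""
    with resources.as_file(_data_path("red_setter_ledger.tsv")) as p:
        return read_population_ledger(p)
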