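"""Six-class EMS substitution-spectrum classification.

A single-base substitution and its reverse-complement counterpart hit the same
base *pair*, so the 12 ordered changes collapse into six canonical classes
named by the base-pair change: GC/AT, GC/TA, AT/TA, AT/GC, AT/CG and GC/CG.
EMS alkylates guanine, so heavily mutagenized plant populations are dominated
by the GC/AT transition class.

Two transition definitions are supported when summarizing: the chemical one
(GC/AT and AT/GC are both purine<->purine transitions) and a reporting
convention in which only GC/AT is counted as "the transition class" and the
other five are grouped as transversions.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_away
from .errors import TillkitError
from .screen_data import MutationRecord

#: Canonical class order used in all tables.
CLASSES = ("GC/AT", "GC/TA", "AT/TA", "AT/GC", "AT/CG", "GC/CG")

#: Classes that are purine<->purine / pyrimidine<->pyrimidine changes.
CHEMICAL_TRANSITIONS = frozenset({"GC/AT", "AT/GC"})

_CLASS_OF: dict[tuple[str, str], str] = {
    ("G", "A"): "GC/AT", ("C", "T"): "GC/AT",
    ("G", "T"): "GC/TA", ("C", "A"): "GC/TA",
    ("A", "T"): "AT/TA", ("T", "A"): "AT/TA",
    ("A", "G"): "AT/GC", ("T", "C"): "AT/GC",
    ("A", "C"): "AT/CG", ("T", "G"): "AT/CG",
    ("G", "C"): "GC/CG", ("C", "G"): "GC/CG",
}


def canonical_class(ref: str, alt: str) -> str:
    """Map an ordered substitution to its canonical base-pair-change class.

    Strand is collapsed: G>A and C>T both report the GC/AT class, etc.
    """
    key = (ref.upper(), alt.upper())
    if key not in _CLASS_OF:
        raise TillkitError(f"invalid substitution {ref!r}>{alt!r}")
    return _CLASS_OF[key]


def is_transition(cls: str, definition: str = "chemical") -> bool:
    """Whether a class counts as a transition under the given definition.

    ``chemical``: GC/AT and AT/GC. ``reporting``: only GC/AT (the convention
    some screen tables use, placing AT/GC with the transversions).
    """
    if cls not in CLASSES:
        raise TillkitError(f"unknown substitution class {cls!r}")
    if definition == "chemical":
        return cls in CHEMICAL_TRANSITIONS
    if definition == "reporting":
        return cls == "GC/AT"
    raise TillkitError(f"unknown transition definition {definition!r}")


def class_counts(records: Iterable[MutationRecord]) -> dict[str, int]:
    """Count records per canonical class (all six classes present, zeros kept)."""
    counts = dict.fromkeys(CLASSES, 0)
    for rec in records:
        counts[canonical_class(rec.ref_base, rec.alt_base)] += 1
    return counts


def load_reference_spectra(names: Sequence[str] | None = None) -> dict[str, dict[str, float]]:
    """Packaged published comparison spectra (percent per class) by organism."""
    text = resources.files("tillkit.data").joinpath("reference_spectra.json").read_text()
    spectra = json.loads(text)
    if names is None:
        return spectra
    missing = [n for n in names if n not in spectra]
    if missing:
        raise TillkitError(f"no packaged reference spectrum for {missing}")
    return {n: spectra[n] for n in names}


def spectrum_table(cohorts: Mapping[str, Sequence[MutationRecord]],
                   reference_columns: Mapping[str, Mapping[str, float]] | None = None,
                   transition_definition: str = "chemical") -> pd.DataFrame:
    """Build a spectrum table: counts and percentages per class per cohort.

    One row per canonical class in canonical order, plus a trailing
    ``transition_pct`` summary row computed under ``transition_definition``.
    Percentages are rounded to one decimal, half away from zero; an empty
    cohort gets NaN percentages (counts stay zero). ``reference_columns`` are
    fixed percentage columns (e.g. published spectra of other species)
    appended verbatim.
    """
    data: dict[str, list] = {"class": list(CLASSES)}
    kinds = ["transition" if is_transition(c, transition_definition) else "transversion"
             for c in CLASSES]
    data["kind"] = kinds
    summary: dict[str, float | str | None] = {"class": "transition_pct", "kind": ""}

    for label, records in cohorts.items():
        counts = class_counts(records)
        total = sum(counts.values())
        data[f"{label} count"] = [counts[c] for c in CLASSES]
        if total:
            pcts = [round_half_away(100.0 * counts[c] / total, 1) for c in CLASSES]
        else:
            pcts = [float("nan")] * len(CLASSES)
        data[f"{label} pct"] = pcts
        summary[f"{label} count"] = total
        summary[f"{label} pct"] = (
            round_half_away(sum(p for c, p in zip(CLASSES, pcts)
                                if is_transition(c, transition_definition)), 1)
            if total else float("nan"))

    if reference_columns:
        for name, col in reference_columns.items():
            data[f"{name} pct"] = [float(col.get(c, 0.0)) for c in CLASSES]
            summary[f"{name} pct"] = round_half_away(
                sum(float(col.get(c, 0.0)) for c in CLASSES
                    if is_transition(c, transition_definition)), 1)

    table = pd.DataFrame(data)
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
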