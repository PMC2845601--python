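"""Local phenotype catalog with a controlled vocabulary.

The vocabulary — 17 phenotype classes and 51 subclasses covering a tomato
mutant collection from seed germination through fruit ripening — ships as
packaged data, together with the published per-subclass plant counts for
reference. Observations are validated against the vocabulary
(case-insensitively, whitespace-normalized), queried with conjunctive
filters, and summarized per class/subclass and per plant.
"""

from __future__ import annotations

import csv
import difflib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import QueryError, VocabularyError


def _norm(term: str) -> str:
    return " ".join(term.strip().lower().split())


@dataclass(frozen=True)
class PhenotypeVocabulary:
    """Ordered classes, each with ordered subclasses; terms are unique."""

    classes: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_subclasses(self) -> int:
        return sum(len(subs) for _, subs in self.classes)

    def class_names(self) -> list[str]:
        return [name for name, _ in self.classes]

    def subclasses_of(self, class_name: str) -> tuple[str, ...]:
        target = _norm(class_name)
        for name, subs in self.classes:
            if _norm(name) == target:
                return subs
        raise VocabularyError(f"unknown phenotype class {class_name!r}")

    def resolve(self, class_name: str, subclass_name: str) -> tuple[str, str]:
        """Return the canonical (class, subclass) pair, or raise with suggestions."""
        target_cls = _norm(class_name)
        for name, subs in self.classes:
            if _norm(name) != target_cls:
                continue
            target_sub = _norm(subclass_name)
            for sub in subs:
                if _norm(sub) == target_sub:
                    return name, sub
            nearest = difflib.get_close_matches(subclass_name, subs, n=3, cutoff=0.3)
            raise VocabularyError(
                f"unknown subclass {subclass_name!r} in class {name!r}; "
                f"did you mean {nearest or list(subs)}?")
        nearest = difflib.get_close_matches(class_name, self.class_names(), n=3, cutoff=0.3)
        raise VocabularyError(
            f"unknown phenotype class {class_name!r}; did you mean {nearest}?")


def load_vocabulary() -> PhenotypeVocabulary:
    """Load the packaged 17-class / 51-subclass vocabulary."""
    raw = json.loads(
        resources.files("tillkit.data").joinpath("phenotype_vocabulary.json").read_text())
    classes = tuple(
        (cls["name"], tuple(sub["name"] for sub in cls["subclasses"]))
        for cls in raw["classes"])
    return PhenotypeVocabulary(classes=classes)


def load_reference_counts() -> dict[tuple[str, str], int]:
    """Published number of plants observed per (class, subclass)."""
    raw = json.loads(
        resources.files("tillkit.data").joinpath("phenotype_vocabulary.json").read_text())
    return {(cls["name"], sub["name"]): sub["reported_plants"]
            for cls in raw["classes"] for sub in cls["subclasses"]}


@dataclass(frozen=True)
class PhenotypeObservation:
    """One scored trait on one plant, with vocabulary-canonical terms."""

    plant_code: str
    family_id: str
    class_name: str
    subclass_name: str
    developmental_stage: str | None = None
    photo_ref: str | None = None


def validate_observation(raw: Mapping[str, str],
                         vocab: PhenotypeVocabulary) -> PhenotypeObservation:
    """Validate a raw record into a :class:`PhenotypeObservation`.

    Terms are matched case-insensitively with collapsed whitespace; an unknown
    class or subclass raises :class:`VocabularyError` suggesting the nearest
    valid terms.
    """
    cls, sub = vocab.resolve(raw["class"], raw["subclass"])
    return PhenotypeObservation(
        plant_code=str(raw["plant_code"]).strip(),
        family_id=str(raw.get("family_id", "")).strip(),
        class_name=cls,
        subclass_name=sub,
        developmental_stage=(raw.get("stage") or None),
        photo_ref=(raw.get("photo") or None),
    )


def read_observations(path: str | Path,
                      vocab: PhenotypeVocabulary | None = None) -> list[PhenotypeObservation]:
    """Read observations from CSV (`plant_code,family_id,class,subclass,stage,photo`)."""
    vocab = vocab or load_vocabulary()
    with Path(path).open(newline="") as fh:
        return [validate_observation(row, vocab) for row in csv.DictReader(fh)]


def write_observations(observations: Sequence[PhenotypeObservation], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant_code", "family_id", "class", "subclass", "stage", "photo"])
        for o in observations:
            writer.writerow([o.plant_code, o.family_id, o.class_name, o.subclass_name,
                             o.developmental_stage or "", o.photo_ref or ""])


_FILTER_FIELDS = {
    "plant": "plant_code",
    "plant_code": "plant_code",
    "family": "family_id",
    "family_id": "family_id",
    "class": "class_name",
    "subclass": "subclass_name",
}


def query_catalog(observations: Iterable[PhenotypeObservation],
                  **filters: str) -> list[PhenotypeObservation]:
    """Conjunctive filtering by plant / family / class / subclass; stable order.

    Term matching is case-insensitive with collapsed whitespace; no match is
    an empty result, not an error. Unknown filter fields raise
    :class:`QueryError`.
    """
    resolved = {}
    for key, value in filters.items():
        if key not in _FILTER_FIELDS:
            raise QueryError(f"unknown query field {key!r}; "
                             f"valid fields: {sorted(set(_FILTER_FIELDS))}")
        resolved[_FILTER_FIELDS[key]] = _norm(str(value))
    return [o for o in observations
            if all(_norm(getattr(o, attr)) == v for attr, v in resolved.items())]


def summarize_catalog(observations: Sequence[PhenotypeObservation],
                      plants_total: int) -> dict:
    """Catalog-level summary: per-term plant counts and mutant-plant fractions.

    Counts distinct plants per subclass and per class (a plant showing traits
    in several classes is counted in each), the fraction of all
    ``plants_total`` plants with at least one observation, and — among those
    mutant plants — the fraction observed in more than one major class.
    Percentages are plain floats (not pre-rounded).
    """
    if plants_total <= 0:
        raise QueryError("plants_total must be positive")
    per_subclass: dict[tuple[str, str], set] = {}
    per_class: dict[str, set] = {}
    classes_of_plant: dict[str, set] = {}
    for o in observations:
        per_subclass.setdefault((o.class_name, o.subclass_name), set()).add(o.plant_code)
        per_class.setdefault(o.class_name, set()).add(o.plant_code)
        classes_of_plant.setdefault(o.plant_code, set()).add(o.class_name)
    mutants = len(classes_of_plant)
    multi = sum(1 for cls_set in classes_of_plant.values() if len(cls_set) > 1)
    return {
        "plants_total": plants_total,
        "plants_with_trait": mutants,
        "pct_with_trait": 100.0 * mutants / plants_total,
        "plants_multi_class": multi,
        "pct_multi_class_among_mutants": (100.0 * multi / mutants) if mutants else 0.0,
        "per_class_counts": {k: len(v) for k, v in per_class.items()},
        "per_subclass_counts": {k: len(v) for k, v in per_subclass.items()},
    }
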