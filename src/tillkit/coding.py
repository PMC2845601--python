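"""Coding-effect annotation of amplicon substitutions.

Given an amplicon with a reference sequence and CDS intervals (forward strand,
1-based inclusive, with a frame offset for truncated leading codons), each
substitution is labelled noncoding, silent, missense, nonsense or stop-loss
by locating its codon in the spliced CDS and translating with the standard
nuclear genetic code. Codons may span CDS segment junctions; amplicons with
no CDS annotation yield region "unknown".

Genes on the reverse strand must be supplied as reverse-complemented
amplicons — effects are always computed on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from ._util import round_half_away
from .errors import BoundsError, ConsistencyError, TillkitError
from .screen_data import AmpliconTarget, MutationRecord

EFFECT_LABELS = ("silent", "missense", "nonsense", "stop-loss")


def codon_effect(ref_codon: str, alt_codon: str) -> str:
    """Classify a single-base codon change as silent/missense/nonsense/stop-loss."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise TillkitError("codons must be 3 bases")
    if any(b not in "ACGT" for b in ref_codon + alt_codon):
        raise TillkitError(f"invalid base in codons {ref_codon!r}/{alt_codon!r}")
    diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if diffs != 1:
        raise TillkitError(f"codons must differ at exactly one position, got {diffs}")
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop-loss"
    return "missense"


def _spliced_cds(amplicon: AmpliconTarget) -> str:
    seq = amplicon.reference_sequence
    return "".join(seq[start - 1:end] for start, end in amplicon.cds.segments)


def _cds_index(amplicon: AmpliconTarget, position: int) -> int | None:
    """0-based index of an amplicon position in the spliced CDS, None if intronic."""
    offset = 0
    for start, end in amplicon.cds.segments:
        if start <= position <= end:
            return offset + (position - start)
        offset += end - start + 1
    return None


def annotate_mutation(record: MutationRecord, amplicon: AmpliconTarget) -> MutationRecord:
    """Return a copy of ``record`` with region and coding effect filled in.

    The amplicon must carry a reference sequence whose base at the record's
    position matches the record's ref base (a mismatch raises
    :class:`ConsistencyError`). Positions outside every CDS segment are
    "noncoding" with no effect; with no CDS annotation at all the region is
    "unknown". A codon truncated by the amplicon boundary (frame offset at the
    5' end, or an incomplete trailing codon) leaves the effect unset.
    Annotation is idempotent.
    """
    if amplicon.reference_sequence is None:
        raise TillkitError(f"amplicon {amplicon.gene_name} has no reference sequence")
    seq = amplicon.reference_sequence
    if not 1 <= record.position <= len(seq):
        raise BoundsError(
            f"position {record.position} outside amplicon {amplicon.gene_name} "
            f"(1..{len(seq)})")
    found = seq[record.position - 1]
    if found != record.ref_base:
        raise ConsistencyError(
            f"{amplicon.gene_name}:{record.position} reference base is {found}, "
            f"record says {record.ref_base}")

    if amplicon.cds is None:
        return replace(record, region="unknown", effect=None)

    idx = _cds_index(amplicon, record.position)
    if idx is None:
        return replace(record, region="noncoding", effect=None)

    spliced = _spliced_cds(amplicon)
    adjusted = idx - amplicon.cds.frame_offset
    if adjusted < 0:
        return replace(record, region="coding", effect=None)  # truncated 5' codon
    codon_start = amplicon.cds.frame_offset + 3 * (adjusted // 3)
    if codon_start + 3 > len(spliced):
        return replace(record, region="coding", effect=None)  # truncated 3' codon
    ref_codon = spliced[codon_start:codon_start + 3]
    within = idx - codon_start
    alt_codon = ref_codon[:within] + record.alt_base + ref_codon[within + 1:]
    return replace(record, region="coding", effect=codon_effect(ref_codon, alt_codon))


def annotate_all(records, amplicons) -> list[MutationRecord]:
    """Annotate each record against its amplicon (matched by gene name)."""
    by_name = {a.gene_name: a for a in amplicons}
    out = []
    for rec in records:
        if rec.gene_name not in by_name:
            raise TillkitError(f"no amplicon annotation for gene {rec.gene_name!r}")
        out.append(annotate_mutation(rec, by_name[rec.gene_name]))
    return out


@dataclass
class EffectSummary:
    """Effect counts, with percentages over determinate coding records only."""

    effect_counts: dict[str, int]
    effect_percentages: dict[str, float | None]
    coding_total: int
    noncoding: int
    unknown: int
    undetermined: int  # coding but codon truncated by the amplicon boundary

    def as_dict(self) -> dict:
        return {
            "effect_counts": self.effect_counts,
            "effect_percentages": self.effect_percentages,
            "coding_total": self.coding_total,
            "noncoding": self.noncoding,
            "unknown": self.unknown,
            "undetermined": self.undetermined,
        }


def effect_summary(records) -> EffectSummary:
    """Summarize annotated records into effect counts and percentages.

    Percentages (one decimal) are taken over coding records with a determinate
    effect — the convention under which screen reports quote e.g. a
    silent/missense split "among the exonic mutations". With no such records
    the percentages are undefined (``None``).
    """
    counts = dict.fromkeys(EFFECT_LABELS, 0)
    noncoding = unknown = undetermined = 0
    for rec in records:
        if rec.region == "noncoding":
            noncoding += 1
        elif rec.region == "unknown":
            unknown += 1
        elif rec.effect is None:
            undetermined += 1
        else:
            counts[rec.effect] += 1
    total = sum(counts.values())
    pcts: dict[str, float | None]
    if total:
        pcts = {k: round_half_away(100.0 * v / total, 1) for k, v in counts.items()}
    else:
        pcts = dict.fromkeys(EFFECT_LABELS, None)
    return EffectSummary(effect_counts=counts, effect_percentages=pcts,
                         coding_total=total, noncoding=noncoding,
                         unknown=unknown, undetermined=undetermined)
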