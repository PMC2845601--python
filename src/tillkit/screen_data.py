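"""Domain types and readers/writers for pooled TILLING screen data.

The central objects are :class:`AmpliconTarget` (a PCR fragment screened for
induced mutations), :class:`MutationRecord` (one nucleotide substitution found
in one M3 family), :class:`CohortScreen` (one EMS dose's screen over a set of
amplicons) and :class:`PopulationLedger` (generation-by-generation accounting
of the mutagenized population).

Coordinates are 1-based inclusive on the forward strand of each amplicon,
matching the variant-call convention used for output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._util import parse_int, round_half_away
from .errors import BoundsError, FormatError, ParseError

VALID_BASES = frozenset("ACGT")

SCREEN_COLUMNS = ("gene", "amplicon_kb", "families_screened", "mutations", "dose")


@dataclass(frozen=True)
class CdsAnnotation:
    """Ordered CDS intervals of an amplicon, 1-based inclusive, forward strand.

    ``frame_offset`` is the number of leading bases of the concatenated CDS
    that belong to an upstream, truncated codon (amplicons clip genes, so the
    spliced CDS need not start in frame or be a multiple of three).
    """

    segments: tuple[tuple[int, int], ...]
    frame_offset: int = 0

    def __post_init__(self):
        prev_end = 0
        for start, end in self.segments:
            if start > end:
                raise BoundsError(f"CDS interval ({start}, {end}) has start > end")
            if start <= prev_end:
                raise BoundsError("CDS intervals must be ascending and non-overlapping")
            prev_end = end
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")


@dataclass(frozen=True)
class AmpliconTarget:
    """A tilled gene fragment: its screened length and optional annotation."""

    gene_name: str
    amplicon_length_kb: float
    reference_sequence: str | None = None
    cds: CdsAnnotation | None = None

    def __post_init__(self):
        if self.amplicon_length_kb <= 0:
            raise ValueError(f"amplicon_length_kb must be positive, got {self.amplicon_length_kb}")
        if self.reference_sequence is not None:
            seq = self.reference_sequence.upper()
            object.__setattr__(self, "reference_sequence", seq)
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases in {self.gene_name}: {sorted(bad)}")
            if abs(len(seq) / 1000.0 - self.amplicon_length_kb) > 0.0005:
                raise ValueError(
                    f"{self.gene_name}: sequence length {len(seq)} bp disagrees with "
                    f"amplicon_length_kb={self.amplicon_length_kb}"
                )
            if self.cds is not None and self.cds.segments and self.cds.segments[-1][1] > len(seq):
                raise BoundsError(f"{self.gene_name}: CDS interval beyond sequence end")

    @property
    def length_bp(self) -> int:
        if self.reference_sequence is not None:
            return len(self.reference_sequence)
        return int(round(self.amplicon_length_kb * 1000))


@dataclass(frozen=True)
class MutationRecord:
    """One induced single-base substitution in one M3 family."""

    gene_name: str
    family_id: str
    position: int  # 1-based within the amplicon
    ref_base: str
    alt_base: str
    region: str = "unknown"  # coding | noncoding | unknown
    effect: str | None = None  # silent | missense | nonsense | stop-loss

    def __post_init__(self):
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValueError(f"bases must be one of A/C/G/T, got {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.position < 1:
            raise BoundsError(f"position must be >= 1, got {self.position}")
        if self.region not in ("coding", "noncoding", "unknown"):
            raise ValueError(f"unknown region label {self.region!r}")
        if self.effect is not None and self.effect not in (
            "silent",
            "missense",
            "nonsense",
            "stop-loss",
        ):
            raise ValueError(f"unknown effect label {self.effect!r}")


@dataclass(frozen=True)
class ScreenRow:
    """One amplicon's line in one dose's screen."""

    amplicon: AmpliconTarget
    families_screened: int
    mutation_count: int
    mutations: tuple[MutationRecord, ...] | None = None

    def __post_init__(self):
        if self.families_screened < 0 or self.mutation_count < 0:
            raise ValueError("counts must be non-negative")
        if self.mutations is not None and len(self.mutations) != self.mutation_count:
            raise ValueError(
                f"{self.amplicon.gene_name}: {len(self.mutations)} mutation records "
                f"but mutation_count={self.mutation_count}"
            )


@dataclass
class CohortScreen:
    """One EMS dose's screen: one row per amplicon."""

    dose_label: str
    rows: list[ScreenRow] = field(default_factory=list)

    def __post_init__(self):
        names = [r.amplicon.gene_name for r in self.rows]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate amplicon row in cohort {self.dose_label!r}")

    @property
    def total_mutations(self) -> int:
        return sum(r.mutation_count for r in self.rows)


@dataclass(frozen=True)
class DoseCounts:
    """Per-dose population counts from mutagenesis through M3 seed harvest."""

    seeds_treated: int
    m1_transplanted: int
    m2_families: int
    m3_families: int

    def __post_init__(self):
        chain = (self.seeds_treated, self.m1_transplanted, self.m2_families, self.m3_families)
        if any(c < 0 for c in chain):
            raise ValueError("counts must be non-negative")
        if not (self.m3_families <= self.m2_families <= self.m1_transplanted <= self.seeds_treated):
            raise ValueError(
                "population counts must be non-increasing: "
                "seeds >= M1 >= M2 families >= M3 families"
            )


@dataclass
class PopulationLedger:
    """Population accounting keyed by dose label."""

    doses: dict[str, DoseCounts]


# ---------------------------------------------------------------------------
# Screen table I/O


def read_screen_table(path: str | Path, *, delimiter: str = "\t") -> list[CohortScreen]:
    """Read a delimited screen summary into one :class:`CohortScreen` per dose.

    The file needs a header with columns ``gene``, ``amplicon_kb``,
    ``families_screened``, ``mutations`` and ``dose``. Integer cells may carry
    thousands separators ("3,885"); derived density columns, if present, are
    ignored (they are outputs, not inputs). Cohorts come back in first-seen
    dose order, rows in file order.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in SCREEN_COLUMNS:
            if col not in header:
                raise FormatError(f"screen table {path.name} is missing column {col!r}")
        cohorts: dict[str, list[ScreenRow]] = {}
        for i, row in enumerate(reader, start=2):
            ctx = f"{path.name} line {i}"
            try:
                kb = float(str(row["amplicon_kb"]).replace(",", ""))
            except ValueError as exc:
                raise ParseError(f"non-numeric cell {row['amplicon_kb']!r} at {ctx}, "
                                 f"column amplicon_kb") from exc
            screen_row = ScreenRow(
                amplicon=AmpliconTarget(gene_name=row["gene"].strip(), amplicon_length_kb=kb),
                families_screened=parse_int(row["families_screened"],
                                            context=f"{ctx}, column families_screened"),
                mutation_count=parse_int(row["mutations"], context=f"{ctx}, column mutations"),
            )
            cohorts.setdefault(row["dose"].strip(), []).append(screen_row)
    return [CohortScreen(dose_label=dose, rows=rows) for dose, rows in cohorts.items()]


def write_screen_table(cohorts: Iterable[CohortScreen], path: str | Path,
                       *, delimiter: str = "\t") -> None:
    """Write cohorts back to the delimited layout `read_screen_table` accepts.

    Numbers are emitted without thousands separators (those are accepted on
    input only).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(SCREEN_COLUMNS)
        for cohort in cohorts:
            for row in cohort.rows:
                writer.writerow([
                    row.amplicon.gene_name,
                    f"{row.amplicon.amplicon_length_kb:g}",
                    row.families_screened,
                    row.mutation_count,
                    cohort.dose_label,
                ])


# ---------------------------------------------------------------------------
# Amplicon annotation I/O


def read_amplicon_annotations(seq_path: str | Path,
                              interval_path: str | Path | None = None) -> list[AmpliconTarget]:
    """Read amplicon FASTA plus an optional CDS interval table.

    The interval file is a BED-like TSV with columns ``name  start  end
    [frame_offset]``; coordinates are 1-based inclusive (declared in the file's
    header comment). ``frame_offset`` is read from the first segment of each
    amplicon. Records without interval lines get no CDS annotation, so
    downstream effect annotation reports region "unknown".
    """
    records = {}
    for rec in SeqIO.parse(str(seq_path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate record name {rec.id!r} in {seq_path}")
        records[rec.id] = str(rec.seq).upper()

    intervals: dict[str, list[tuple[int, int]]] = {}
    offsets: dict[str, int] = {}
    if interval_path is not None:
        with Path(interval_path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"interval line needs name/start/end: {line!r}")
                name = parts[0]
                start, end = parse_int(parts[1]), parse_int(parts[2])
                if name not in records:
                    raise FormatError(f"interval names unknown record {name!r}")
                if start > end:
                    raise BoundsError(f"interval ({start}, {end}) has start > end")
                if end > len(records[name]):
                    raise BoundsError(
                        f"{name}: interval end {end} beyond sequence end {len(records[name])}")
                if name not in intervals and len(parts) >= 4:
                    offsets[name] = parse_int(parts[3])
                intervals.setdefault(name, []).append((start, end))

    targets = []
    for name, seq in records.items():
        cds = None
        if name in intervals:
            segs = tuple(sorted(intervals[name]))
            cds = CdsAnnotation(segments=segs, frame_offset=offsets.get(name, 0))
        targets.append(AmpliconTarget(
            gene_name=name,
            amplicon_length_kb=round_half_away(len(seq) / 1000.0, 4),
            reference_sequence=seq,
            cds=cds,
        ))
    return targets


# ---------------------------------------------------------------------------
# Mutation record I/O (minimal sites-only VCF)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=tillkit
##INFO=<ID=REGION,Number=1,Type=String,Description="Amplicon region: coding, noncoding or unknown">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect: silent, missense, nonsense or stop-loss">
##INFO=<ID=FAMILY,Number=1,Type=String,Description="M3 family in which the mutation was detected">
"""


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write mutation records as a minimal sites-only VCF.

    The amplicon name stands in for the reference name; REGION, EFFECT and
    FAMILY travel as INFO tags. An empty record list yields a header-only file.
    """
    path = Path(path)
    contigs = sorted({r.gene_name for r in records})
    lines = [_VCF_HEADER]
    lines += [f"##contig=<ID={c}>\n" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for r in records:
        info = [f"REGION={r.region}", f"FAMILY={r.family_id}"]
        if r.effect is not None:
            info.insert(1, f"EFFECT={r.effect}")
        lines.append(
            f"{r.gene_name}\t{r.position}\t.\t{r.ref_base}\t{r.alt_base}\t.\t.\t{';'.join(info)}\n"
        )
    path.write_text("".join(lines))


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read mutation records from a VCF written by :func:`write_mutations`."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            out.append(MutationRecord(
                gene_name=rec.chrom,
                family_id=str(info.get("FAMILY", "")),
                position=rec.pos,
                ref_base=rec.ref,
                alt_base=rec.alts[0],
                region=str(info.get("REGION", "unknown")),
                effect=str(info["EFFECT"]) if "EFFECT" in info else None,
            ))
    return out


# ---------------------------------------------------------------------------
# Ledger


def read_population_ledger(path: str | Path, *, delimiter: str = "\t") -> PopulationLedger:
    """Read a per-dose population ledger TSV (thousands separators tolerated)."""
    doses = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = ("dose", "seeds_treated", "m1_transplanted", "m2_families", "m3_families")
        for col in required:
            if col not in (reader.fieldnames or []):
                raise FormatError(f"ledger is missing column {col!r}")
        for row in reader:
            doses[row["dose"].strip()] = DoseCounts(
                seeds_treated=parse_int(row["seeds_treated"]),
                m1_transplanted=parse_int(row["m1_transplanted"]),
                m2_families=parse_int(row["m2_families"]),
                m3_families=parse_int(row["m3_families"]),
            )
    return PopulationLedger(doses=doses)


def ledger_summary(ledger: PopulationLedger) -> pd.DataFrame:
    """Per-dose and total population counts with M3 seed-set failure rates.

    The failure count is the number of M2 families that produced no M3 seed
    stock (m2 - m3); the rate is that count over the M2 families, as a percent
    rounded to one decimal. The last row ("Total") sums all doses.
    """
    rows = []
    for dose, c in ledger.doses.items():
        fail = c.m2_families - c.m3_families
        rate = round_half_away(100.0 * fail / c.m2_families, 1) if c.m2_families else 0.0
        rows.append({
            "dose": dose,
            "seeds_treated": c.seeds_treated,
            "m1_transplanted": c.m1_transplanted,
            "m2_families": c.m2_families,
            "m3_families": c.m3_families,
            "m3_failures": fail,
            "m3_failure_rate_pct": rate,
        })
    total = {k: sum(r[k] for r in rows) for k in
             ("seeds_treated", "m1_transplanted", "m2_families", "m3_families", "m3_failures")}
    total["dose"] = "Total"
    total["m3_failure_rate_pct"] = (
        round_half_away(100.0 * total["m3_failures"] / total["m2_families"], 1)
        if total["m2_families"] else 0.0
    )
    rows.append(total)
    return pd.DataFrame(rows)


def _with_mutations(row: ScreenRow, mutations: Sequence[MutationRecord]) -> ScreenRow:
    return replace(row, mutations=tuple(mutations), mutation_count=len(mutations))
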