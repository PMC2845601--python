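"""Mutation-density estimation for pooled TILLING screens.

Density is reported the way screen papers print it: kilobases screened per
discovered mutation ("1 mutation / X kb"); a small X means a dense population.
For an amplicon of length L kb screened over N M3 families with m mutations,
the per-amplicon reciprocal density is L*N/m, uncorrected.

The population average applies a Mendelian correction: each M3 family derives
from a single selfed M2 plant, so for any induced variant one quarter of
families descend from a homozygous wild-type parent and cannot reveal it. The
observed mutation count therefore underestimates the induced load by a factor
3/4, and the screened kilobases are scaled by 0.75 before dividing by the
total mutation count:

    density = 0.75 * sum_i(L_i * N_i) / sum_i(m_i)

Amplicons with zero mutations still contribute their screened kilobases to
the numerator. The correction applies at the population level only — the
per-amplicon values are conventionally reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._util import round_half_away
from .errors import TillkitError
from .screen_data import CohortScreen

#: Fraction of M3 families able to reveal an induced variant under 1:2:1
#: segregation of the M2 parent (1 - 1/4 homozygous wild type).
MENDELIAN_CORRECTION = 0.75


def amplicon_density(length_kb: float, families: int, mutations: int) -> float | None:
    """Reciprocal mutation density of one amplicon, in kb per mutation.

    Returns ``length_kb * families / mutations``, or ``None`` when no mutation
    was found (screen tables print "-" for that cell). No Mendelian correction
    is applied at this level.
    """
    if length_kb <= 0:
        raise TillkitError(f"amplicon length must be positive, got {length_kb}")
    if families < 0 or mutations < 0:
        raise TillkitError("families and mutations must be non-negative")
    if mutations == 0:
        return None
    return length_kb * families / mutations


def population_density(cohort: CohortScreen,
                       correction: float = MENDELIAN_CORRECTION) -> float | None:
    """Corrected population-average reciprocal density for one dose, kb/mutation.

    Sums screened kilobases (L_i * N_i) over all amplicons — including those
    with zero mutations — scales by ``correction`` and divides by the total
    mutation count. Returns ``None`` when the cohort found no mutations at all.
    """
    if not cohort.rows:
        raise TillkitError(f"cohort {cohort.dose_label!r} has no rows")
    if not 0 < correction <= 1:
        raise TillkitError(f"correction must be in (0, 1], got {correction}")
    screened_kb = sum(r.amplicon.amplicon_length_kb * r.families_screened for r in cohort.rows)
    total_m = cohort.total_mutations
    if total_m == 0:
        return None
    return correction * screened_kb / total_m


def population_density_interval(cohort: CohortScreen,
                                correction: float = MENDELIAN_CORRECTION,
                                level: float = 0.95) -> tuple[float, float] | None:
    """Exact Poisson interval on the corrected reciprocal density (extension).

    Treats the total mutation count as Poisson and inverts the standard exact
    (Garwood) interval on the count into an interval on kb-per-mutation. The
    source screens report point estimates only; this interval is an extra the
    toolkit provides, flagged as such in report metadata.
    """
    m = cohort.total_mutations
    if m == 0:
        return None
    screened_kb = sum(r.amplicon.amplicon_length_kb * r.families_screened for r in cohort.rows)
    alpha = 1.0 - level
    lo_count = stats.chi2.ppf(alpha / 2, 2 * m) / 2.0
    hi_count = stats.chi2.ppf(1 - alpha / 2, 2 * (m + 1)) / 2.0
    # more mutations -> denser -> smaller kb/mutation
    return (correction * screened_kb / hi_count, correction * screened_kb / lo_count)


def fold_difference(density_a: float | None, density_b: float | None) -> float | None:
    """Fold difference in per-genome mutation load between two densities.

    Densities are reciprocal (kb per mutation), so with the sparser population
    first (larger kb/mutation) the ratio a/b reads as "b carries a/b-fold more
    mutations per genome than a". Undefined inputs propagate as ``None``.
    """
    if density_a is None or density_b is None:
        return None
    if density_a <= 0 or density_b <= 0:
        raise TillkitError("densities must be positive")
    return density_a / density_b


def render_density(density_kb: float | None) -> str:
    """Render a reciprocal density as '1/X kb', '-' when undefined.

    X is rounded half away from zero to integer kilobases.
    """
    if density_kb is None:
        return "-"
    return f"1/{int(round_half_away(density_kb))} kb"


@dataclass
class DensityReport:
    """Tabular density report: per-amplicon rows plus per-dose totals."""

    rows: pd.DataFrame
    totals: pd.DataFrame
    correction: float

    @property
    def grand_total_mutations(self) -> int:
        return int(self.totals["mutations"].sum())


def density_report(cohorts: list[CohortScreen],
                   correction: float = MENDELIAN_CORRECTION) -> DensityReport:
    """Build a screen-table-shaped density report over one or more cohorts.

    Per-amplicon rows keep input order and carry the uncorrected reciprocal
    density; each dose's totals row carries the summed amplicon sizes, the
    summed screened kilobases and mutation count, and the corrected
    population-average density.
    """
    row_records = []
    total_records = []
    for cohort in cohorts:
        for r in cohort.rows:
            d = amplicon_density(r.amplicon.amplicon_length_kb, r.families_screened,
                                 r.mutation_count)
            row_records.append({
                "gene": r.amplicon.gene_name,
                "dose": cohort.dose_label,
                "amplicon_kb": r.amplicon.amplicon_length_kb,
                "families_screened": r.families_screened,
                "screened_kb": r.amplicon.amplicon_length_kb * r.families_screened,
                "mutations": r.mutation_count,
                "density_kb_per_mutation": d,
                "density": render_density(d),
            })
        pop = population_density(cohort, correction)
        interval = population_density_interval(cohort, correction)
        total_records.append({
            "dose": cohort.dose_label,
            "total_amplicon_kb": round_half_away(
                sum(r.amplicon.amplicon_length_kb for r in cohort.rows), 3),
            "total_screened_kb": sum(
                r.amplicon.amplicon_length_kb * r.families_screened for r in cohort.rows),
            "mutations": cohort.total_mutations,
            "corrected_density_kb_per_mutation": pop,
            "corrected_density": render_density(pop),
            "poisson95_low_kb": None if interval is None else interval[0],
            "poisson95_high_kb": None if interval is None else interval[1],
        })
    return DensityReport(rows=pd.DataFrame(row_records),
                         totals=pd.DataFrame(total_records),
                         correction=correction)
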