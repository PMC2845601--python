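import pytest

from tillkit import AmpliconTarget, CdsAnnotation
from tillkit.datasets import red_setter_screen


@pytest.fixture(scope="session")
def cohorts():
    """The packaged seven-gene Red Setter screen, both EMS doses."""
    return red_setter_screen()


@pytest.fixture(scope="session")
def cohort_by_dose(cohorts):
    return {c.dose_label: c for c in cohorts}


@pytest.fixture()
def splice_amplicon():
    """30 bp toy amplicon whose third CDS codon spans a segment junction.

    Spliced CDS = ATGGCTA + CGTTAGGCT = ATG GCT ACG TTA GGC T; the codon ACG
    draws its first base from segment 1 and the rest from segment 2.
    """
    seq = "AAA" + "ATGGCTA" + "AAAAA" + "CGTTAGGCT" + "AAAAAA"
    return AmpliconTarget(
        gene_name="toy",
        amplicon_length_kb=0.03,
        reference_sequence=seq,
        cds=CdsAnnotation(segments=((4, 10), (16, 24)), frame_offset=0),
    )
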