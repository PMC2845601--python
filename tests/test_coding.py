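"""Coding-effect annotation: codon classification and amplicon-level annotation."""

import itertools

import numpy as np
import pytest

from tillkit import (AmpliconTarget, CdsAnnotation, MutationRecord, SimulationParams,
                     annotate_all, annotate_mutation, codon_effect, effect_summary,
                     simulate_screen)
from tillkit.errors import BoundsError, ConsistencyError, TillkitError

# Independent statement of the standard nuclear genetic code (TCAG order),
# kept separate from the implementation's translation machinery.
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {b1 + b2 + b3: _AA[16 * i + 4 * j + k]
               for i, b1 in enumerate(_BASES)
               for j, b2 in enumerate(_BASES)
               for k, b3 in enumerate(_BASES)}


def oracle_effect(ref_codon, alt_codon):
    ref_aa, alt_aa = ORACLE_CODE[ref_codon], ORACLE_CODE[alt_codon]
    if ref_aa == alt_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop-loss"
    return "missense"


class TestCodonEffect:
    def test_exhaustive_single_base_neighbors_match_translation_oracle(self):
        """All 64 x 9 single-base codon changes agree with the independent code."""
        checked = 0
        for ref in map("".join, itertools.product("ACGT", repeat=3)):
            for pos in range(3):
                for base in "ACGT":
                    if base == ref[pos]:
                        continue
                    alt = ref[:pos] + base + ref[pos + 1:]
                    assert codon_effect(ref, alt) == oracle_effect(ref, alt), (ref, alt)
                    checked += 1
        assert checked == 64 * 9

    def test_examples(self):
        assert codon_effect("GAA", "GAG") == "silent"      # both Glu
        assert codon_effect("TGG", "TGA") == "nonsense"    # Trp -> stop
        assert codon_effect("TGA", "TGG") == "stop-loss"
        assert codon_effect("GAC", "GCC") == "missense"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(TillkitError):
            codon_effect("GAA", "GAA")
        with pytest.raises(TillkitError):
            codon_effect("GAA", "CTT")
        with pytest.raises(TillkitError):
            codon_effect("GAN", "GAA")


class TestAnnotateMutation:
    def test_intron_position_is_noncoding(self, splice_amplicon):
        rec = MutationRecord("toy", "F1", 12, "A", "T")
        assert annotate_mutation(rec, splice_amplicon).region == "noncoding"

    def test_third_position_synonymous_change(self):
        # CDS = GAC GTT: third-position C>T keeps Asp
        amp = AmpliconTarget("m", 0.006, "GACGTT",
                             cds=CdsAnnotation(segments=((1, 6),)))
        out = annotate_mutation(MutationRecord("m", "F1", 3, "C", "T"), amp)
        assert (out.region, out.effect) == ("coding", "silent")

    def test_codon_spanning_segment_junction(self, splice_amplicon):
        # spliced CDS codon 3 is ACG (Thr): A from segment 1, CG from segment 2.
        out = annotate_mutation(MutationRecord("toy", "F1", 16, "C", "A"),
                                splice_amplicon)
        assert (out.region, out.effect) == ("coding", "missense")  # ACG->AAG Thr->Lys
        # position 10, the last base of segment 1, is the same codon's first base
        out2 = annotate_mutation(MutationRecord("toy", "F1", 10, "A", "G"),
                                 splice_amplicon)
        assert (out2.region, out2.effect) == ("coding", oracle_effect("ACG", "GCG"))

    def test_frame_offset_shifts_codon_phase(self):
        # CDS bases: [offset junk 2] + ATG GAT; frame_offset=2
        amp = AmpliconTarget("f", 0.008, "CCATGGAT",
                             cds=CdsAnnotation(segments=((1, 8),), frame_offset=2))
        out = annotate_mutation(MutationRecord("f", "F1", 8, "T", "C"), amp)
        assert out.effect == "silent"  # GAT->GAC both Asp
        # a hit inside the truncated leading codon has no determinate effect
        lead = annotate_mutation(MutationRecord("f", "F1", 1, "C", "T"), amp)
        assert (lead.region, lead.effect) == ("coding", None)

    def test_no_cds_annotation_gives_unknown_region(self):
        amp = AmpliconTarget("u", 0.004, "ACGT")
        out = annotate_mutation(MutationRecord("u", "F1", 2, "C", "A"), amp)
        assert (out.region, out.effect) == ("unknown", None)

    def test_reference_mismatch_is_a_consistency_error(self, splice_amplicon):
        with pytest.raises(ConsistencyError, match="16"):
            annotate_mutation(MutationRecord("toy", "F1", 16, "G", "A"), splice_amplicon)

    def test_out_of_bounds_position(self, splice_amplicon):
        with pytest.raises(BoundsError):
            annotate_mutation(MutationRecord("toy", "F1", 99, "A", "T"), splice_amplicon)

    def test_annotation_is_idempotent(self, splice_amplicon):
        rec = MutationRecord("toy", "F1", 16, "C", "A")
        once = annotate_mutation(rec, splice_amplicon)
        assert annotate_mutation(once, splice_amplicon) == once


class TestEffectSummary:
    def test_silent_missense_split(self):
        recs = ([MutationRecord("g", "f", i + 1, "C", "T", region="coding",
                                effect="silent") for i in range(3)]
                + [MutationRecord("g", "f", i + 10, "G", "A", region="coding",
                                  effect="missense") for i in range(5)])
        s = effect_summary(recs)
        assert s.effect_percentages["silent"] == 37.5
        assert s.effect_percentages["missense"] == 62.5
        assert s.coding_total == 8

    def test_noncoding_records_excluded_from_percentage_base(self):
        recs = [MutationRecord("g", "f", 1, "C", "T", region="noncoding"),
                MutationRecord("g", "f", 2, "G", "A", region="coding", effect="silent")]
        s = effect_summary(recs)
        assert s.noncoding == 1
        assert s.effect_percentages["silent"] == 100.0

    def test_all_noncoding_has_undefined_percentages(self):
        recs = [MutationRecord("g", "f", 1, "C", "T", region="noncoding")]
        s = effect_summary(recs)
        assert s.coding_total == 0
        assert all(v is None for v in s.effect_percentages.values())

    def test_simulated_cohort_silent_fraction_matches_site_enumeration(self):
        """GC/AT mutations simulated on a fully-coding amplicon hit silent codon
        positions at the rate exhaustive site enumeration predicts."""
        rng = np.random.default_rng(2024)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        amp = AmpliconTarget("sim", 0.3, seq, cds=CdsAnnotation(segments=((1, 300),)))
        # enumeration oracle: silent fraction over all G/C sites
        gc_sites = [i for i, b in enumerate(seq) if b in "GC"]
        silent_sites = 0
        for i in gc_sites:
            codon_start = 3 * (i // 3)
            ref_codon = seq[codon_start:codon_start + 3]
            alt = {"G": "A", "C": "T"}[seq[i]]
            alt_codon = ref_codon[:i - codon_start] + alt + ref_codon[i - codon_start + 1:]
            if oracle_effect(ref_codon, alt_codon) == "silent":
                silent_sites += 1
        expected = silent_sites / len(gc_sites)

        probs = {"GC/AT": 1.0, "GC/TA": 0.0, "AT/TA": 0.0,
                 "AT/GC": 0.0, "AT/CG": 0.0, "GC/CG": 0.0}
        params = SimulationParams(rate_per_kb=10.0, amplicons=[amp], families=1000,
                                  spectrum_probs=probs, seed=5)
        cohort = simulate_screen(params)
        annotated = annotate_all([m for r in cohort.rows for m in r.mutations], [amp])
        s = effect_summary(annotated)
        n = s.coding_total
        observed = s.effect_counts["silent"] / n
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(observed - expected) < 4 * se
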