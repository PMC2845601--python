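# Methods

## Mutation-density estimation

A TILLING screen observes, per amplicon of length *L* kb, the number of induced
mutations *m* found across *N* screened M3 families. The per-amplicon
reciprocal density is `L·N/m` kb per mutation, reported raw ("1/X kb", X
rounded half away from zero to integer kb; an amplicon with no mutation is
printed "-"). The population average for one dose is

```
D = c · Σᵢ(Lᵢ·Nᵢ) / Σᵢ mᵢ ,   c = 0.75 by default
```

Zero-mutation amplicons contribute their screened kilobases to the numerator.
The correction `c` reflects M2→M3 sampling: each M3 family descends from one
selfed M2 plant, and for any given induced variant the parent is homozygous
wild type with probability 1/4 under 1:2:1 segregation, so only 3/4 of families
can reveal the variant. The factor is applied at the population level only;
per-amplicon cells are conventionally reported uncorrected, and both choices
together reproduce all thirteen defined per-gene cells of the Red Setter screen
table exactly. `c` is exposed as a parameter so the simulator can contrast the
corrected (c = 0.75) and uncorrected (c = 1) estimators.

**Known discrepancy.** Recomputing the corrected dose averages from the printed
inputs (amplicon kb to 3 decimals, family counts, mutation counts) gives
1/592 kb (0.7% EMS) and 1/327 kb (1% EMS), while the original report prints
1/574 and 1/322 kb — a ~3% gap. The exact inputs behind the printed averages
(unrounded amplicon lengths, possibly different family denominators) are not
published. The package reproduces the per-gene cells exactly and reports the
recomputed averages; it does not tune toward the printed overall values.

**Interval extension.** `population_density_interval` supplies an exact
(Garwood) Poisson 95% interval on the corrected density, treating the total
mutation count as Poisson. The original screens report point estimates only;
artifacts flag the interval as an extension.

## Substitution spectrum

The twelve ordered single-base substitutions collapse by strand symmetry into
six base-pair-change classes: GC/AT, GC/TA, AT/TA, AT/GC, AT/CG, GC/CG.
Percentages are rounded to one decimal, half away from zero. Two transition
definitions are supported in summaries: *chemical* (GC/AT and AT/GC are
transitions — the default, since A→G is a purine→purine change by definition)
and *reporting* (only GC/AT counted as the transition row, matching the layout
convention of some screen tables). The six-class table itself is identical
under both. Packaged comparison columns (barley, rice reverse-TILLING spectra,
percent per class) can be appended verbatim.

## Coding effects

CDS intervals are 1-based inclusive on the amplicon's forward strand, with a
frame offset giving the number of leading spliced-CDS bases that belong to an
upstream truncated codon. Codons are located in the spliced CDS (they may span
segment junctions) and translated with the standard nuclear code; labels are
silent / missense / nonsense / stop-loss (stop-loss is included for
completeness of the enumeration even where screens observe none). Variants in
a codon truncated by the amplicon boundary are coding but effect-undetermined
and are excluded from the percentage base, as are noncoding variants —
silent/missense splits are quoted "among exonic mutations" with determinate
codons. Genes on the reverse strand must be supplied as reverse-complemented
amplicons; intronic positions are plain "noncoding" (no splice-site model).

## Forward screen simulator

The generator mirrors the estimator's assumptions and defines the default
study conditions:

- **Induction.** Per family and amplicon, induced variant counts are Poisson
  with mean `rate_per_kb × L` — EMS lesions are sparse and independent at
  screen densities (hundreds of kb per mutation). One germline genome per M1
  plant; chimerism is not modeled.
- **Segregation.** Each variant survives into the sampled M3 family with
  probability 3/4 (M2 parent not homozygous wild type), the exact assumption
  the 0.75 correction encodes.
- **Detection.** `detection_prob` defaults to 1.0: mismatch-cleavage detection
  in eightfold pools is treated as perfect, since published screens do not
  quantify pool sensitivity; the assumption is recorded in artifact metadata.
  `het_detection_prob` optionally lowers detection for variants from
  heterozygous parents (mutant:wild-type allele ratio 1:15 in an eightfold
  pool of four-plant families); `plants_pooled_per_family` (default 4) and
  `pool_size` (default 8) describe the sampling design and are carried for
  such sensitivity models.
- **Spectrum.** Classes are drawn from a six-class probability vector,
  defaulting to the larger (0.7% EMS) observed cohort spectrum,
  (9,1,3,2,0,0)/15. With a reference sequence present, positions are uniform
  over class-compatible sites (GC classes need a G/C reference base);
  without one, positions are uniform and reference bases synthesized.

`recovery_experiment` simulates replicate screens, applies the population
estimator at corrections 0.75 and 1.0, and reports the mean rate estimate,
bias, Monte-Carlo SE, mean kb-per-mutation and interval coverage (fraction of
replicates whose exact Poisson 95% interval covers the true reciprocal
density). Replicates with zero detected mutations have undefined density and
are excluded, with the exclusion count reported.

**Finite-count expectation.** The mean of kb-per-mutation across replicates is
`c·Σ(L·N)·E[1/m | m>0]`, and `E[1/m] > 1/E[m]` at finite counts (Jensen; about
+3.5% at E[m] ≈ 28, the high-dose configuration). Tests therefore compare
Monte-Carlo means against `expected_reciprocal_density`, which computes the
truncated-Poisson expectation exactly by direct summation, and verify the 4/3
uncorrected-vs-true factor on the rate scale, where the estimator is linear in
the mutation count and exactly unbiased. Parameter-recovery checks use the
seven-amplicon high-dose configuration with 1,284 families (the modal
published family count for that dose; the simulator takes a single family
count per cohort) and 200 replicates — sizes at which a corrected-estimator
bias of one Monte-Carlo SE corresponds to ~1.4% of the true rate.

## Phenotype catalog

The controlled vocabulary — 17 classes, 51 subclasses covering tomato mutant
phenotypes from germination to fruit ripening — ships as packaged JSON
together with the published per-subclass plant counts. Zero-count subclasses
remain in the vocabulary: the vocabulary is the contract, counts are data.
Validation is case-insensitive with collapsed whitespace and suggests nearest
terms on failure; queries are conjunctive over plant / family / class /
subclass; summaries count distinct plants per term, the fraction of plants
with ≥1 trait, and the multi-class fraction among those. Storage is flat CSV
plus in-memory indexing — no database server or web layer.

## Numerical and design choices

- Rounding is half away from zero throughout rendered output (integer kb for
  densities, one decimal for percentages), matching every printed cell it is
  tested against; none of those cells are ties, so the choice is a convention,
  not a fit.
- Thousands separators ("3,885") are accepted in all integer input cells and
  never emitted.
- Screen-table dose labels are opaque text keys; any dose→rate interpretation
  lives in simulation configs, not the data layer.
- A header-only screen table yields zero cohorts (dose labels are data, so no
  cohorts exist without rows).
- Mutation records travel as minimal sites-only VCF with `REGION`, `EFFECT`
  and `FAMILY` INFO tags; reading goes through pysam, writing is plain
  formatted text lines under a declared VCF 4.2 header.
- Reports are emitted as TSV plus a JSON twin with tool version, config hash
  and seed; no timestamps are written, so fixed seed + config gives
  byte-identical artifacts.

## What the simulations do and do not show

Passing parameter recovery demonstrates that the estimator is consistent with
its own generative assumptions (Poisson induction, independent 1:2:1
segregation, known detection). Real screens add features the generator omits:
M1 chimerism and shared M2 ancestry, non-uniform EMS target preference along
amplicons beyond base composition, pool-sensitivity and gel-scoring losses,
and amplicon-specific family attrition. The sensitivity analysis with
`detection_prob < 1` shows how violated detection assumptions bias even the
corrected estimator; it does not calibrate any real assay.
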