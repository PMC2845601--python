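"""Forward simulation of an EMS mutagenesis and pooled TILLING screen.

The generative model mirrors the statistical structure the density estimator
assumes. Each M3 family descends from a single selfed M2 plant carrying one
mutagenized germline genome (no chimerism). Per family and amplicon the
number of induced variants is Poisson with mean rate_per_kb * L — EMS lesions
are sparse and independent at screen densities. Each variant segregates
1:2:1 in the M2 parent, so the sampled M3 family carries it unless the parent
was homozygous wild type (probability 1/4): a variant enters the screened
material with probability 3/4, which is exactly the assumption the 0.75
density correction encodes. Surviving variants are then detected with
``detection_prob`` (mismatch-cleavage detection in 8-fold pools is treated as
perfect by default; the screen literature does not quantify its sensitivity,
and this assumption is recorded in report metadata).

Substitution classes are drawn from a six-class spectrum; when an amplicon
carries a reference sequence, positions are drawn uniformly over the bases
compatible with the drawn class (a GC/AT change needs a G or C reference
base), otherwise positions are uniform and reference bases synthesized to
match the class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import population_density, population_density_interval
from .errors import TillkitError
from .screen_data import AmpliconTarget, CohortScreen, MutationRecord, ScreenRow
from .spectrum import CLASSES

#: P(M2 parent is hom-wild-type, heterozygous, hom-mutant) for one variant.
SEGREGATION_1_2_1 = (0.25, 0.5, 0.25)

#: Default six-class spectrum: the 0.7% EMS cohort's observed class
#: frequencies (counts 9,1,3,2,0,0 over 15 classified substitutions).
DEFAULT_SPECTRUM = {
    "GC/AT": 9 / 15, "GC/TA": 1 / 15, "AT/TA": 3 / 15,
    "AT/GC": 2 / 15, "AT/CG": 0.0, "GC/CG": 0.0,
}

# alt base implied by (class, ref base)
_ALT_FOR = {
    ("GC/AT", "G"): "A", ("GC/AT", "C"): "T",
    ("GC/TA", "G"): "T", ("GC/TA", "C"): "A",
    ("GC/CG", "G"): "C", ("GC/CG", "C"): "G",
    ("AT/TA", "A"): "T", ("AT/TA", "T"): "A",
    ("AT/GC", "A"): "G", ("AT/GC", "T"): "C",
    ("AT/CG", "A"): "C", ("AT/CG", "T"): "G",
}


def _ref_bases_for(cls: str) -> str:
    return "GC" if cls.startswith("GC") else "AT"


@dataclass
class SimulationParams:
    """Parameters of one simulated dose cohort.

    rate_per_kb is the expected number of induced variants per kilobase per
    mutagenized genome (the quantity the density estimator inverts:
    1/rate_per_kb is the true kb-per-mutation). ``plants_pooled_per_family``
    and ``pool_size`` describe the DNA sampling design (four plants per M3
    family, families pooled eightfold); under the default perfect detection
    they do not change detection odds but are carried for sensitivity models
    such as ``het_detection_prob``, which, when set, applies to variants whose
    M2 parent was heterozygous (mutant:wild-type allele ratio 1:15 in an
    eightfold pool) while homozygous ones use ``detection_prob``.
    """

    rate_per_kb: float
    amplicons: list[AmpliconTarget]
    families: int
    spectrum_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    plants_pooled_per_family: int = 4
    pool_size: int = 8
    detection_prob: float = 1.0
    het_detection_prob: float | None = None
    segregation_probs: tuple[float, float, float] = SEGREGATION_1_2_1
    dose_label: str = "simulated"
    seed: int | None = None

    def __post_init__(self):
        if self.rate_per_kb < 0:
            raise TillkitError("rate_per_kb must be non-negative")
        if not self.amplicons:
            raise TillkitError("at least one amplicon is required")
        if self.families <= 0 or self.plants_pooled_per_family <= 0 or self.pool_size <= 0:
            raise TillkitError("counts must be positive")
        if set(self.spectrum_probs) != set(CLASSES):
            raise TillkitError(f"spectrum_probs must cover exactly the classes {CLASSES}")
        total = sum(self.spectrum_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise TillkitError(f"spectrum_probs must sum to 1, got {total}")
        for p in (self.detection_prob, *self.segregation_probs,
                  *([self.het_detection_prob] if self.het_detection_prob is not None else [])):
            if not 0.0 <= p <= 1.0:
                raise TillkitError(f"probability {p} outside [0, 1]")
        if abs(sum(self.segregation_probs) - 1.0) > 1e-9:
            raise TillkitError("segregation_probs must sum to 1")


def simulate_screen(params: SimulationParams,
                    rng: np.random.Generator | None = None) -> CohortScreen:
    """Simulate one screened cohort, returning rows with full mutation lists.

    Reproducible: the same params (including seed) give an identical cohort.
    Pass an external ``rng`` to chain replicates off one stream.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    probs = np.array([params.spectrum_probs[c] for c in CLASSES])
    p_wt = params.segregation_probs[0]
    rows = []
    for amp in params.amplicons:
        counts = rng.poisson(params.rate_per_kb * amp.amplicon_length_kb,
                             size=params.families)
        n = int(counts.sum())
        family_of = np.repeat(np.arange(params.families), counts)
        u = rng.random(n)
        present = u >= p_wt
        het = (u >= p_wt) & (u < p_wt + params.segregation_probs[1])
        if params.het_detection_prob is None:
            p_det = np.full(n, params.detection_prob)
        else:
            p_det = np.where(het, params.het_detection_prob, params.detection_prob)
        detected = present & (rng.random(n) < p_det)
        cls_idx = rng.choice(len(CLASSES), size=n, p=probs)

        muts = []
        for j in np.nonzero(detected)[0]:
            cls = CLASSES[cls_idx[j]]
            ref_ok = _ref_bases_for(cls)
            if amp.reference_sequence is not None:
                sites = [i for i, b in enumerate(amp.reference_sequence) if b in ref_ok]
                if not sites:
                    continue  # no compatible site on this amplicon
                pos = sites[rng.integers(len(sites))] + 1
                ref = amp.reference_sequence[pos - 1]
            else:
                pos = int(rng.integers(amp.length_bp)) + 1
                ref = ref_ok[rng.integers(2)]
            muts.append(MutationRecord(
                gene_name=amp.gene_name,
                family_id=f"F{family_of[j]:05d}",
                position=pos,
                ref_base=ref,
                alt_base=_ALT_FOR[(cls, ref)],
            ))
        rows.append(ScreenRow(amplicon=amp, families_screened=params.families,
                              mutation_count=len(muts), mutations=tuple(muts)))
    return CohortScreen(dose_label=params.dose_label, rows=rows)


def expected_detected_count(params: SimulationParams) -> float:
    """Mean total detected mutations per simulated cohort (closed form).

    Each induced variant is carried by the sampled M3 family with probability
    P(het) + P(hom mutant) and detected with the zygosity-appropriate
    probability, so the detected total is Poisson with mean
    rate * sum_i(L_i) * families * (p_het*d_het + p_hom*d_hom).
    """
    p_het, p_hom = params.segregation_probs[1], params.segregation_probs[2]
    d_het = (params.het_detection_prob if params.het_detection_prob is not None
             else params.detection_prob)
    thinning = p_het * d_het + p_hom * params.detection_prob
    total_kb = sum(a.amplicon_length_kb for a in params.amplicons)
    return params.rate_per_kb * total_kb * params.families * thinning


def expected_reciprocal_density(params: SimulationParams,
                                correction: float = 0.75) -> float:
    """Exact expectation of the estimated kb-per-mutation over replicates.

    The estimate is correction * sum(L*N) / m with m Poisson; replicates with
    m = 0 are excluded, so the relevant moment is E[1/m | m > 0], which
    exceeds 1/E[m] at finite counts (Jensen). Computed by direct summation of
    the truncated Poisson law — this is the oracle parameter-recovery tests
    compare Monte-Carlo means against.
    """
    mu = expected_detected_count(params)
    if mu <= 0:
        raise TillkitError("expected count is zero; no density is estimable")
    upper = int(mu + 20 * np.sqrt(mu)) + 20
    m = np.arange(1, upper)
    logpmf = m * np.log(mu) - mu - np.array([np.sum(np.log(np.arange(1, k + 1))) for k in m])
    pmf = np.exp(logpmf)
    e_inv_m = float((pmf / m).sum() / pmf.sum())
    screened_kb = params.families * sum(a.amplicon_length_kb for a in params.amplicons)
    return correction * screened_kb * e_inv_m


@dataclass
class EstimatorStats:
    """Monte-Carlo summary for one correction setting."""

    correction: float
    mean_rate_per_kb: float
    bias: float
    mc_se: float
    mean_kb_per_mutation: float
    mc_se_kb_per_mutation: float
    coverage: float  # fraction of replicates whose exact Poisson 95% interval
    #                  on the reciprocal density covers the true 1/rate


@dataclass
class RecoveryReport:
    """Parameter-recovery experiment result across replicates."""

    true_rate_per_kb: float
    replicates: int
    excluded_zero_mutation: int
    estimators: dict[str, EstimatorStats]

    def as_dict(self) -> dict:
        return {
            "true_rate_per_kb": self.true_rate_per_kb,
            "replicates": self.replicates,
            "excluded_zero_mutation": self.excluded_zero_mutation,
            "estimators": {k: vars(v) for k, v in self.estimators.items()},
        }


def recovery_experiment(params: SimulationParams, replicates: int,
                        corrections: tuple[float, ...] = (0.75, 1.0)) -> RecoveryReport:
    """Check that the corrected density estimator recovers the true rate.

    Runs ``simulate_screen`` per replicate, applies the population density
    estimator at each correction, inverts kb-per-mutation into a rate, and
    reports mean, bias and Monte-Carlo standard error of the rate estimate
    plus interval coverage. Replicates in which no mutation was detected
    yield an undefined density and are excluded (their count is reported).
    """
    if replicates < 2:
        raise TillkitError("need at least 2 replicates")
    rng = np.random.default_rng(params.seed)
    per_corr: dict[float, list[float]] = {c: [] for c in corrections}
    cover: dict[float, int] = {c: 0 for c in corrections}
    excluded = 0
    true_recip = 1.0 / params.rate_per_kb
    for _ in range(replicates):
        cohort = simulate_screen(params, rng=rng)
        if cohort.total_mutations == 0:
            excluded += 1
            continue
        for c in corrections:
            d = population_density(cohort, correction=c)
            per_corr[c].append(d)
            lo, hi = population_density_interval(cohort, correction=c)
            if lo <= true_recip <= hi:
                cover[c] += 1
    kept = replicates - excluded
    estimators = {}
    for c in corrections:
        recips = np.array(per_corr[c])
        rates = 1.0 / recips if recips.size else np.array([])
        mean_rate = float(rates.mean()) if rates.size else float("nan")
        mean_kb = float(recips.mean()) if recips.size else float("nan")
        mc_se = float(rates.std(ddof=1) / np.sqrt(kept)) if kept > 1 else float("nan")
        mc_se_kb = float(recips.std(ddof=1) / np.sqrt(kept)) if kept > 1 else float("nan")
        label = f"corrected_{c:g}" if c != 1.0 else "uncorrected"
        estimators[label] = EstimatorStats(
            correction=c,
            mean_rate_per_kb=mean_rate,
            bias=mean_rate - params.rate_per_kb,
            mc_se=mc_se,
            mean_kb_per_mutation=mean_kb,
            mc_se_kb_per_mutation=mc_se_kb,
            coverage=cover[c] / kept if kept else float("nan"),
        )
    return RecoveryReport(true_rate_per_kb=params.rate_per_kb, replicates=replicates,
                          excluded_zero_mutation=excluded, estimators=estimators)
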