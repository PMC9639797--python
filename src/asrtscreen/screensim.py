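"""Screening simulations: primary-care case finding and PET pre-screening.

Two deterministic expectation analyses:

1. *Primary-care screening* — apply a screening test's sensitivity/specificity
   to an age-structured population with stratum-specific condition prevalence
   and report expected confusion counts, PPV and NPV; compare two tests by
   relative change in detected cases and in false positives.

2. *Trial-enrichment pre-screening* — use a cheap test to select likely
   biomarker-positive candidates before confirmatory PET scanning.  For a
   pre-specified target of N confirmed positives, pre-screening trades extra
   recruitment (factor 1/Sn) for fewer scans (N/PPV instead of N/prevalence).

All quantities are expectations (infinite-population arithmetic); a seeded
binomial-draw mode is available for uncertainty bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreeningTest",
    "PopulationStratum",
    "Population",
    "ScreenOutcome",
    "TestComparison",
    "EnrichmentResult",
    "build_population",
    "screen_outcomes",
    "compare_tests",
    "derive_comparator",
    "pet_enrichment",
    "PRESETS",
    "MMSE_MCI_META",
]


@dataclass(frozen=True)
class ScreeningTest:
    """A binary test summarized by its operating characteristics."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PopulationStratum:
    age_band: str
    weight: float
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class Population:
    n: float
    strata: tuple[PopulationStratum, ...]
    prevalence: float
    expected_cases: float
    cases_by_stratum: tuple[float, ...]


@dataclass(frozen=True)
class ScreenOutcome:
    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def detected(self) -> float:
        return self.tp

    @property
    def false_positives(self) -> float:
        return self.fp


@dataclass(frozen=True)
class TestComparison:
    outcome_a: ScreenOutcome
    outcome_b: ScreenOutcome
    detection_change: float | None
    false_positive_change: float | None
    false_positive_change_absolute: float = 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    target_positive: float
    scans_without_prescreen: float
    scans_with_prescreen: float
    recruited_with_prescreen: float
    prescreen_ppv: float

    @property
    def scan_reduction(self) -> float:
        return 1.0 - self.scans_with_prescreen / self.scans_without_prescreen

    @property
    def recruitment_increase(self) -> float:
        return self.recruited_with_prescreen / self.scans_without_prescreen - 1.0


def build_population(strata, n: float) -> Population:
    """Expected case structure of an age-stratified population of size ``n``.

    Stratum weights must sum to 1 (tolerance 1e-9).
    """
    strata = tuple(strata)
    if not strata:
        raise ValueError("at least one stratum required")
    total_w = sum(s.weight for s in strata)
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"stratum weights must sum to 1, got {total_w}")
    cases = tuple(n * s.weight * s.prevalence for s in strata)
    prevalence = sum(s.weight * s.prevalence for s in strata)
    return Population(
        n=n,
        strata=strata,
        prevalence=prevalence,
        expected_cases=sum(cases),
        cases_by_stratum=cases,
    )


def single_stratum(prevalence: float, n: float, age_band: str = "all") -> Population:
    """Convenience: a homogeneous population at one prevalence."""
    return build_population([PopulationStratum(age_band, 1.0, prevalence)], n)


def screen_outcomes(
    population: Population,
    test: ScreeningTest,
    draw: bool = False,
    rng: np.random.Generator | None = None,
) -> ScreenOutcome:
    """Expected confusion counts of applying ``test`` across all strata.

    Sensitivity and specificity are assumed constant across strata, so the
    pooled counts equal those at the pooled prevalence.  With ``draw=True``
    counts are sampled binomially (for uncertainty bands) instead of taken
    in expectation.
    """
    tp = fp = fn = tn = 0.0
    for s in population.strata:
        n_s = population.n * s.weight
        cases = n_s * s.prevalence
        non_cases = n_s - cases
        if draw:
            if rng is None:
                raise ValueError("draw mode requires an rng")
            tp_s = rng.binomial(int(round(cases)), test.sensitivity)
            tn_s = rng.binomial(int(round(non_cases)), test.specificity)
            tp += tp_s
            fn += int(round(cases)) - tp_s
            tn += tn_s
            fp += int(round(non_cases)) - tn_s
        else:
            tp += cases * test.sensitivity
            fn += cases * (1 - test.sensitivity)
            tn += non_cases * test.specificity
            fp += non_cases * (1 - test.specificity)
    return ScreenOutcome(tp=tp, fp=fp, fn=fn, tn=tn)


def compare_tests(
    test_a: ScreeningTest, test_b: ScreeningTest, population: Population
) -> TestComparison:
    """Relative change in detection and false positives of A versus B.

    Detection change = Sn_A/Sn_B - 1; false-positive change =
    (1-Sp_A)/(1-Sp_B) - 1.  When B makes no false positives the relative
    change is undefined and only the absolute change is reported.
    """
    out_a = screen_outcomes(population, test_a)
    out_b = screen_outcomes(population, test_b)
    det = test_a.sensitivity / test_b.sensitivity - 1 if test_b.sensitivity > 0 else None
    if test_b.specificity < 1.0:
        fp_rel = (1 - test_a.specificity) / (1 - test_b.specificity) - 1
    else:
        fp_rel = None
    return TestComparison(
        outcome_a=out_a,
        outcome_b=out_b,
        detection_change=det,
        false_positive_change=fp_rel,
        false_positive_change_absolute=out_a.fp - out_b.fp,
    )


def derive_comparator(
    base: ScreeningTest,
    detection_change: float,
    false_positive_change: float,
    name: str = "comparator",
) -> ScreeningTest:
    """Build the test implied by relative deltas against ``base``.

    Sn = Sn_base * (1 + detection_change); the false-positive rate (1 - Sp)
    is scaled by (1 + false_positive_change).
    """
    sn = base.sensitivity * (1 + detection_change)
    fpr = (1 - base.specificity) * (1 + false_positive_change)
    return ScreeningTest(name=name, sensitivity=sn, specificity=1 - fpr)


def pet_enrichment(
    prevalence: float, prescreen: ScreeningTest, target_positive: float
) -> EnrichmentResult:
    """Scans and recruitment needed to confirm ``target_positive`` cases by PET.

    Without pre-screening, N/p candidates are scanned.  With pre-screening,
    N/(Sn*p) candidates are recruited, test-positives are scanned, and the
    scan count is N/PPV where PPV = Sn*p / (Sn*p + (1-Sp)(1-p)).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    if prescreen.sensitivity <= 0.0:
        raise ValueError("pre-screen sensitivity must be positive to reach the target")
    sn, sp = prescreen.sensitivity, prescreen.specificity
    ppv = sn * prevalence / (sn * prevalence + (1 - sp) * (1 - prevalence))
    return EnrichmentResult(
        target_positive=target_positive,
        scans_without_prescreen=target_positive / prevalence,
        scans_with_prescreen=target_positive / ppv,
        recruited_with_prescreen=target_positive / (sn * prevalence),
        prescreen_ppv=ppv,
    )


#: Pooled MMSE operating point for MCI detection from meta-analysis.
MMSE_MCI_META = ScreeningTest("MMSE", sensitivity=0.627, specificity=0.633)

#: Prevalence presets used by the shipped scenarios.
PRESETS: dict[str, float] = {
    "mci_65plus": 0.154,          # MCI prevalence, age 65+ aggregate
    "abeta_positive_mci": 0.559,  # amyloid positivity among MCI, age 65-85
    "abeta_positive_cu": 0.249,   # amyloid positivity among CU, age 65-85
}
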