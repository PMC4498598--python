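"""Preset scenario battery: prevalence windows x penetrance models x loci.

The simulation study crosses three archetypal prevalence windows (rare
0.1-1%, common 1-5%, pandemic 10-20%) with four penetrance parameterisations
(multiplicative gamma in {0.3, 0.1}; logistic (alpha, beta) in {(-5, 1),
(-5, 0.5)}) and 1 or 2 unlinked loci, in a population of N = 10,000 haploid
individuals.

The mutation rate is the one free quantity of the generative model that the
study conditions do not pin down directly.  It is calibrated per scenario
(``scripts/calibrate_mutation_rate.py``) so that the median number of
segregating causative mutations per accepted population matches the
scenario's reference median in :data:`REFERENCE_PER_POPULATION_MEDIANS`;
the calibrated rates are frozen in :data:`CALIBRATED_RATES`.  A single rate
shared across scenarios cannot span the reference spectra: the prevalence
window and penetrance jointly determine how much mutational input a
population needs before its prevalence can fall inside the window at all
(a pandemic-prevalence logistic disease needs roughly twenty times the
mutation supply of a rare multiplicative one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coalor.penetrance import PenetranceModel
from coalor.scenario import PREVALENCE_WINDOWS, ScenarioConfig, run_scenario

__all__ = [
    "MODELS",
    "ScenarioOutcome",
    "run_study_scenario",
    "REFERENCE_PER_POPULATION_MEDIANS",
    "CALIBRATED_RATES",
    "study_config",
    "scenario_names",
]

#: The four penetrance parameterisations of the study grid.
MODELS = {
    "mult_0.3": PenetranceModel.multiplicative(0.3),
    "mult_0.1": PenetranceModel.multiplicative(0.1),
    "log_1": PenetranceModel.logistic(-5.0, 1.0),
    "log_0.5": PenetranceModel.logistic(-5.0, 0.5),
}

#: Reference median segregating-mutation counts per accepted population,
#: keyed by (window, model, loci).  These define each scenario's mutation
#: supply and are the calibration anchor for the per-scenario mutation rate.
REFERENCE_PER_POPULATION_MEDIANS = {
    # single locus
    ("rare", "mult_0.3", 1): 3,
    ("rare", "mult_0.1", 1): 5,
    ("rare", "log_1", 1): 6,
    ("rare", "log_0.5", 1): 9,
    ("common", "mult_0.3", 1): 5,
    ("common", "mult_0.1", 1): 9,
    ("common", "log_1", 1): 19,
    ("common", "log_0.5", 1): 41,
    ("pandemic", "mult_0.3", 1): 11,
    ("pandemic", "mult_0.1", 1): 24,
    ("pandemic", "log_1", 1): 37,
    ("pandemic", "log_0.5", 1): 74,
    # two unlinked loci (joint count over both loci)
    ("rare", "mult_0.3", 2): 3,
    ("rare", "mult_0.1", 2): 5,
    ("rare", "log_1", 2): 5,
    ("rare", "log_0.5", 2): 9,
    ("common", "mult_0.3", 2): 5,
    ("common", "mult_0.1", 2): 8,
    ("common", "log_1", 2): 18,
    ("common", "log_0.5", 2): 40,
    ("pandemic", "mult_0.3", 2): 10,
    ("pandemic", "mult_0.1", 2): 22,
    ("pandemic", "log_1", 2): 35,
    ("pandemic", "log_0.5", 2): 72,
}

#: Calibrated mutation rates per unit coalescent branch length, keyed by
#: (window, model, loci); produced by ``scripts/calibrate_mutation_rate.py``
#: (250 accepted datasets per evaluation, seed 20150710; see that script's
#: header for the procedure).
CALIBRATED_RATES = {
    ("rare", "mult_0.3", 1): 0.2216,
    ("rare", "mult_0.1", 1): 0.3601,
    ("rare", "log_1", 1): 0.4251,
    ("rare", "log_0.5", 1): 0.5630,
    ("common", "mult_0.3", 1): 0.3243,
    ("common", "mult_0.1", 1): 0.5467,
    ("common", "log_1", 1): 1.1026,
    ("common", "log_0.5", 1): 2.3405,
    ("pandemic", "mult_0.3", 1): 0.6220,
    ("pandemic", "mult_0.1", 1): 1.3524,
    ("pandemic", "log_1", 1): 2.0246,
    ("pandemic", "log_0.5", 1): 3.9834,
    ("rare", "mult_0.3", 2): 0.1089,
    ("rare", "mult_0.1", 2): 0.1648,
    ("rare", "log_1", 2): 0.1622,
    ("rare", "log_0.5", 2): 0.2779,
    ("common", "mult_0.3", 2): 0.1509,
    ("common", "mult_0.1", 2): 0.2407,
    ("common", "log_1", 2): 0.5223,
    ("common", "log_0.5", 2): 1.1270,
    ("pandemic", "mult_0.3", 2): 0.2827,
    ("pandemic", "mult_0.1", 2): 0.6098,
    ("pandemic", "log_1", 2): 0.9576,
    ("pandemic", "log_0.5", 2): 1.9378,
}


def scenario_names():
    """Keys of the preset grid, ``(window, model, loci)``."""
    return sorted(REFERENCE_PER_POPULATION_MEDIANS)


@dataclass(frozen=True)
class ScenarioOutcome:
    """Summaries of one scenario run of the study battery."""

    key: tuple
    spectrum: "SpectrumSummary"
    or_distribution: "ORDistributionSummary"
    median_or: float
    median_log10_or: float
    attempts_made: int
    acceptance_fraction: float
    n_accepted: int
    #: raw per-dataset statistics (for bootstrap intervals)
    seg_counts: "np.ndarray" = None
    case_means: "np.ndarray" = None
    control_means: "np.ndarray" = None
    #: pooled evaluable odds ratios
    evaluable_ors: "np.ndarray" = None


def run_study_scenario(
    window: str,
    model: str,
    loci: int = 1,
    target_accepted: int = 400,
    seed: int = 0,
    mutation_rate: float | None = None,
) -> ScenarioOutcome:
    """Run one preset scenario end to end and summarise it.

    Rejection-samples ``target_accepted`` populations of N=10,000 with the
    scenario's calibrated mutation rate and returns the mutation-spectrum
    and OR-distribution summaries (accepted datasets themselves are
    discarded to bound memory).
    """
    from coalor import epi  # deferred: avoid an import cycle at module load

    config = study_config(
        window, model, loci, target_accepted=target_accepted, seed=seed,
        mutation_rate=mutation_rate,
    )
    result = run_scenario(config)
    spectrum = epi.summarize_mutation_spectrum(result.datasets)
    records = epi.pooled_records(result.datasets)
    ors = epi.summarize_or_distribution(records)
    med, med_log = epi.median_or(records)
    seg, case_means, control_means = [], [], []
    for ds in result.datasets:
        seg.append(ds.n_segregating)
        k = ds.k_total
        affected = ds.phenotype == 1
        case_means.append(float(k[affected].mean()))
        control_means.append(float(k[~affected].mean()))
    return ScenarioOutcome(
        key=(window, model, loci),
        spectrum=spectrum,
        or_distribution=ors,
        median_or=med,
        median_log10_or=med_log,
        attempts_made=result.attempts_made,
        acceptance_fraction=result.acceptance_fraction,
        n_accepted=len(result.datasets),
        seg_counts=np.asarray(seg),
        case_means=np.asarray(case_means),
        control_means=np.asarray(control_means),
        evaluable_ors=np.array([r.or_value for r in records if r.evaluable]),
    )


def study_config(
    window: str,
    model: str,
    loci: int = 1,
    target_accepted: int = 1000,
    seed: int = 0,
    population_size: int = 10_000,
    mutation_rate: float | None = None,
    max_attempts: int = 2_000_000,
) -> ScenarioConfig:
    """Scenario configuration for one cell of the study grid.

    ``window`` is one of rare/common/pandemic, ``model`` a key of
    :data:`MODELS`.  The calibrated per-scenario mutation rate is used
    unless ``mutation_rate`` overrides it.
    """
    key = (window, model, loci)
    if mutation_rate is None:
        if key not in CALIBRATED_RATES:
            raise KeyError(
                "no calibrated mutation rate for scenario %r; pass "
                "mutation_rate explicitly or run the calibration script" % (key,)
            )
        mutation_rate = CALIBRATED_RATES[key]
    return ScenarioConfig(
        penetrance=MODELS[model],
        population_size=population_size,
        loci=loci,
        mutation_rate=mutation_rate,
        prevalence_window=PREVALENCE_WINDOWS[window],
        target_accepted=target_accepted,
        max_attempts=max_attempts,
        seed=seed,
    )
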