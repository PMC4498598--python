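"""Whole-population scenario engine with prevalence-window rejection sampling.

One *candidate* dataset is produced by simulating ``m`` independent
coalescent genealogies (one per unlinked locus) for a population of ``N``
haploid individuals, placing causative mutations on each tree, summing the
per-individual mutation counts over loci, and drawing disease states from
the penetrance model.  Candidates are accepted only if their population
disease prevalence falls inside a half-open window ``[lo, hi)``; candidates
are redrawn in full (genealogies, mutations and phenotypes) until the target
number of accepted datasets is reached.

Each rejection attempt uses its own random stream derived from
``(seed, attempt_index)``, so attempt ``r`` depends only on the root seed
and ``r`` — results are reproducible and independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from coalor.coalescent import (
    GenealogyTree,
    Mutation,
    sample_mutation_nodes,
    simulate_tree,
)
from coalor.penetrance import PenetranceModel, assign_phenotypes

__all__ = [
    "DEFAULT_MUTATION_RATE",
    "PREVALENCE_WINDOWS",
    "ScenarioConfig",
    "ScenarioError",
    "ScenarioResult",
    "PopulationDataset",
    "simulate_candidate",
    "run_scenario",
]

logger = logging.getLogger(__name__)

#: Fallback mutation rate per unit of coalescent branch length (units of N
#: generations): the value calibrated for the rare-disease
#: multiplicative(gamma=0.3) scenario (median of 3 segregating causative
#: mutations per accepted population of N=10,000).  Study scenarios use the
#: per-scenario rates in :data:`coalor.study.CALIBRATED_RATES`; see
#: ``scripts/calibrate_mutation_rate.py``.
DEFAULT_MUTATION_RATE = 0.2216

#: Archetypal disease prevalence windows (half-open, fractions).
PREVALENCE_WINDOWS = {
    "rare": (0.001, 0.01),
    "common": (0.01, 0.05),
    "pandemic": (0.10, 0.20),
}


class ScenarioError(RuntimeError):
    """Raised when the rejection sampler exhausts its attempt budget."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``mutation_rate`` is shared by all loci unless ``per_locus_rates``
    overrides it with one rate per locus.
    """

    penetrance: PenetranceModel
    population_size: int = 10_000
    loci: int = 1
    mutation_rate: float = DEFAULT_MUTATION_RATE
    per_locus_rates: tuple | None = None
    prevalence_window: tuple = PREVALENCE_WINDOWS["rare"]
    target_accepted: int = 1_000
    max_attempts: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.prevalence_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("prevalence window must satisfy 0 <= lo < hi <= 1")
        if self.population_size < 2:
            raise ValueError("population size must be at least 2")
        if self.loci < 1:
            raise ValueError("need at least one locus")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.per_locus_rates is not None and len(self.per_locus_rates) != self.loci:
            raise ValueError("per_locus_rates must have one entry per locus")
        if self.target_accepted < 1 or self.max_attempts < 1:
            raise ValueError("target_accepted and max_attempts must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def locus_rates(self) -> tuple:
        if self.per_locus_rates is not None:
            return tuple(float(r) for r in self.per_locus_rates)
        return (float(self.mutation_rate),) * self.loci


@dataclass
class PopulationDataset:
    """One simulated population: genealogies, mutations and phenotypes.

    ``counts[i, j]`` is the number of locus-``i`` mutations carried by
    individual ``j`` (leaf ``j`` at every locus); ``phenotype`` is the 0/1
    disease state vector and ``prevalence`` the affected fraction.
    """

    trees: list
    mutations: list
    counts: np.ndarray
    phenotype: np.ndarray
    prevalence: float
    attempt_index: int = 0

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]

    @property
    def n_affected(self) -> int:
        return int(self.phenotype.sum())

    @property
    def k_total(self) -> np.ndarray:
        """Total causative-mutation count per individual, summed over loci."""
        return self.counts.sum(axis=0)

    def all_mutations(self):
        """Iterate over mutations of all loci."""
        for per_locus in self.mutations:
            yield from per_locus

    @property
    def n_segregating(self) -> int:
        """Number of causative mutations present in the population."""
        return sum(len(per_locus) for per_locus in self.mutations)


def _attempt_rng(seed: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, attempt)))


def simulate_candidate(
    config: ScenarioConfig, rng: np.random.Generator, attempt_index: int = 0
) -> PopulationDataset:
    """Simulate one unconditioned candidate dataset.

    Draws ``loci`` fresh genealogies, places mutations on each, sums carrier
    counts per individual across loci and assigns phenotypes from the total.
    """
    n = config.population_size
    rates = config.locus_rates()
    trees: list[GenealogyTree] = []
    mutations: list[list[Mutation]] = []
    counts = np.zeros((config.loci, n), dtype=np.int32)
    for i in range(config.loci):
        tree = simulate_tree(n, rng)
        nodes = sample_mutation_nodes(tree, rates[i], rng)
        trees.append(tree)
        per_locus: list[Mutation] = []
        if nodes.size:
            lo, hi, tour = tree.leaf_intervals()
            k_tour = np.zeros(n, dtype=np.int32)
            for v in nodes:
                v = int(v)
                k_tour[lo[v]:hi[v]] += 1
                size = int(hi[v] - lo[v])
                per_locus.append(
                    Mutation(
                        locus_index=i,
                        branch_child_node=v,
                        carrier_count=size,
                        frequency=size / n,
                    )
                )
            counts[i, tour] = k_tour
        mutations.append(per_locus)
    phenotype = assign_phenotypes(counts.sum(axis=0), config.penetrance, rng)
    return PopulationDataset(
        trees=trees,
        mutations=mutations,
        counts=counts,
        phenotype=phenotype,
        prevalence=float(phenotype.mean()),
        attempt_index=attempt_index,
    )


@dataclass
class ScenarioResult:
    """Accepted datasets plus bookkeeping of the rejection sampler."""

    config: ScenarioConfig
    datasets: list = field(repr=False)
    attempts_made: int = 0

    @property
    def acceptance_fraction(self) -> float:
        return len(self.datasets) / self.attempts_made if self.attempts_made else 0.0

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


def run_scenario(config: ScenarioConfig, log_every: int = 50_000) -> ScenarioResult:
    """Rejection-sample accepted datasets for one scenario.

    Candidates are simulated (fully redrawn each attempt) until
    ``target_accepted`` of them have prevalence inside the window, or until
    ``max_attempts`` is exhausted, in which case a :class:`ScenarioError`
    reporting the acceptance fraction so far is raised.
    """
    lo, hi = config.prevalence_window
    accepted: list[PopulationDataset] = []
    attempts = 0
    while len(accepted) < config.target_accepted:
        if attempts >= config.max_attempts:
            raise ScenarioError(
                "max_attempts=%d exhausted with %d/%d accepted "
                "(acceptance fraction %.3g)"
                % (
                    config.max_attempts,
                    len(accepted),
                    config.target_accepted,
                    len(accepted) / attempts,
                )
            )
        rng = _attempt_rng(config.seed, attempts)
        dataset = simulate_candidate(config, rng, attempt_index=attempts)
        attempts += 1
        if lo <= dataset.prevalence < hi:
            accepted.append(dataset)
        if log_every and attempts % log_every == 0:
            logger.info(
                "scenario %s: %d attempts, %d/%d accepted (%.3g)",
                config.penetrance.label(),
                attempts,
                len(accepted),
                config.target_accepted,
                len(accepted) / attempts,
            )
    return ScenarioResult(config=config, datasets=accepted, attempts_made=attempts)
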