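"""Per-mutation odds ratios and scenario-level epidemiological summaries.

For every causative mutation the population-wide 2x2 table is

    a = affected carriers        b = unaffected carriers
    c = affected non-carriers    d = unaffected non-carriers

and the odds ratio OR = (a*d) / (b*c).  These are true population values,
not estimates: the whole simulated population enters the table.  A mutation
is *evaluable* only if all four cells are positive; mutations present
exclusively in cases or exclusively in controls (and fixed mutations, which
have no non-carriers) have an undefined OR and are flagged rather than
summarised.

Summaries mirror the simulation study's tables: the median (and IQR) of the
per-population segregating-mutation count and of the within-population mean
mutation count per case and per control, and pooled OR-distribution
percentages (share with OR<1, share of large-effect mutations, share with
OR<1 among low-frequency mutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coalor.coalescent import Mutation
from coalor.scenario import PopulationDataset

__all__ = [
    "MutationEpiRecord",
    "mutation_or",
    "dataset_records",
    "pooled_records",
    "SpectrumSummary",
    "ORDistributionSummary",
    "summarize_mutation_spectrum",
    "summarize_or_distribution",
    "median_or",
    "spectrum_table",
    "or_table",
    "log10_or_histogram",
]


@dataclass(frozen=True)
class MutationEpiRecord:
    """2x2 counts, frequency and odds ratio of one causative mutation."""

    locus_index: int
    frequency: float
    a: int
    b: int
    c: int
    d: int
    evaluable: bool
    or_value: float
    log10_or: float

    @classmethod
    def from_counts(cls, locus_index, frequency, a, b, c, d) -> "MutationEpiRecord":
        evaluable = a > 0 and b > 0 and c > 0 and d > 0
        if evaluable:
            or_value = (a * d) / (b * c)
            log10_or = math.log10(or_value)
        else:
            or_value = math.nan
            log10_or = math.nan
        return cls(
            locus_index=int(locus_index),
            frequency=float(frequency),
            a=int(a),
            b=int(b),
            c=int(c),
            d=int(d),
            evaluable=evaluable,
            or_value=or_value,
            log10_or=log10_or,
        )


def _affected_carriers(dataset: PopulationDataset, mutation: Mutation) -> int:
    tree = dataset.trees[mutation.locus_index]
    lo, hi, tour = tree.leaf_intervals()
    v = mutation.branch_child_node
    return int(dataset.phenotype[tour[lo[v]:hi[v]]].sum())


def mutation_or(dataset: PopulationDataset, mutation: Mutation) -> MutationEpiRecord:
    """Population-wide 2x2 table and OR for one mutation of the dataset."""
    n = dataset.n
    total_affected = dataset.n_affected
    a = _affected_carriers(dataset, mutation)
    b = mutation.carrier_count - a
    c = total_affected - a
    d = n - mutation.carrier_count - c
    return MutationEpiRecord.from_counts(
        mutation.locus_index, mutation.frequency, a, b, c, d
    )


def dataset_records(dataset: PopulationDataset) -> list[MutationEpiRecord]:
    """2x2 records for every segregating mutation of one dataset."""
    n = dataset.n
    total_affected = dataset.n_affected
    out: list[MutationEpiRecord] = []
    for locus, per_locus in enumerate(dataset.mutations):
        if not per_locus:
            continue
        tree = dataset.trees[locus]
        lo, hi, tour = tree.leaf_intervals()
        pref = np.concatenate(
            ([0], np.cumsum(dataset.phenotype[tour], dtype=np.int64))
        )
        for mut in per_locus:
            v = mut.branch_child_node
            a = int(pref[hi[v]] - pref[lo[v]])
            b = mut.carrier_count - a
            c = total_affected - a
            d = n - mut.carrier_count - c
            out.append(
                MutationEpiRecord.from_counts(locus, mut.frequency, a, b, c, d)
            )
    return out


def _as_records(datasets) -> list[MutationEpiRecord]:
    """Accept an iterable of datasets or a ready list of records."""
    items = list(datasets)
    if items and isinstance(items[0], MutationEpiRecord):
        return items
    out: list[MutationEpiRecord] = []
    for ds in items:
        out.extend(dataset_records(ds))
    return out


def pooled_records(datasets) -> list[MutationEpiRecord]:
    """Records of all mutations pooled over a collection of datasets."""
    return _as_records(datasets)


@dataclass(frozen=True)
class SpectrumSummary:
    """Median (IQR) of per-population mutation counts and per-case/control means.

    Each field is ``(q25, median, q75)`` over datasets; the per-case and
    per-control entries summarise the *within-dataset mean* number of
    causative mutations carried by an affected (resp. unaffected)
    individual.  All segregating mutations count, evaluable or not.
    """

    per_population: tuple
    per_case: tuple
    per_control: tuple
    n_datasets: int


def _quartiles(values) -> tuple:
    q25, q50, q75 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return (float(q25), float(q50), float(q75))


def summarize_mutation_spectrum(datasets) -> SpectrumSummary:
    """Mutation-spectrum summary across accepted datasets."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    n_seg, per_case, per_control = [], [], []
    for ds in datasets:
        n_seg.append(ds.n_segregating)
        k = ds.k_total
        affected = ds.phenotype == 1
        per_case.append(float(k[affected].mean()) if affected.any() else math.nan)
        per_control.append(
            float(k[~affected].mean()) if (~affected).any() else math.nan
        )
    return SpectrumSummary(
        per_population=_quartiles(n_seg),
        per_case=_quartiles(per_case),
        per_control=_quartiles(per_control),
        n_datasets=len(datasets),
    )


@dataclass(frozen=True)
class ORDistributionSummary:
    """Pooled OR-distribution percentages over evaluable mutations.

    ``pct_or_lt1``: share (percent) of evaluable mutations with OR < 1.
    ``large_effect[t]``: ``(pct_large, pct_lt1_within)`` — share with OR > t
    or OR < 1/t, and, of those, the share with OR < 1.
    ``by_frequency[f]``: share with OR < 1 among evaluable mutations of
    population frequency < f (NaN if none).
    """

    pct_or_lt1: float
    large_effect: dict
    by_frequency: dict
    n_evaluable: int
    n_total: int


def summarize_or_distribution(
    datasets,
    effect_thresholds=(1.5, 2.0),
    freq_thresholds=(0.001, 0.01, 0.05),
    per_dataset_average: bool = False,
) -> ORDistributionSummary:
    """OR-distribution percentages pooled over all accepted datasets.

    With ``per_dataset_average=True`` the percentages are computed within
    each dataset and then averaged across datasets (sensitivity variant);
    the default pools all evaluable mutations into one denominator.
    """
    if per_dataset_average:
        per = [
            summarize_or_distribution(
                dataset_records(ds), effect_thresholds, freq_thresholds
            )
            for ds in datasets
            if any(r.evaluable for r in dataset_records(ds))
        ]
        if not per:
            raise ValueError("no evaluable mutations in any dataset")
        return ORDistributionSummary(
            pct_or_lt1=float(np.mean([s.pct_or_lt1 for s in per])),
            large_effect={
                t: (
                    float(np.mean([s.large_effect[t][0] for s in per])),
                    float(np.nanmean([s.large_effect[t][1] for s in per])),
                )
                for t in effect_thresholds
            },
            by_frequency={
                f: float(np.nanmean([s.by_frequency[f] for s in per]))
                for f in freq_thresholds
            },
            n_evaluable=sum(s.n_evaluable for s in per),
            n_total=sum(s.n_total for s in per),
        )

    records = _as_records(datasets)
    ors = np.array([r.or_value for r in records if r.evaluable])
    freqs = np.array([r.frequency for r in records if r.evaluable])
    if ors.size == 0:
        raise ValueError("no evaluable mutations to summarise")
    pct_lt1 = 100.0 * float(np.mean(ors < 1.0))
    large = {}
    for t in effect_thresholds:
        mask = (ors > t) | (ors < 1.0 / t)
        pct_large = 100.0 * float(np.mean(mask))
        pct_within = (
            100.0 * float(np.mean(ors[mask] < 1.0)) if mask.any() else math.nan
        )
        large[t] = (pct_large, pct_within)
    by_freq = {}
    for f in freq_thresholds:
        mask = freqs < f
        by_freq[f] = (
            100.0 * float(np.mean(ors[mask] < 1.0)) if mask.any() else math.nan
        )
    return ORDistributionSummary(
        pct_or_lt1=pct_lt1,
        large_effect=large,
        by_frequency=by_freq,
        n_evaluable=int(ors.size),
        n_total=len(records),
    )


def median_or(datasets) -> tuple:
    """Median OR and median log10 OR over pooled evaluable mutations."""
    records = _as_records(datasets)
    ors = np.array([r.or_value for r in records if r.evaluable])
    if ors.size == 0:
        raise ValueError("no evaluable mutations to summarise")
    med = float(np.median(ors))
    med_log = float(np.median(np.log10(ors)))
    return med, med_log


def spectrum_table(rows: dict) -> pd.DataFrame:
    """Tabulate :class:`SpectrumSummary` objects keyed by scenario label."""
    data = []
    for label, s in rows.items():
        data.append(
            {
                "scenario": label,
                "per_population_median": s.per_population[1],
                "per_population_q25": s.per_population[0],
                "per_population_q75": s.per_population[2],
                "per_case_median": s.per_case[1],
                "per_case_q25": s.per_case[0],
                "per_case_q75": s.per_case[2],
                "per_control_median": s.per_control[1],
                "per_control_q25": s.per_control[0],
                "per_control_q75": s.per_control[2],
                "n_datasets": s.n_datasets,
            }
        )
    return pd.DataFrame(data)


def or_table(rows: dict, round_to: int | None = 2) -> pd.DataFrame:
    """Tabulate :class:`ORDistributionSummary` objects keyed by scenario label.

    Percentages are rounded to ``round_to`` decimals (2 mirrors the study's
    tables); pass ``None`` for full precision.
    """
    data = []
    for label, s in rows.items():
        row = {"scenario": label, "pct_or_lt1": s.pct_or_lt1}
        for t, (pct_large, pct_within) in s.large_effect.items():
            row["pct_large_effect_%g" % t] = pct_large
            row["pct_lt1_within_large_%g" % t] = pct_within
        for f, pct in s.by_frequency.items():
            row["pct_or_lt1_freq_lt_%g" % f] = pct
        row["n_evaluable"] = s.n_evaluable
        row["n_total"] = s.n_total
        data.append(row)
    df = pd.DataFrame(data)
    if round_to is not None:
        num = [c for c in df.columns if c.startswith("pct_")]
        df[num] = df[num].round(round_to)
    return df


def log10_or_histogram(datasets, bins=60, value_range=(-3.0, 3.0)) -> pd.DataFrame:
    """Histogram of log10 OR over pooled evaluable mutations.

    A plain table of bin edges and counts (plotting is left to the caller).
    """
    records = _as_records(datasets)
    values = np.array([r.log10_or for r in records if r.evaluable])
    counts, edges = np.histogram(values, bins=bins, range=value_range)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def write_summary_tsv(df: pd.DataFrame, path) -> None:
    """Write a summary table so that a reader recovers every float bit-exactly."""
    # shortest round-trip repr per float, so the reader recovers exact bits
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_summary_tsv(path) -> pd.DataFrame:
    # round_trip parsing: the default C float parser can be off by one ULP
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
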