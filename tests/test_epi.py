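"""Odds-ratio records and summaries against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from coalor.coalescent import Mutation, simulate_tree
from coalor.epi import (
    MutationEpiRecord,
    dataset_records,
    median_or,
    mutation_or,
    or_table,
    pooled_records,
    spectrum_table,
    summarize_mutation_spectrum,
    summarize_or_distribution,
)
from coalor.penetrance import PenetranceModel
from coalor.scenario import PopulationDataset
from conftest import make_toy_dataset


def leaf_climb_carriers(tree, node):
    out = set()
    for leaf in range(tree.n):
        v = leaf
        while v != tree.root:
            if v == node:
                out.add(leaf)
                break
            v = int(tree.parent[v])
    return out


def brute_force_record(ds, mut):
    """Independent 2x2 tally via per-leaf membership tests."""
    carr = leaf_climb_carriers(ds.trees[mut.locus_index], mut.branch_child_node)
    a = sum(int(ds.phenotype[j]) for j in carr)
    b = len(carr) - a
    c = int(ds.phenotype.sum()) - a
    d = ds.n - len(carr) - c
    return a, b, c, d


def interesting_toy(rng):
    """A toy dataset with at least one case, one control and one mutation."""
    while True:
        ds = make_toy_dataset(rng, n=30, mutation_rate=1.5,
                              model=PenetranceModel.logistic(-1.0, 1.0))
        if 0 < ds.phenotype.sum() < ds.n and ds.n_segregating:
            return ds


# ----------------------------------------------------------- 2x2 mechanics


def test_balanced_table_gives_or_one():
    r = MutationEpiRecord.from_counts(0, 0.5, 10, 10, 10, 10)
    assert r.evaluable
    assert r.or_value == 1.0
    assert r.log10_or == 0.0


def test_cross_ratio_example():
    r = MutationEpiRecord.from_counts(0, 0.001, 5, 5, 45, 9945)
    assert r.or_value == pytest.approx(221.0)


def test_case_only_mutation_not_evaluable():
    r = MutationEpiRecord.from_counts(0, 0.01, 7, 0, 93, 900)
    assert not r.evaluable
    assert math.isnan(r.or_value)


def test_mutation_or_matches_brute_force(rng):
    for _ in range(30):
        ds = interesting_toy(rng)
        for mut in ds.all_mutations():
            rec = mutation_or(ds, mut)
            a, b, c, d = brute_force_record(ds, mut)
            assert (rec.a, rec.b, rec.c, rec.d) == (a, b, c, d)
            if rec.evaluable:
                assert rec.or_value == pytest.approx(a * d / (b * c))


def test_dataset_records_agree_with_mutation_or(rng):
    ds = interesting_toy(rng)
    assert dataset_records(ds) == [mutation_or(ds, m) for m in ds.all_mutations()]


def test_exclusion_categories_partition_mutations(rng):
    """evaluable / case-only / control-only / fixed partition the mutations."""
    for _ in range(20):
        ds = interesting_toy(rng)
        recs = dataset_records(ds)
        n_eval = sum(r.evaluable for r in recs)
        # classify each non-evaluable record by its first empty cell; this
        # is exhaustive and disjoint even for tiny populations where the
        # non-carrier complement can itself be phenotype-pure (c=0 or d=0)
        n_control_only = sum(r.a == 0 for r in recs)
        n_case_only = sum(r.a > 0 and r.b == 0 for r in recs)
        n_all_cases_carry = sum(r.a > 0 and r.b > 0 and r.c == 0 for r in recs)
        n_all_controls_carry = sum(
            r.a > 0 and r.b > 0 and r.c > 0 and r.d == 0 for r in recs
        )
        assert (
            n_eval + n_control_only + n_case_only
            + n_all_cases_carry + n_all_controls_carry
        ) == len(recs)
        # fixed mutations are the intersection of the two "all carry" cases
        for r in recs:
            if r.c == 0 and r.d == 0:
                assert r.a > 0 and r.b > 0 and not r.evaluable


def test_log10_or_sign_tracks_frequency_difference(rng):
    """OR < 1 exactly when the mutation is rarer among cases than controls."""
    for _ in range(10):
        ds = interesting_toy(rng)
        for r in dataset_records(ds):
            if not r.evaluable:
                continue
            freq_cases = r.a / (r.a + r.c)
            freq_controls = r.b / (r.b + r.d)
            assert np.sign(r.log10_or) == np.sign(freq_cases - freq_controls)


def test_phenotype_swap_inverts_odds_ratios(rng):
    ds = interesting_toy(rng)
    before = dataset_records(ds)
    ds.phenotype = (1 - ds.phenotype).astype(np.int8)
    after = dataset_records(ds)
    for x, y in zip(before, after):
        assert x.evaluable == y.evaluable
        if x.evaluable:
            assert y.or_value == pytest.approx(1.0 / x.or_value)


# ----------------------------------------------------------------- spectrum


def _hand_dataset():
    """Six individuals, three singleton mutations on leaves 0..2, cases 0..2."""
    tree = simulate_tree(6, np.random.default_rng(0))
    muts = [
        Mutation(locus_index=0, branch_child_node=j, carrier_count=1,
                 frequency=1 / 6)
        for j in range(3)
    ]
    counts = np.zeros((1, 6), dtype=np.int32)
    counts[0, :3] = 1
    phenotype = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
    return PopulationDataset(
        trees=[tree], mutations=[muts], counts=counts,
        phenotype=phenotype, prevalence=0.5,
    )


def test_spectrum_on_hand_built_dataset():
    s = summarize_mutation_spectrum([_hand_dataset()])
    assert s.per_population == (3.0, 3.0, 3.0)
    assert s.per_case == (1.0, 1.0, 1.0)
    assert s.per_control == (0.0, 0.0, 0.0)


def test_spectrum_matches_exhaustive_toy_computation(rng):
    datasets = [interesting_toy(rng) for _ in range(5)]
    s = summarize_mutation_spectrum(datasets)
    seg = [ds.n_segregating for ds in datasets]
    per_case = [
        np.mean([ds.k_total[j] for j in range(ds.n) if ds.phenotype[j]])
        for ds in datasets
    ]
    per_control = [
        np.mean([ds.k_total[j] for j in range(ds.n) if not ds.phenotype[j]])
        for ds in datasets
    ]
    assert s.per_population == tuple(np.percentile(seg, [25, 50, 75]))
    assert s.per_case == pytest.approx(tuple(np.percentile(per_case, [25, 50, 75])))
    assert s.per_control == pytest.approx(
        tuple(np.percentile(per_control, [25, 50, 75]))
    )


def test_spectrum_requires_datasets():
    with pytest.raises(ValueError):
        summarize_mutation_spectrum([])


# ------------------------------------------------------------- OR summaries


def _record(or_value, frequency=0.1):
    """An evaluable record with a prescribed OR (counts are placeholders)."""
    return MutationEpiRecord(
        locus_index=0, frequency=frequency, a=1, b=1, c=1, d=1,
        evaluable=True, or_value=float(or_value),
        log10_or=math.log10(or_value),
    )


def test_all_or_above_one_gives_zero_percent():
    recs = [_record(v) for v in (1.5, 2.0, 8.0)]
    assert summarize_or_distribution(recs).pct_or_lt1 == 0.0


def test_or_distribution_matches_exhaustive_count():
    ors = [0.4, 0.8, 0.96, 1.0, 1.2, 1.7, 2.5, 4.0]
    freqs = [0.0005, 0.0005, 0.004, 0.004, 0.03, 0.03, 0.2, 0.2]
    recs = [_record(v, f) for v, f in zip(ors, freqs)]
    s = summarize_or_distribution(recs)
    assert s.pct_or_lt1 == pytest.approx(100 * 3 / 8)
    # large-effect: OR>1.5 or OR<1/1.5 -> {0.4, 1.7, 2.5, 4.0}; of these OR<1: {0.4}
    # frequency<0.05 covers the first six ORs, of which {0.4, 0.8, 0.96} are <1
    assert s.large_effect[1.5][0] == pytest.approx(100 * 4 / 8)
    assert s.large_effect[1.5][1] == pytest.approx(100 * 1 / 4)
    # OR>2 or OR<0.5 -> {0.4, 2.5, 4.0}
    assert s.large_effect[2.0][0] == pytest.approx(100 * 3 / 8)
    assert s.large_effect[2.0][1] == pytest.approx(100 * 1 / 3)
    # frequency strata
    assert s.by_frequency[0.001] == pytest.approx(100 * 2 / 2)
    assert s.by_frequency[0.01] == pytest.approx(100 * 3 / 4)
    assert s.by_frequency[0.05] == pytest.approx(100 * 3 / 6)


def test_or_distribution_requires_evaluable():
    with pytest.raises(ValueError):
        summarize_or_distribution([MutationEpiRecord.from_counts(0, 0.5, 5, 0, 5, 5)])


def test_median_or_small_pools():
    recs = [_record(v) for v in (0.5, 1.0, 2.0)]
    med, med_log = median_or(recs)
    assert med == pytest.approx(1.0)
    assert med_log == pytest.approx(0.0, abs=1e-12)
    med, med_log = median_or([_record(4.0)])
    assert med == pytest.approx(4.0)
    assert med_log == pytest.approx(math.log10(4.0))


def test_median_or_matches_sort_oracle(rng):
    values = rng.lognormal(0.2, 0.8, size=101)
    recs = [_record(v) for v in values]
    med, med_log = median_or(recs)
    s = np.sort(values)
    assert med == pytest.approx(s[50])
    assert med_log == pytest.approx(math.log10(s[50]))


def test_median_log_consistent_with_log_of_median(rng):
    # odd pool size: the sample median is an order statistic, so the
    # monotone log10 transform commutes with it exactly
    values = rng.lognormal(0.1, 0.5, size=201)
    med, med_log = median_or([_record(v) for v in values])
    assert med_log == pytest.approx(math.log10(med))


def test_per_dataset_average_variant_runs(rng):
    datasets = [interesting_toy(rng) for _ in range(4)]
    pooled = summarize_or_distribution(datasets)
    averaged = summarize_or_distribution(datasets, per_dataset_average=True)
    assert 0 <= averaged.pct_or_lt1 <= 100
    assert pooled.n_evaluable == averaged.n_evaluable


def test_log10_or_histogram_counts_evaluable_records():
    from coalor.epi import log10_or_histogram

    recs = [_record(v) for v in (0.5, 1.0, 2.0, 10.0)]
    hist = log10_or_histogram(recs, bins=6, value_range=(-3.0, 3.0))
    assert hist["count"].sum() == 4
    mids = (hist["bin_left"] + hist["bin_right"]) / 2
    assert hist.loc[(mids > 0) & (mids < 1), "count"].sum() >= 2


# ------------------------------------------------------------------- tables


def test_summary_tables_round_trip_exactly(rng, tmp_path):
    datasets = [interesting_toy(rng) for _ in range(4)]
    spec = spectrum_table({"toy": summarize_mutation_spectrum(datasets)})
    ors = or_table(
        {"toy": summarize_or_distribution(pooled_records(datasets))}, round_to=None
    )
    from coalor.epi import read_summary_tsv, write_summary_tsv

    for name, df in (("spectrum", spec), ("or", ors)):
        path = tmp_path / ("%s.tsv" % name)
        write_summary_tsv(df, path)
        back = read_summary_tsv(path)
        pd.testing.assert_frame_equal(back, df, check_exact=True)
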