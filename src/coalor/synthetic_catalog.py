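"""Synthetic GWAS-catalogue generator with known ground truth.

Emits the four TSV inputs the catalogue pipeline consumes (catalogue,
synonym map, trait prevalence table, ancestral-allele table) from a known
generative model: each trait gets an adult prevalence drawn log-uniformly
from a window, and each association's minor-allele log10 OR follows a
linear trend in prevalence plus Gaussian noise.  Rows are deliberately
corrupted at configurable rates — incomplete fields, strand-ambiguous
allele pairs (A/T, C/G), SNPs missing from the ancestral table, reported
synonym spellings — and every row's intended fate is recorded, so filter
counts and the recovered regression slope can be checked against ground
truth.

Defaults approximate the scale of the real catalogue analysis this
emulates: 31 traits with prevalence 0.1-20%, ~60 associations each of which
~70% reach genome-wide significance, and roughly a fifth of associations
lost when restricting to an unambiguous derived allele.  The generator does
not emulate linkage structure, genomic positions, or per-study heterogeneity
of the real catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticCatalogSpec", "SyntheticCatalog", "generate_catalog"]

_PAIRS_OK = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PAIRS_AMBIGUOUS = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class SyntheticCatalogSpec:
    """Parameters of the synthetic catalogue generator.

    ``true_slope``/``true_intercept`` define the minor-allele
    log10 OR trend against trait prevalence; ``noise_sd`` is the residual
    standard deviation on the log10 scale.  ``maf_beta`` parameterises the
    Beta draw rescaled onto (0, 0.5].  The ``fraction_*`` knobs corrupt
    rows to exercise the pipeline's filters.
    """

    n_traits: int = 31
    associations_per_trait: int = 60
    prevalence_range: tuple = (0.001, 0.20)
    true_slope: float = -0.5
    true_intercept: float = 0.26
    noise_sd: float = 0.15
    maf_beta: tuple = (1.0, 3.0)
    fraction_incomplete: float = 0.2
    fraction_strand_ambiguous: float = 0.1
    fraction_missing_ancestral: float = 0.1
    fraction_synonym: float = 0.15
    fraction_weak: float = 0.1
    gws_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in (
            "fraction_incomplete",
            "fraction_strand_ambiguous",
            "fraction_missing_ancestral",
            "fraction_synonym",
            "fraction_weak",
            "gws_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError("%s must be in [0,1], got %g" % (name, v))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_traits < 1 or self.associations_per_trait < 1:
            raise ValueError("need at least one trait and one association")
        lo, hi = self.prevalence_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("prevalence range must satisfy 0 < lo < hi < 1")


@dataclass
class SyntheticCatalog:
    """Generated tables plus per-row ground truth."""

    spec: SyntheticCatalogSpec
    catalog: pd.DataFrame
    synonyms: pd.DataFrame
    prevalence: pd.DataFrame
    ancestral: pd.DataFrame
    truth: pd.DataFrame = field(repr=False)

    def write(self, out_dir) -> dict:
        """Write the four input TSVs (and the truth table) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("catalog", self.catalog),
            ("synonyms", self.synonyms),
            ("prevalence", self.prevalence),
            ("ancestral", self.ancestral),
            ("truth", self.truth),
        ):
            paths[name] = out / ("%s.tsv" % name)
            df.to_csv(paths[name], sep="\t", index=False)
        return paths


def generate_catalog(spec: SyntheticCatalogSpec) -> SyntheticCatalog:
    """Generate a synthetic catalogue with per-row ground truth.

    The same spec (same seed) always yields byte-identical tables.  The
    truth table records, per association row: the trait prevalence, the
    noiseless and realised minor-allele log10 OR, and the row's ``fate`` —
    ``incomplete`` (dropped at load), ``weak`` (dropped by the association
    p-value filter), ``strand_ambiguous`` / ``missing_ancestral`` (dropped
    by the derived-allele restriction) or ``retained``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.prevalence_range
    n_rows = spec.n_traits * spec.associations_per_trait

    trait_names = np.array(["trait_%02d" % i for i in range(spec.n_traits)])
    prevalence = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_traits))

    trait_idx = np.repeat(np.arange(spec.n_traits), spec.associations_per_trait)
    prev_row = prevalence[trait_idx]

    a, b = spec.maf_beta
    maf = 0.5 * rng.beta(a, b, n_rows)
    maf = np.maximum(maf, 5e-4)

    mean_log10 = spec.true_intercept + spec.true_slope * prev_row
    log10_minor_or = mean_log10 + rng.normal(0.0, spec.noise_sd, n_rows)
    minor_or = 10.0 ** log10_minor_or

    # allele pair; a configurable share is strand-ambiguous (A/T or C/G)
    ambiguous = rng.random(n_rows) < spec.fraction_strand_ambiguous
    pair_ok = np.array(_PAIRS_OK, dtype=object)[rng.integers(len(_PAIRS_OK), size=n_rows)]
    pair_amb = np.array(_PAIRS_AMBIGUOUS, dtype=object)[
        rng.integers(len(_PAIRS_AMBIGUOUS), size=n_rows)
    ]
    pair = np.where(ambiguous[:, None], pair_amb, pair_ok)
    minor_allele, major_allele = pair[:, 0], pair[:, 1]

    # risk allele randomised so both orientation branches are exercised
    risk_is_minor = rng.random(n_rows) < 0.5
    risk_allele = np.where(risk_is_minor, minor_allele, major_allele)
    other_allele = np.where(risk_is_minor, major_allele, minor_allele)
    raf = np.where(risk_is_minor, maf, 1.0 - maf)
    or_reported = np.where(risk_is_minor, minor_or, 1.0 / minor_or)

    # p-value strata: genome-wide significant, intermediate, weak
    u = rng.random(n_rows)
    weak = u < spec.fraction_weak
    gws = u >= 1.0 - spec.gws_fraction
    p_value = np.exp(rng.uniform(np.log(5e-8), np.log(5e-4), n_rows))
    p_value[gws] = np.exp(rng.uniform(np.log(1e-30), np.log(5e-8), gws.sum()))
    p_value[weak] = np.exp(rng.uniform(np.log(5e-4), np.log(5e-2), weak.sum()))

    snp_id = np.array(["rs%06d" % i for i in range(n_rows)])

    # ancestral allele: either member of the pair, so the derived allele is
    # sometimes the risk and sometimes the other allele
    anc_is_risk = rng.random(n_rows) < 0.5
    ancestral = np.where(anc_is_risk, risk_allele, other_allele)
    missing_anc = rng.random(n_rows) < spec.fraction_missing_ancestral

    # synonym spellings for a share of rows
    synonym = rng.random(n_rows) < spec.fraction_synonym
    reported_trait = trait_names[trait_idx].astype(object)
    reported_trait[synonym] = [t + " (reported)" for t in reported_trait[synonym]]

    catalog = pd.DataFrame(
        {
            "trait": reported_trait,
            "snp_id": snp_id,
            "risk_allele": risk_allele,
            "other_allele": other_allele,
            "raf": raf,
            "or_reported": or_reported,
            "p_value": p_value,
        }
    )

    # incomplete rows: blank one required field, cycling through candidates
    incomplete = rng.random(n_rows) < spec.fraction_incomplete
    blank_cols = ("raf", "or_reported", "p_value", "risk_allele")
    catalog_out = catalog.astype(object)
    for j, i in enumerate(np.flatnonzero(incomplete)):
        catalog_out.iat[i, catalog.columns.get_loc(blank_cols[j % len(blank_cols)])] = ""

    fate = np.full(n_rows, "retained", dtype=object)
    fate[missing_anc] = "missing_ancestral"
    fate[ambiguous] = "strand_ambiguous"
    fate[weak] = "weak"
    fate[incomplete] = "incomplete"

    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "trait": trait_names[trait_idx],
            "prevalence": prev_row,
            "maf": maf,
            "mean_log10_minor_or": mean_log10,
            "log10_minor_or": log10_minor_or,
            "risk_is_minor": risk_is_minor,
            "gws": gws,
            "fate": fate,
        }
    )

    synonyms = pd.DataFrame(
        {
            "reported_name": [t + " (reported)" for t in trait_names],
            "canonical_name": trait_names,
        }
    )
    prevalence_df = pd.DataFrame({"trait": trait_names, "prevalence": prevalence})
    anc_df = pd.DataFrame(
        {"snp_id": snp_id[~missing_anc], "ancestral_allele": ancestral[~missing_anc]}
    )
    return SyntheticCatalog(
        spec=spec,
        catalog=catalog_out,
        synonyms=synonyms,
        prevalence=prevalence_df,
        ancestral=anc_df,
        truth=truth,
    )
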