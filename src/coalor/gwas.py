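"""GWAS-catalogue filtering and the odds-ratio-versus-prevalence regression.

The simulations predict that, across diseases, reported per-variant effect
sizes should shrink as trait prevalence grows.  This module implements the
empirical check on a tab-separated extract of a GWAS catalogue: load rows
with complete information, merge synonymous trait names, keep traits with
enough genome-wide-significant associations and a known adult prevalence
inside a window, orient every odds ratio to the minor (optionally to the
derived) allele, and regress log10 OR on trait prevalence with a Wald test
for the slope.

Expected input dialects (all plain TSV):

* catalogue: columns ``trait``, ``snp_id``, ``risk_allele``,
  ``other_allele``, ``raf`` (risk-allele frequency), ``or_reported``,
  ``p_value`` (a ``column_map`` can rename foreign headers onto these);
* synonyms: ``reported_name`` -> ``canonical_name``;
* prevalence: ``trait`` -> ``prevalence`` (adult population fraction);
* ancestral: ``snp_id`` -> ``ancestral_allele`` (dbSNP-derived).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "RegressionResult",
    "load_catalog",
    "load_two_column_tsv",
    "merge_trait_synonyms",
    "filter_traits",
    "orient_to_minor_allele",
    "restrict_to_derived",
    "regress_or_vs_prevalence",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "trait",
    "snp_id",
    "risk_allele",
    "other_allele",
    "raf",
    "or_reported",
    "p_value",
)

_STRAND_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def load_catalog(catalog_tsv, column_map: dict | None = None) -> pd.DataFrame:
    """Load a catalogue extract, dropping rows with incomplete information.

    ``column_map`` maps the required canonical names to the file's own
    headers.  Rows missing any required field (or with non-numeric
    raf/OR/p) are dropped; the count of dropped rows is logged and stored in
    ``df.attrs["n_dropped_incomplete"]``.
    """
    df = pd.read_csv(catalog_tsv, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError("catalogue is missing required column %r" % col)
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    n_raw = len(df)
    for col in ("raf", "or_reported", "p_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("trait", "snp_id", "risk_allele", "other_allele"):
        df[col] = df[col].str.strip()
        df.loc[df[col] == "", col] = pd.NA
    df = df.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
    n_dropped = n_raw - len(df)
    df.attrs["n_dropped_incomplete"] = n_dropped
    logger.info(
        "catalogue: %d rows, %d dropped as incomplete, %d retained",
        n_raw, n_dropped, len(df),
    )
    return df


def load_two_column_tsv(path, key: str, value: str) -> dict:
    """Read a two-column TSV into a dict (synonym/prevalence/ancestral maps)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise ValueError("%s is missing required column %r" % (path, col))
    return dict(zip(df[key], df[value]))


def merge_trait_synonyms(rows: pd.DataFrame, synonym_map: dict) -> pd.DataFrame:
    """Replace reported trait names by canonical ones; unknown names pass through."""
    out = rows.copy()
    out["trait"] = out["trait"].map(lambda t: synonym_map.get(t, t))
    return out


def filter_traits(
    rows: pd.DataFrame,
    prevalences: dict,
    min_gws: int = 10,
    gws_threshold: float = 5e-8,
    assoc_threshold: float = 5e-4,
    prevalence_window: tuple = (0.001, 0.20),
) -> pd.DataFrame:
    """Trait-level quality filter followed by the association p-value filter.

    A trait is kept if it has at least ``min_gws`` (not necessarily
    distinct) associations at ``p < gws_threshold`` *and* a known adult
    prevalence inside ``prevalence_window`` (inclusive bounds, the window
    being a reporting-bias guard, not a disease category).  Rows of kept
    traits are then restricted to ``p < assoc_threshold``.  The trait
    prevalence is joined on as a ``prevalence`` column.
    """
    if not prevalences:
        raise ValueError("prevalence table is empty")
    prev = {t: float(p) for t, p in prevalences.items()}
    for t, p in prev.items():
        if not 0.0 < p < 1.0:
            raise ValueError("prevalence for %r must be in (0,1), got %g" % (t, p))
    lo, hi = prevalence_window
    gws_counts = rows.loc[rows["p_value"] < gws_threshold, "trait"].value_counts()
    keep_traits = {
        t
        for t, c in gws_counts.items()
        if c >= min_gws and t in prev and lo <= prev[t] <= hi
    }
    out = rows[
        rows["trait"].isin(keep_traits) & (rows["p_value"] < assoc_threshold)
    ].copy()
    out["prevalence"] = out["trait"].map(prev)
    logger.info(
        "trait filter: %d/%d traits kept, %d associations at p<%g",
        len(keep_traits), rows["trait"].nunique(), len(out), assoc_threshold,
    )
    return out.reset_index(drop=True)


def orient_to_minor_allele(rows: pd.DataFrame) -> pd.DataFrame:
    """Orient every odds ratio to the minor allele.

    Adds ``maf`` (= raf, or 1-raf if the risk allele is the major one) and
    ``minor_or`` (reciprocal of the reported OR when flipped), and sets
    ``or_used`` to the minor-allele OR.  Idempotent: a second application
    changes nothing because maf <= 0.5 is a fixed point.
    """
    raf = rows["raf"].to_numpy(dtype=float)
    if np.any((raf <= 0.0) | (raf >= 1.0)):
        raise ValueError("risk-allele frequencies must lie strictly in (0,1)")
    out = rows.copy()
    flip = raf > 0.5
    out["maf"] = np.where(flip, 1.0 - raf, raf)
    out["minor_or"] = np.where(
        flip, 1.0 / rows["or_reported"], rows["or_reported"]
    )
    out["minor_allele"] = np.where(flip, rows["other_allele"], rows["risk_allele"])
    out["or_used"] = out["minor_or"]
    return out


def restrict_to_derived(rows: pd.DataFrame, ancestral_table: dict) -> pd.DataFrame:
    """Keep rows whose derived allele is unambiguous; orient ORs to it.

    Drops rows whose SNP has no ancestral call, whose ancestral call matches
    neither allele, or whose allele pair is strand-ambiguous (A/T, C/G).
    For the survivors the derived allele is the non-ancestral member of the
    pair; ``or_used`` becomes the derived-allele OR (reported OR if the risk
    allele is derived, its reciprocal otherwise).  Drop counts are logged
    and stored in ``df.attrs``.
    """
    out = rows.copy()
    risk = out["risk_allele"].to_numpy(dtype=object)
    other = out["other_allele"].to_numpy(dtype=object)
    anc = np.array([ancestral_table.get(s) for s in out["snp_id"]], dtype=object)

    ambiguous = np.array(
        [frozenset((r, o)) in _STRAND_AMBIGUOUS for r, o in zip(risk, other)]
    )
    no_call = np.array(
        [a is None or (a != r and a != o) for a, r, o in zip(anc, risk, other)]
    )
    keep = ~(ambiguous | no_call)
    out = out[keep].copy()
    anc_kept = anc[keep]
    risk_is_derived = anc_kept != out["risk_allele"].to_numpy(dtype=object)
    out["derived_allele"] = np.where(
        risk_is_derived, out["risk_allele"], out["other_allele"]
    )
    out["derived_or"] = np.where(
        risk_is_derived, out["or_reported"], 1.0 / out["or_reported"]
    )
    out["or_used"] = out["derived_or"]
    out.attrs["n_dropped_strand_ambiguous"] = int(ambiguous.sum())
    out.attrs["n_dropped_no_ancestral"] = int((no_call & ~ambiguous).sum())
    logger.info(
        "derived-allele restriction: %d strand-ambiguous and %d without "
        "ancestral call dropped, %d retained",
        out.attrs["n_dropped_strand_ambiguous"],
        out.attrs["n_dropped_no_ancestral"],
        len(out),
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log10 OR on trait prevalence with a Wald slope test."""

    slope: float
    intercept: float
    wald_p: float
    n_points: int
    mode: str

    @property
    def slope_ci(self) -> tuple:
        return self._ci

    def __post_init__(self):  # slope CI filled by the regression routine
        object.__setattr__(self, "_ci", (np.nan, np.nan))


def regress_or_vs_prevalence(
    rows: pd.DataFrame, mode: str = "per-association"
) -> RegressionResult:
    """Regress log10 oriented OR on trait prevalence.

    ``mode="per-association"`` uses one point per association;
    ``mode="per-trait"`` one point per trait (its median log10 OR).
    Requires a ``prevalence`` column (from :func:`filter_traits`) and an
    ``or_used`` column (from one of the orientation steps).
    """
    if mode not in ("per-association", "per-trait"):
        raise ValueError("mode must be 'per-association' or 'per-trait'")
    df = rows.copy()
    df["log10_or"] = np.log10(df["or_used"].to_numpy(dtype=float))
    if mode == "per-trait":
        df = (
            df.groupby("trait", as_index=False)
            .agg(log10_or=("log10_or", "median"), prevalence=("prevalence", "first"))
        )
    if len(df) < 3:
        raise ValueError("need at least 3 points for the regression, have %d" % len(df))
    X = sm.add_constant(df["prevalence"].to_numpy(dtype=float))
    fit = sm.OLS(df["log10_or"].to_numpy(dtype=float), X).fit()
    wald_p = float(fit.pvalues[1])
    if fit.ssr <= 1e-24 * len(df):
        # perfectly collinear response: no evidence against a zero slope
        wald_p = 1.0 if abs(fit.params[1]) < 1e-12 else 0.0
    result = RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        wald_p=wald_p,
        n_points=len(df),
        mode=mode,
    )
    ci = fit.conf_int()
    object.__setattr__(result, "_ci", (float(ci[1][0]), float(ci[1][1])))
    return result


def run_pipeline(
    catalog_tsv,
    synonyms_tsv=None,
    prevalence_tsv=None,
    ancestral_tsv=None,
    min_gws: int = 10,
    gws_threshold: float = 5e-8,
    assoc_threshold: float = 5e-4,
    prevalence_window: tuple = (0.001, 0.20),
    mode: str = "per-association",
):
    """Full catalogue analysis: load -> merge synonyms -> trait filters ->
    minor-allele orientation -> optional derived-allele restriction ->
    regression.  Returns ``(rows, RegressionResult)``.
    """
    rows = load_catalog(catalog_tsv)
    if synonyms_tsv is not None:
        rows = merge_trait_synonyms(
            rows, load_two_column_tsv(synonyms_tsv, "reported_name", "canonical_name")
        )
    if prevalence_tsv is None:
        raise ValueError("a trait prevalence table is required")
    prev = {
        t: float(p)
        for t, p in load_two_column_tsv(prevalence_tsv, "trait", "prevalence").items()
    }
    rows = filter_traits(
        rows, prev, min_gws, gws_threshold, assoc_threshold, prevalence_window
    )
    rows = orient_to_minor_allele(rows)
    if ancestral_tsv is not None:
        rows = restrict_to_derived(
            rows, load_two_column_tsv(ancestral_tsv, "snp_id", "ancestral_allele")
        )
    return rows, regress_or_vs_prevalence(rows, mode=mode)
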