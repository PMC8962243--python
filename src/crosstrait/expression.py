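"""Differential expression of candidate pleiotropic genes and gene-set tests.

The expression stage takes a genes x samples matrix with case/control
labels, z-scales each gene across all samples, masks entries more than 3
standard deviations from the mean, runs a two-tailed t-test per gene
(Welch by default), and applies Benjamini-Hochberg correction across the
tested genes with significance declared at q < 0.05.  A generic
hypergeometric over-representation test against user-supplied gene sets
(GMT format) and threshold filters for variant-level annotations (CADD
deleteriousness, RegulomeDB regulatory rank) round out the downstream
interpretation toolkit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DeResult",
    "AnnotationThresholds",
    "scale_expression",
    "remove_outliers",
    "de_ttest",
    "bh_adjust",
    "read_gmt",
    "hypergeom_enrich",
    "filter_annotations",
]


@dataclass
class DeResult:
    """Per-gene differential-expression statistics.

    ``frame`` columns: gene, t, p, q, mean_case, mean_control,
    n_case, n_control, significant (q < alpha).  ``excluded`` lists
    genes dropped for insufficient usable values.
    """

    frame: pd.DataFrame = field(repr=False)
    excluded: list = field(default_factory=list)
    alpha: float = 0.05


def scale_expression(matrix: pd.DataFrame):
    """Center and unit-variance scale each gene across all samples.

    Uses the sample standard deviation (ddof=1).  Genes with zero
    variance (or fewer than two distinct values) cannot be scaled and
    are excluded with a flag.

    Returns ``(scaled, excluded_gene_list)``.
    """
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    zero = ~(sd > 0)
    excluded = matrix.index[zero].tolist()
    if excluded:
        logger.warning("%d constant genes excluded from scaling", len(excluded))
    scaled = matrix.loc[~zero].sub(mu[~zero], axis=0).div(sd[~zero], axis=0)
    return scaled, excluded


def remove_outliers(scaled: pd.DataFrame, sd_cutoff=3.0):
    """Mask (NaN) entries with |value| strictly greater than ``sd_cutoff``.

    Masking is per entry on the scaled matrix; a value exactly at the
    cutoff is retained.  Returns ``(masked, n_masked)``.
    """
    mask = scaled.abs() > sd_cutoff
    masked = scaled.mask(mask)
    return masked, int(mask.to_numpy().sum())


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_ttest(matrix, labels, genes=None, equal_var=False, alpha=0.05) -> DeResult:
    """Two-tailed t-test per gene between case and control samples.

    Parameters
    ----------
    matrix : genes x samples DataFrame (typically scaled and
        outlier-masked; NaNs are ignored per gene).
    labels : mapping/Series sample -> "case"/"control" (any two labels;
        the lexically smaller one after ``case``-first normalization is
        taken as case if literal "case"/"control" are not used).
    genes : optional subset of genes to test; BH correction is applied
        across this subset only.
    equal_var : pooled-variance (Student) t-test instead of Welch.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    groups = sorted(labels.unique(), key=lambda g: (g != "case", g))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    gcase, gctrl = groups
    sub = matrix.loc[list(genes)] if genes is not None else matrix
    if len(sub) == 0:
        raise ValueError("empty gene subset")

    case = sub.loc[:, labels == gcase].to_numpy(float)
    ctrl = sub.loc[:, labels == gctrl].to_numpy(float)
    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    usable = (n_case >= 2) & (n_ctrl >= 2)
    excluded = sub.index[~usable].tolist()
    if excluded:
        logger.warning("%d genes excluded from testing (<2 usable values in a group)",
                       len(excluded))

    t, p = stats.ttest_ind(
        case[usable], ctrl[usable], axis=1, equal_var=equal_var, nan_policy="omit"
    )
    q = bh_adjust(p)
    frame = pd.DataFrame(
        {
            "gene": sub.index[usable],
            "t": t,
            "p": p,
            "q": q,
            "mean_case": np.nanmean(case[usable], axis=1),
            "mean_control": np.nanmean(ctrl[usable], axis=1),
            "n_case": n_case[usable],
            "n_control": n_ctrl[usable],
            "significant": q < alpha,
        }
    ).reset_index(drop=True)
    return DeResult(frame=frame, excluded=excluded, alpha=alpha)


def read_gmt(path):
    """Parse a GMT gene-set file: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeom_enrich(query, gene_sets, universe):
    """One-sided hypergeometric over-representation of ``query`` in each set.

    For a universe of M genes, a set of K (after intersection with the
    universe), and a query of n with k overlapping, p = P(X >= k) under
    Hypergeometric(M, K, n).  BH correction across the tested sets.

    Returns a DataFrame: set, k, set_size, p, q, overlap (sorted by p).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append({"set": name, "k": k, "set_size": len(members),
                     "p": min(p, 1.0), "overlap": ",".join(overlap)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
        out = out[["set", "k", "set_size", "p", "q", "overlap"]]
    return out


#: RegulomeDB categories from most to least evidence of regulatory function
REGULOME_ORDER = ["1a", "1b", "1c", "1d", "1e", "1f",
                  "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "7"]
_REGULOME_RANK = {tok: i for i, tok in enumerate(REGULOME_ORDER)}


@dataclass
class AnnotationThresholds:
    """Cutoffs for variant-level functional annotation flags.

    A CADD (scaled) score strictly above 12.37 marks a variant as
    potentially pathogenic; a RegulomeDB category at or better than
    ``regulome_max_rank`` (ordering 1a < 1b < ... < 7) marks it as
    likely regulatory.
    """

    cadd_cutoff: float = 12.37
    regulome_max_rank: str = "1f"

    def __post_init__(self):
        if self.cadd_cutoff <= 0:
            raise ValueError("cadd_cutoff must be positive")
        if self.regulome_max_rank not in _REGULOME_RANK:
            raise ValueError(f"unknown RegulomeDB category {self.regulome_max_rank!r}")


def filter_annotations(table: pd.DataFrame, thresholds: AnnotationThresholds | None = None):
    """Flag deleterious / regulatory variants in an annotation table.

    ``table`` may carry columns CADD (numeric) and/or REGULOMEDB
    (categories 1a..7).  Adds boolean columns ``deleterious`` (CADD
    strictly above the cutoff), ``regulatory`` (rank at or better than
    the configured category) and ``regulome_unparsed``.
    """
    thresholds = thresholds or AnnotationThresholds()
    out = table.copy()
    if "CADD" in out.columns:
        cadd = pd.to_numeric(out["CADD"], errors="coerce")
        out["deleterious"] = (cadd > thresholds.cadd_cutoff).fillna(False)
    if "REGULOMEDB" in out.columns:
        tok = out["REGULOMEDB"].astype(str).str.strip().str.lower()
        rank = tok.map(_REGULOME_RANK)
        out["regulome_unparsed"] = rank.isna()
        out["regulatory"] = (rank <= _REGULOME_RANK[thresholds.regulome_max_rank]).fillna(False)
    return out
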