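"""Reading, validation, and harmonization of GWAS summary statistics.

This module handles the plumbing that every cross-trait analysis needs
before any statistics can be computed: parsing whitespace/tab-delimited
summary-statistics tables into a canonical frame, converting between
signed z-scores and two-sided p-values without losing precision in the
far tail, aligning the effect alleles of two studies (allele swaps,
strand flips, ambiguous-strand removal), and the median-based genomic
inflation correction.

Canonical per-variant columns are ``snp, chrom, pos, a1, a2, z, p``
(plus optional ``n``).  ``a1`` is the effect allele: ``z`` measures the
association of each additional copy of ``a1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatsError",
    "ColumnConfigError",
    "PairedSumstats",
    "p_from_z",
    "log10p_from_z",
    "z_from_p",
    "gc_correct",
    "read_sumstats",
    "harmonize_pair",
    "exclude_mhc",
]

# median of the chi-square(1) distribution, the denominator of lambda_GC
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

# smallest positive double; p-values of 0 (or underflowed) are clamped here
TINY_P = 5e-324

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: roles understood by :func:`read_sumstats`
ROLES = ("snp", "chrom", "pos", "a1", "a2", "z", "p", "beta", "se", "n")


class SumstatsError(ValueError):
    """Invalid summary-statistics input."""


class ColumnConfigError(SumstatsError):
    """A required column role could not be resolved from the header."""


@dataclass
class PairedSumstats:
    """Two harmonized traits merged on variant id.

    ``frame`` columns: ``snp, chrom, pos, a1, a2, z1, p1, z2, p2,
    allele_swapped, strand_flipped`` with z2 expressed relative to the
    primary trait's effect allele ``a1``.  ``meta`` records drop counts
    (ambiguous, mismatched alleles) and option flags.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.frame)


# ---------------------------------------------------------------------------
# z/p conversions


def p_from_z(z):
    """Two-sided p-value ``2*Phi(-|z|)`` of a signed z-score.

    Evaluated through the log survival function so the tail is accurate
    for |z| up to ~38; beyond that the true value is smaller than the
    smallest subnormal double and the result is clamped to 5e-324.  Use
    :func:`log10p_from_z` when the tail magnitude itself matters.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise SumstatsError("non-finite z-score")
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    p = np.exp(logp)
    p = np.maximum(p, TINY_P)
    return p if p.ndim else float(p)


def log10p_from_z(z):
    """log10 of the two-sided p-value; tail-stable for any finite z."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise SumstatsError("non-finite z-score")
    out = (np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    return out if out.ndim else float(out)


def z_from_p(p, sign=1):
    """Signed z-score with two-sided p-value ``p``: ``sign * Phi^-1(1 - p/2)``."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise SumstatsError("p-values must lie in (0, 1]")
    z = stats.norm.isf(p / 2.0) * np.sign(np.asarray(sign, dtype=float))
    return z if z.ndim else float(z)


def gc_correct(z, force=False):
    """Genomic-inflation correction of a z-score vector.

    lambda = median(z^2) / median(chi^2_1); corrected z = z / sqrt(lambda).
    Deflation (lambda < 1) is not applied unless ``force`` is set, and a
    degenerate all-zero input is treated as lambda = 1.

    Returns ``(z_corrected, lam)``.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 100:
        logger.warning("gc_correct on %d variants; lambda is unstable below 100", z.size)
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    if lam <= 0:
        return z.copy(), 1.0
    if lam < 1 and not force:
        return z.copy(), lam
    return z / np.sqrt(lam), lam


# ---------------------------------------------------------------------------
# reading


def read_sumstats(path, column_map, z_p_rel_tol=0.05, delim=None):
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path : str or Path
        File with a header row.
    column_map : dict
        Role -> column-name mapping, e.g. ``{"snp": "SNP", "z": "Z",
        "p": "P"}``.  Mandatory roles: ``snp``, ``a1``, ``a2``, and at
        least one of ``z``, (``beta`` and ``se``), or ``p``.
    z_p_rel_tol : float
        Relative tolerance for flagging records whose supplied p and z
        disagree (``|p - p_from_z(z)| / p > tol``).  The p column stays
        authoritative for flagged records.
    delim : str, optional
        Field separator; default any whitespace run.

    Returns a DataFrame with canonical columns; parse metadata (drop
    counts, inconsistency count) is stored in ``df.attrs``.
    """
    unknown = set(column_map) - set(ROLES)
    if unknown:
        raise ColumnConfigError(f"unknown roles in column map: {sorted(unknown)}")
    raw = pd.read_csv(path, sep=delim if delim is not None else r"\s+", dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    for role in ("snp", "a1", "a2"):
        if role not in column_map:
            raise ColumnConfigError(f"column map must supply the '{role}' role")
    has_z = "z" in column_map
    has_beta = "beta" in column_map and "se" in column_map
    has_p = "p" in column_map
    if not (has_z or has_beta or has_p):
        raise ColumnConfigError(
            "no association column resolvable: need role 'z', or 'beta'+'se', or 'p'"
        )
    for role, col in column_map.items():
        if col not in raw.columns:
            raise ColumnConfigError(f"column '{col}' for role '{role}' not in header")

    df = pd.DataFrame({"snp": raw[column_map["snp"]].str.strip()})
    df["a1"] = raw[column_map["a1"]].str.strip().str.upper()
    df["a2"] = raw[column_map["a2"]].str.strip().str.upper()
    df["chrom"] = (
        raw[column_map["chrom"]].str.strip().str.replace("^chr", "", regex=True)
        if "chrom" in column_map
        else ""
    )

    def _num(role):
        return pd.to_numeric(raw[column_map[role]], errors="coerce") if role in column_map else None

    pos = _num("pos")
    df["pos"] = pos.astype("Int64") if pos is not None else pd.NA
    z, p, beta, se, n = _num("z"), _num("p"), _num("beta"), _num("se"), _num("n")

    dropped = {"bad_numeric": 0, "bad_allele": 0, "p_clamped": 0}

    if z is None and beta is not None and se is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
    keep = np.ones(len(df), dtype=bool)
    if z is not None:
        keep &= np.isfinite(z.to_numpy(dtype=float))
    if p is not None:
        pv = p.to_numpy(dtype=float)
        clamp = np.isfinite(pv) & (pv == 0)
        p = pd.Series(np.where(clamp, TINY_P, pv), index=p.index)
        dropped["p_clamped"] = int(clamp.sum())
        keep &= np.isfinite(p.to_numpy(dtype=float)) & (p.to_numpy(dtype=float) > 0) & (
            p.to_numpy(dtype=float) <= 1.0
        )
    ok_allele = df["a1"].isin(_COMPLEMENT) & df["a2"].isin(_COMPLEMENT) & (df["a1"] != df["a2"])
    dropped["bad_allele"] = int((~ok_allele).sum())
    dropped["bad_numeric"] = int((~keep).sum())
    mask = keep & ok_allele.to_numpy()

    if z is not None:
        df["z"] = z
    if p is not None:
        df["p"] = p
    if n is not None:
        df["n"] = n
    df = df.loc[mask].reset_index(drop=True)
    if len(df) == 0:
        raise SumstatsError(f"no parseable records in {path}")

    if "z" not in df.columns:
        # direction unknown: magnitude-only z (sign from nothing -> +)
        df["z"] = z_from_p(np.clip(df["p"].to_numpy(dtype=float), TINY_P, 1.0))
        logger.warning("no z/beta source; z magnitudes derived from p with positive sign")
    if "p" not in df.columns:
        df["p"] = p_from_z(df["z"].to_numpy(dtype=float))

    with np.errstate(divide="ignore"):
        implied = p_from_z(df["z"].to_numpy())
    pv = df["p"].to_numpy()
    df["zp_inconsistent"] = np.abs(pv - implied) / pv > z_p_rel_tol
    df.attrs["dropped"] = dropped
    df.attrs["n_inconsistent"] = int(df["zp_inconsistent"].sum())
    logger.info(
        "read %d records from %s (dropped: %s, z/p inconsistent: %d)",
        len(df), path, dropped, df.attrs["n_inconsistent"],
    )
    return df


# ---------------------------------------------------------------------------
# harmonization


def _is_ambiguous(a1, a2):
    return np.asarray([_COMPLEMENT.get(x) == y for x, y in zip(a1, a2)])


def harmonize_pair(primary, secondary, drop_ambiguous=True):
    """Merge two canonical sumstats frames on ``snp``, aligning alleles.

    The merged record keeps the primary trait's (a1, a2) orientation.
    Secondary alleles equal to (a2, a1) flip the sign of z2; strand
    complements are complemented before matching (possibly combined
    with a swap); A/T and C/G pairs are strand-ambiguous and dropped by
    default; any remaining allele mismatch is dropped and counted.
    """
    if len(primary) == 0 or len(secondary) == 0:
        raise SumstatsError("harmonize_pair requires two nonempty inputs")
    m = primary.merge(
        secondary[[c for c in ("snp", "a1", "a2", "z", "p") if c in secondary.columns]],
        on="snp",
        suffixes=("", "_2"),
        validate="one_to_one",
    )
    if len(m) == 0:
        raise SumstatsError("empty variant intersection between traits")

    a1 = m["a1"].to_numpy(dtype=object)
    a2 = m["a2"].to_numpy(dtype=object)
    b1 = m["a1_2"].to_numpy(dtype=object)
    b2 = m["a2_2"].to_numpy(dtype=object)
    c1 = np.array([_COMPLEMENT[x] for x in b1], dtype=object)
    c2 = np.array([_COMPLEMENT[x] for x in b2], dtype=object)

    same = (b1 == a1) & (b2 == a2)
    swapped = (b1 == a2) & (b2 == a1)
    flipped = (c1 == a1) & (c2 == a2) & ~same & ~swapped
    flip_swap = (c1 == a2) & (c2 == a1) & ~same & ~swapped
    ambiguous = _is_ambiguous(a1, a2)

    matched = same | swapped | flipped | flip_swap
    keep = matched & (~ambiguous if drop_ambiguous else True)

    z2 = m["z_2"].to_numpy(dtype=float).copy()
    z2[swapped | flip_swap] *= -1.0

    out = m.loc[keep, ["snp", "chrom", "pos", "a1", "a2", "z", "p"]].rename(
        columns={"z": "z1", "p": "p1"}
    )
    out["z2"] = z2[keep]
    out["p2"] = m.loc[keep, "p_2"].to_numpy()
    out["allele_swapped"] = (swapped | flip_swap)[keep]
    out["strand_flipped"] = (flipped | flip_swap)[keep]
    out = out.reset_index(drop=True)
    meta = {
        "n_merged": int(matched.sum()),
        "ambiguous_dropped": int((ambiguous & matched).sum()) if drop_ambiguous else 0,
        "allele_mismatch_dropped": int((~matched).sum()),
        "allele_swapped": int(out["allele_swapped"].sum()),
        "strand_flipped": int(out["strand_flipped"].sum()),
        "drop_ambiguous": bool(drop_ambiguous),
    }
    logger.info("harmonized %d variants (%s)", len(out), meta)
    return PairedSumstats(frame=out, meta=meta)


#: extended major histocompatibility complex, chr6 (1-based, closed)
MHC_WINDOW = ("6", 25_000_000, 35_000_000)


def exclude_mhc(paired: PairedSumstats) -> PairedSumstats:
    """Drop variants inside the MHC window chr6:25,000,000-35,000,000 (closed)."""
    f = paired.frame
    chrom, lo, hi = MHC_WINDOW
    pos = pd.to_numeric(f["pos"], errors="coerce")
    inside = (f["chrom"].astype(str) == chrom) & (pos >= lo) & (pos <= hi)
    meta = dict(paired.meta, mhc_excluded=int(inside.sum()))
    return PairedSumstats(frame=f.loc[~inside.fillna(False)].reset_index(drop=True), meta=meta)
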