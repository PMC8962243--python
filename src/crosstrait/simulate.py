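"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all bit-reproducible given a seed:

* :func:`simulate_sumstats_pair` — paired GWAS summary statistics from a
  four-component polygenic mixture (null / trait-1-only / trait-2-only /
  pleiotropic).  One component label and true effect pair (delta1,
  delta2) is drawn per LD block; the pleiotropic component is bivariate
  normal with effect correlation rho_b.  Observed z-scores add
  unit-variance noise with cross-trait correlation rho_ns (shared
  samples between the two GWAS), and within-block correlation is
  induced by a shared per-block noise factor at level ``ld_r2``, the
  same r^2 written to the emitted pairwise LD table, so the LD table
  and the z correlation are mutually consistent.  Secondary-trait
  alleles are randomly swapped/strand-complemented (recorded in the
  truth table) so harmonization is exercised.
* :func:`simulate_mr_instruments` — instruments with exposure effects
  bx ~ N(bx_mean, bx_sd^2) (resampled away from zero), outcome effects
  by = beta_true * bx + alpha_j + N(0, se_y^2) where alpha_j ~
  N(0, pleiotropy_sd^2) is a directional-pleiotropy contamination.
* :func:`simulate_expression` — a genes x samples matrix of N(0, 1)
  expression (the published design this emulates has 50 cases and 66
  controls) with a fraction of genes mean-shifted in cases and optional
  injected outliers at |value| in (4, 8) to exercise masking.

Default parameters are the study conditions for all calibration and
power tests in this package; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import p_from_z

__all__ = [
    "SimulationTruth",
    "simulate_sumstats_pair",
    "simulate_mr_instruments",
    "simulate_expression",
]

COMPONENTS = ("null", "trait1_only", "trait2_only", "pleiotropic")

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationTruth:
    """Ground truth for one simulated paired-GWAS dataset.

    ``frame`` columns: snp, block, component, delta1, delta2, secondary
    allele bookkeeping (swapped/flipped).  ``params`` echoes the
    generator arguments.
    """

    frame: pd.DataFrame = field(repr=False)
    params: dict = field(default_factory=dict)


def _block_sizes(n_variants, block_sizes, rng):
    if np.isscalar(block_sizes):
        lo = hi = int(block_sizes)
    else:
        lo, hi = int(block_sizes[0]), int(block_sizes[1])
    if lo < 1 or hi < lo:
        raise ValueError("invalid block size range")
    sizes = []
    total = 0
    while total < n_variants:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, n_variants - total)
        sizes.append(s)
        total += s
    return np.array(sizes)


def simulate_sumstats_pair(
    n_variants=100_000,
    pi=(0.90, 0.04, 0.04, 0.02),
    sigma_b1=3.0,
    sigma_b2=3.0,
    rho_b=0.5,
    rho_ns=0.0,
    block_sizes=(1, 5),
    ld_r2=0.8,
    ambiguous_frac=0.0,
    seed=0,
):
    """Simulate a pair of GWAS summary-statistics tables with shared truth.

    Parameters
    ----------
    n_variants : total variant count.
    pi : mixture weights (null, trait1-only, trait2-only, pleiotropic);
        must be nonnegative and sum to 1.  One component per LD block.
    sigma_b1, sigma_b2 : SD of nonzero true effects on the z scale.
    rho_b : correlation of (delta1, delta2) within the pleiotropic
        component (|rho_b| <= 1).
    rho_ns : cross-trait correlation of the noise, modelling overlapping
        GWAS samples (|rho_ns| < 1).
    block_sizes : int or (lo, hi); block sizes drawn uniformly.
    ld_r2 : within-block z-score correlation under the null, emitted as
        R2 in the LD pairs table (strictly above the conventional 0.1
        blocking threshold).
    ambiguous_frac : fraction of variants given strand-ambiguous (A/T
        or C/G) allele pairs.
    seed : generator seed.

    Returns ``(primary_df, secondary_df, ld_pairs_df, truth)`` where the
    two sumstats frames have columns SNP, CHR, BP, A1, A2, Z, P and the
    LD table has SNP_A, SNP_B, R2 (a chain per block).
    """
    pi = np.asarray(pi, float)
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be a nonnegative 4-vector summing to 1")
    if not (abs(rho_ns) < 1 and abs(rho_b) <= 1):
        raise ValueError("require |rho_ns| < 1 and |rho_b| <= 1")
    if not (0 < ld_r2 < 1):
        raise ValueError("ld_r2 must lie in (0, 1)")
    rng = np.random.default_rng(int(seed))

    sizes = _block_sizes(n_variants, block_sizes, rng)
    n_blocks = len(sizes)
    block_of = np.repeat(np.arange(n_blocks), sizes)

    # one mixture component and effect pair per block
    comp = rng.choice(4, size=n_blocks, p=pi)
    d1 = np.zeros(n_blocks)
    d2 = np.zeros(n_blocks)
    t1 = comp == 1
    t2 = comp == 2
    pl = comp == 3
    d1[t1] = rng.normal(0.0, sigma_b1, t1.sum())
    d2[t2] = rng.normal(0.0, sigma_b2, t2.sum())
    if pl.any():
        cov = np.array(
            [[sigma_b1**2, rho_b * sigma_b1 * sigma_b2],
             [rho_b * sigma_b1 * sigma_b2, sigma_b2**2]]
        )
        # svd method tolerates the singular |rho_b| = 1 boundary
        eff = rng.multivariate_normal([0.0, 0.0], cov, size=int(pl.sum()))
        d1[pl], d2[pl] = eff[:, 0], eff[:, 1]

    def _bvn(size):
        e1 = rng.standard_normal(size)
        e2 = rho_ns * e1 + np.sqrt(1 - rho_ns**2) * rng.standard_normal(size)
        return e1, e2

    be1, be2 = _bvn(n_blocks)       # block-shared noise factor
    ve1, ve2 = _bvn(n_variants)     # idiosyncratic noise
    a = np.sqrt(ld_r2)
    b = np.sqrt(1.0 - ld_r2)
    z1 = d1[block_of] + a * be1[block_of] + b * ve1
    z2 = d2[block_of] + a * be2[block_of] + b * ve2

    snp = np.array([f"rs{i:07d}" for i in range(n_variants)])
    chrom = (block_of % 22) + 1
    pos = np.empty(n_variants, dtype=int)
    for c in range(1, 23):
        m = chrom == c
        pos[m] = 1_000_000 + 10_000 * np.arange(m.sum())

    # primary alleles; a slice of ambiguous pairs if requested
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_variants)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    amb = rng.random(n_variants) < ambiguous_frac
    if amb.any():
        amb_idx = rng.integers(0, len(_AMBIGUOUS_PAIRS), int(amb.sum()))
        a1[amb] = [_AMBIGUOUS_PAIRS[i][0] for i in amb_idx]
        a2[amb] = [_AMBIGUOUS_PAIRS[i][1] for i in amb_idx]

    # secondary orientation: random swaps and strand flips
    swapped = rng.random(n_variants) < 0.25
    flipped = rng.random(n_variants) < 0.25
    b1, b2 = a1.copy(), a2.copy()
    b1[swapped], b2[swapped] = a2[swapped], a1[swapped]
    comp_map = np.vectorize(_COMP.get)
    b1[flipped] = comp_map(b1[flipped])
    b2[flipped] = comp_map(b2[flipped])
    z2_reported = np.where(swapped, -z2, z2)

    primary = pd.DataFrame(
        {"SNP": snp, "CHR": chrom, "BP": pos, "A1": a1, "A2": a2,
         "Z": z1, "P": p_from_z(z1)}
    )
    secondary = pd.DataFrame(
        {"SNP": snp, "CHR": chrom, "BP": pos, "A1": b1, "A2": b2,
         "Z": z2_reported, "P": p_from_z(z2_reported)}
    )

    # chain of within-block pairs
    left = np.flatnonzero(block_of[:-1] == block_of[1:])
    ld_pairs = pd.DataFrame(
        {"SNP_A": snp[left], "SNP_B": snp[left + 1],
         "R2": np.full(len(left), float(ld_r2))}
    )

    truth = SimulationTruth(
        frame=pd.DataFrame(
            {
                "snp": snp,
                "block": block_of,
                "component": np.array(COMPONENTS, dtype=object)[comp[block_of]],
                "delta1": d1[block_of],
                "delta2": d2[block_of],
                "z2_true": z2,
                "swapped": swapped,
                "flipped": flipped,
                "ambiguous": amb,
            }
        ),
        params=dict(
            n_variants=n_variants, pi=tuple(pi), sigma_b1=sigma_b1,
            sigma_b2=sigma_b2, rho_b=rho_b, rho_ns=rho_ns,
            block_sizes=block_sizes, ld_r2=ld_r2,
            ambiguous_frac=ambiguous_frac, seed=seed,
        ),
    )
    return primary, secondary, ld_pairs, truth


def simulate_mr_instruments(
    n_iv=50,
    beta_true=0.2,
    bx_mean=0.3,
    bx_sd=0.1,
    se_y=0.05,
    pleiotropy_sd=0.0,
    seed=0,
):
    """Simulate a two-sample MR instrument table.

    Exposure effects bx are N(bx_mean, bx_sd^2) resampled until
    |bx| > 0.05 (no weak instruments); outcome effects are
    by = beta_true * bx + alpha + N(0, se_y^2), alpha ~ N(0,
    pleiotropy_sd^2).  Returns ``(instruments_df, truth_dict)``; the
    frame carries both the TSV-style and canonical column names.
    """
    if n_iv < 1 or se_y <= 0:
        raise ValueError("need n_iv >= 1 and se_y > 0")
    rng = np.random.default_rng(int(seed))
    bx = rng.normal(bx_mean, bx_sd, n_iv)
    while np.any(np.abs(bx) <= 0.05):
        redo = np.abs(bx) <= 0.05
        bx[redo] = rng.normal(bx_mean, bx_sd, int(redo.sum()))
    alpha = rng.normal(0.0, pleiotropy_sd, n_iv) if pleiotropy_sd > 0 else np.zeros(n_iv)
    by = beta_true * bx + alpha + rng.normal(0.0, se_y, n_iv)
    ea = rng.choice(["A", "C", "G", "T"], n_iv)
    df = pd.DataFrame(
        {
            "snp": [f"iv{i:04d}" for i in range(n_iv)],
            "ea": ea,
            "oa": [_COMP[x] for x in ea],
            "beta_exposure": bx,
            "se_exposure": np.full(n_iv, 0.01),
            "beta_outcome": by,
            "se_outcome": np.full(n_iv, float(se_y)),
        }
    )
    truth = dict(beta_true=beta_true, alpha=alpha, seed=seed)
    return df, truth


def simulate_expression(
    n_genes=100,
    n_case=50,
    n_control=66,
    de_fraction=0.10,
    effect_sd_units=1.5,
    outlier_rate=0.0,
    seed=0,
):
    """Simulate a genes x samples expression matrix with case shifts.

    Baseline expression is N(0, 1); a ``de_fraction`` of genes (the
    first ones, recorded in the truth) is shifted by ``effect_sd_units``
    in cases.  With ``outlier_rate`` > 0, that fraction of entries is
    replaced by values of magnitude uniform in (4, 8) with random sign.

    Returns ``(matrix, labels, truth)``: matrix is a DataFrame indexed
    by gene with sample columns, labels a Series sample -> case/control,
    truth a DataFrame with the per-gene DE indicator and effect.
    """
    if not (0 <= de_fraction <= 1) or min(n_genes, n_case, n_control) < 0:
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(int(seed))
    n_s = n_case + n_control
    x = rng.standard_normal((n_genes, n_s))
    n_de = int(round(de_fraction * n_genes))
    x[:n_de, :n_case] += effect_sd_units
    if outlier_rate > 0:
        out = rng.random((n_genes, n_s)) < outlier_rate
        x[out] = rng.choice([-1.0, 1.0], int(out.sum())) * rng.uniform(4.0, 8.0, int(out.sum()))
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    samples = [f"case{i:03d}" for i in range(n_case)] + [f"ctrl{i:03d}" for i in range(n_control)]
    matrix = pd.DataFrame(x, index=genes, columns=samples)
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    truth = pd.DataFrame(
        {"gene": genes,
         "is_de": np.arange(n_genes) < n_de,
         "effect": np.where(np.arange(n_genes) < n_de, effect_sd_units, 0.0)}
    )
    return matrix, labels, truth
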