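"""Conditional Q-Q enrichment and condFDR/conjFDR estimation.

The conditional false discovery rate condFDR(trait1 | trait2) of a
variant is the posterior probability that it is null for trait 1 given
that the p-values of both traits are at most the observed ones.  With
the conservative choice pi0 = 1 it is estimated as

    condFDR_i = p1_i / F_hat(p1_i | p2 <= p2_i),

where F_hat is the empirical conditional CDF of p1 within the stratum of
variants at least as significant as variant i for trait 2.  The
conjunctional FDR (null for *either* trait) is conservatively the
maximum of the two reciprocal condFDRs, and variants below a conjFDR
cutoff (0.01 by default) are declared shared.

Two evaluation routes are provided:

* ``exact`` direct counting — F_hat evaluated at every variant's own
  (p1, p2) by 2-D dominance counting.  This is the defining formula and
  the reference for tests.
* a stratified lookup table (:func:`build_conditional_cdf`) — F_hat
  tabulated on a -log10 grid of cumulative trait-2 strata, optionally
  averaged over random LD-pruning iterations (one variant per LD block,
  100 draws by default) so correlated variants do not inflate the
  empirical CDF; per-variant values interpolate the table bilinearly.
  This is the pipeline default: pruning enters the CDF estimate only,
  while every variant (pruned out or not) receives a condFDR value.

Conditional Q-Q curves — quantiles of -log10 p1 within strata of
increasingly significant trait-2 association — visualize the same
enrichment; successive leftward deflection of the stratified curves from
the all-SNP curve indicates pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldops import LdBlockSet
from .sumstats import PairedSumstats, TINY_P

logger = logging.getLogger(__name__)

__all__ = [
    "QQConfig",
    "ConditionalCdf",
    "CondFdrResult",
    "QQCurves",
    "build_conditional_cdf",
    "cond_fdr",
    "conj_fdr",
    "conditional_qq",
    "select_significant",
]


@dataclass
class QQConfig:
    """Settings for conditional CDF/Q-Q estimation.

    strata_thresholds are cumulative -log10 p cutoffs on the secondary
    trait (the all-SNP stratum, cutoff 0, is always included).
    """

    strata_thresholds: tuple = (1.0, 2.0, 3.0)
    pruning_iterations: int = 100
    r2_threshold: float = 0.1
    seed: int = 0
    min_stratum_size: int = 100
    knot_step: float = 0.1

    def __post_init__(self):
        t = tuple(self.strata_thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("strata thresholds must be strictly increasing")
        if self.pruning_iterations < 1:
            raise ValueError("pruning_iterations must be >= 1")


@dataclass
class ConditionalCdf:
    """Tabulated F_hat(-log10 p1 knot | -log10 p2 >= stratum cutoff).

    ``fhat[i, j]`` estimates P(P1 <= 10^-knot_i | P2 <= 10^-stratum_j),
    averaged over pruning iterations.  ``valid`` marks strata whose
    denominator was nonzero in at least one iteration.  ``direction`` is
    1 for FDR(trait1 | trait2), 2 for the reciprocal.
    """

    p1_knots: np.ndarray = field(repr=False)
    p2_strata: np.ndarray = field(repr=False)
    fhat: np.ndarray = field(repr=False)
    denominators: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)
    direction: int = 1
    n_iterations: int = 1

    def evaluate(self, log10p1, log10p2):
        """Bilinear interpolation of F_hat at per-variant coordinates.

        Coordinates are clipped to the tabulated (valid) range.
        """
        x = np.clip(np.asarray(log10p1, float), self.p1_knots[0], self.p1_knots[-1])
        last_valid = np.max(np.flatnonzero(self.valid))
        y = np.clip(np.asarray(log10p2, float), self.p2_strata[0], self.p2_strata[last_valid])
        ix = np.clip(np.searchsorted(self.p1_knots, x) - 1, 0, len(self.p1_knots) - 2)
        iy = np.clip(np.searchsorted(self.p2_strata[: last_valid + 1], y) - 1, 0, max(last_valid - 1, 0))
        x0, x1 = self.p1_knots[ix], self.p1_knots[ix + 1]
        y0, y1 = self.p2_strata[iy], self.p2_strata[iy + 1]
        tx = np.where(x1 > x0, (x - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
        ty = np.where(y1 > y0, (y - y0) / np.where(y1 > y0, y1 - y0, 1.0), 0.0)
        f00 = self.fhat[ix, iy]
        f10 = self.fhat[ix + 1, iy]
        # zero-weight corners may sit on an invalid (NaN) stratum column
        f01 = np.where(ty > 0, self.fhat[ix, iy + 1], 0.0)
        f11 = np.where(ty > 0, self.fhat[ix + 1, iy + 1], 0.0)
        return (f00 * (1 - tx) * (1 - ty) + f10 * tx * (1 - ty)
                + f01 * (1 - tx) * ty + f11 * tx * ty)


@dataclass
class CondFdrResult:
    """Per-variant condFDR in both directions and their conjunction."""

    frame: pd.DataFrame = field(repr=False)  # snp, fdr_1_given_2, fdr_2_given_1, conj_fdr

    def __len__(self):
        return len(self.frame)


def _neglog10(p):
    return -np.log10(np.maximum(np.asarray(p, float), TINY_P))


def _paired_arrays(paired, direction):
    f = paired.frame if isinstance(paired, PairedSumstats) else paired
    p1 = f["p1"].to_numpy(float)
    p2 = f["p2"].to_numpy(float)
    return (p1, p2) if direction == 1 else (p2, p1)


def _prune_index_arrays(paired, blocks):
    """Row indices of the paired frame grouped by LD block."""
    f = paired.frame if isinstance(paired, PairedSumstats) else paired
    row_of = pd.Series(np.arange(len(f)), index=f["snp"])
    flat, offsets, counts = blocks.member_arrays()
    rows = row_of.reindex(flat).to_numpy(dtype=float)
    if np.isnan(rows).any():
        raise ValueError("every paired variant must be assigned to a block")
    return rows.astype(int), offsets, counts


def build_conditional_cdf(paired, blocks=None, config=None, direction=1):
    """Estimate the conditional empirical CDF table for one direction.

    For every pruning iteration one variant is drawn uniformly per LD
    block (``blocks=None`` disables pruning: a single pass over all
    variants).  Within an iteration, for each cumulative trait-2 stratum
    cutoff t and each -log10 p1 knot x,

        F_iter(x | t) = #{p1 <= 10^-x and p2 <= 10^-t} / #{p2 <= 10^-t},

    and the reported table is the across-iteration mean (iterations with
    an empty stratum contribute nothing to that stratum).  The table is
    regularized to be monotone in p1, which exact counting already
    guarantees; averaging preserves it.
    """
    config = config or QQConfig()
    l1, l2 = (_neglog10(x) for x in _paired_arrays(paired, direction))
    if len(l1) == 0:
        raise ValueError("empty paired input")
    step = config.knot_step
    knots = np.arange(0.0, np.max(l1) + 2 * step, step)
    strata = np.arange(0.0, np.max(l2) + 2 * step, step)

    if blocks is None:
        iters = [None]
    else:
        rows, offsets, counts = _prune_index_arrays(paired, blocks)
        iters = range(config.pruning_iterations)

    f_sum = np.zeros((len(knots), len(strata)))
    f_n = np.zeros(len(strata))
    den_sum = np.zeros(len(strata))
    for it in iters:
        if it is None:
            s1, s2 = l1, l2
        else:
            rng = np.random.default_rng([int(config.seed), int(it)])
            pick = rows[offsets + rng.integers(0, counts)]
            s1, s2 = l1[pick], l2[pick]
        hist, _, _ = np.histogram2d(
            s1, s2, bins=[np.append(knots, np.inf), np.append(strata, np.inf)]
        )
        counts2d = np.cumsum(np.cumsum(hist[::-1, ::-1], 0), 1)[::-1, ::-1]
        den = counts2d[0, :]
        ok = den > 0
        f_sum[:, ok] += counts2d[:, ok] / den[ok]
        f_n[ok] += 1
        den_sum += den
    valid = f_n > 0
    if not valid.any():
        raise ValueError("all conditioning strata are empty")
    fhat = np.full_like(f_sum, np.nan)
    fhat[:, valid] = f_sum[:, valid] / f_n[valid]
    # monotone regularization along p1 (no-op on already-monotone columns)
    fhat[:, valid] = np.maximum.accumulate(fhat[::-1, valid], axis=0)[::-1]
    return ConditionalCdf(
        p1_knots=knots,
        p2_strata=strata,
        fhat=fhat,
        denominators=den_sum / max(len(iters), 1),
        valid=valid,
        direction=direction,
        n_iterations=len(iters) if blocks is not None else 1,
    )


# ---------------------------------------------------------------------------
# exact direct counting


class _Fenwick:
    """Binary indexed tree for prefix counts over ranks (1-based)."""

    __slots__ = ("n", "t")

    def __init__(self, n):
        self.n = n
        self.t = [0] * (n + 1)

    def add(self, i):
        t = self.t
        while i <= self.n:
            t[i] += 1
            i += i & (-i)

    def prefix(self, i):
        s, t = 0, self.t
        while i > 0:
            s += t[i]
            i -= i & (-i)
        return s


def _direct_counting_fdr(p1, p2):
    """condFDR by the defining counts, ties handled as exact <=.

    FDR_i = min(1, p1_i * D_i / N_i) with D_i = #{j : p2_j <= p2_i} and
    N_i = #{j : p1_j <= p1_i and p2_j <= p2_i}  (N_i >= 1: includes i).
    O(n log n) via a Fenwick tree over p1 ranks, sweeping p2 tie-groups.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n = len(p1)
    r1 = np.searchsorted(np.sort(p1), p1, side="right")  # rank with ties <=
    d = np.searchsorted(np.sort(p2), p2, side="right").astype(float)
    order = np.argsort(p2, kind="stable")
    tree = _Fenwick(n)
    num = np.empty(n)
    i = 0
    p2s = p2[order]
    while i < n:
        j = i
        while j < n and p2s[j] == p2s[i]:
            j += 1
        for k in order[i:j]:
            tree.add(int(r1[k]))
        for k in order[i:j]:
            num[k] = tree.prefix(int(r1[k]))
        i = j
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = p1 * d / num
    return np.minimum(fdr, 1.0)


def cond_fdr(paired, cdf=None, direction=1):
    """Per-variant condFDR(primary | secondary) for one direction.

    With ``cdf=None`` the exact direct-counting definition is evaluated
    at every variant's own (p1, p2).  With a :class:`ConditionalCdf`
    (possibly pruning-averaged) the tabulated F_hat is interpolated
    bilinearly in (-log10 p1, -log10 p2).  Values are clipped to [0, 1];
    a variant where the interpolated F_hat is nonpositive gets 1 and is
    flagged.

    Returns ``(fdr_values, flags)`` as numpy arrays.
    """
    p1, p2 = _paired_arrays(paired, direction)
    if cdf is None:
        fdr = _direct_counting_fdr(p1, p2)
        return fdr, np.zeros(len(fdr), dtype=bool)
    if cdf.direction != direction:
        raise ValueError(f"cdf was built for direction {cdf.direction}, not {direction}")
    f = cdf.evaluate(_neglog10(p1), _neglog10(p2))
    flags = ~(f > 0) | ~np.isfinite(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(flags, 1.0, p1 / np.where(f > 0, f, 1.0))
    return np.clip(fdr, 0.0, 1.0), flags


def conj_fdr(fdr_1_given_2, fdr_2_given_1):
    """Conjunctional FDR: elementwise maximum of the reciprocal condFDRs."""
    a = np.asarray(fdr_1_given_2, float)
    b = np.asarray(fdr_2_given_1, float)
    if a.shape != b.shape:
        raise ValueError("condFDR vectors must have equal length")
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("condFDR values must lie in [0, 1]")
    return np.maximum(a, b)


def compute_condfdr_result(paired, blocks=None, config=None) -> CondFdrResult:
    """Both condFDR directions plus conjFDR for every paired variant."""
    config = config or QQConfig()
    if blocks is None:
        f12, fl1 = cond_fdr(paired, direction=1)
        f21, fl2 = cond_fdr(paired, direction=2)
    else:
        cdf1 = build_conditional_cdf(paired, blocks, config, direction=1)
        cdf2 = build_conditional_cdf(paired, blocks, config, direction=2)
        f12, fl1 = cond_fdr(paired, cdf1, direction=1)
        f21, fl2 = cond_fdr(paired, cdf2, direction=2)
    frame = paired.frame if isinstance(paired, PairedSumstats) else paired
    out = pd.DataFrame(
        {
            "snp": frame["snp"].to_numpy(),
            "fdr_1_given_2": f12,
            "fdr_2_given_1": f21,
            "conj_fdr": conj_fdr(f12, f21),
            "flagged": fl1 | fl2,
        }
    )
    return CondFdrResult(frame=out)


def select_significant(result, threshold=0.01):
    """Variants with conjFDR strictly below ``threshold``, ascending order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frame = result.frame if isinstance(result, CondFdrResult) else result
    sel = frame.loc[frame["conj_fdr"] < threshold]
    return sel.sort_values(["conj_fdr", "snp"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# conditional Q-Q curves


@dataclass
class QQCurves:
    """Plot-ready conditional Q-Q curves and per-stratum enrichment summaries.

    ``curves`` columns: stratum (the -log10 p2 cutoff), nominal_log10p
    (expected -log10 p1 under the null at that rank), empirical_log10p
    (averaged over pruning iterations).  ``enrichment`` maps stratum ->
    mean vertical gap to the all-SNP curve over the shared nominal grid;
    by construction enrichment[0.0] == 0.
    """

    curves: pd.DataFrame = field(repr=False)
    enrichment: dict = field(default_factory=dict)
    stratum_sizes: dict = field(default_factory=dict)


def conditional_qq(paired, blocks=None, config=None, direction=1):
    """Conditional Q-Q curves of the primary trait stratified by the secondary.

    For each stratum cutoff t in {0} + strata_thresholds the variants
    with -log10 p2 >= t are ranked by p1; rank i maps to the nominal
    quantile -log10(i / (m + 1)).  Curves are evaluated on a common
    nominal grid and averaged over pruning iterations.  Strata smaller
    than ``config.min_stratum_size`` (after pruning) are omitted.
    """
    config = config or QQConfig()
    l1, l2 = (_neglog10(x) for x in _paired_arrays(paired, direction))
    cutoffs = [0.0] + [float(t) for t in config.strata_thresholds]

    if blocks is None:
        iters = [None]
    else:
        rows, offsets, counts = _prune_index_arrays(paired, blocks)
        iters = range(config.pruning_iterations)

    # common nominal grid; upper end set by the all-SNP stratum size
    grid = np.arange(0.0, np.log10(len(l1) + 1) + config.knot_step, config.knot_step)
    acc = {t: np.zeros_like(grid) for t in cutoffs}
    cnt = {t: 0 for t in cutoffs}
    sizes = {t: [] for t in cutoffs}
    for it in iters:
        if it is None:
            s1, s2 = l1, l2
        else:
            rng = np.random.default_rng([int(config.seed), int(it)])
            pick = rows[offsets + rng.integers(0, counts)]
            s1, s2 = l1[pick], l2[pick]
        for t in cutoffs:
            vals = s1[s2 >= t]
            m = len(vals)
            sizes[t].append(m)
            if m < config.min_stratum_size:
                continue
            emp = np.sort(vals)[::-1]
            nominal = -np.log10(np.arange(1, m + 1) / (m + 1))
            # interpolate empirical quantiles onto the common grid
            acc[t] += np.interp(grid, nominal[::-1], emp[::-1])
            cnt[t] += 1

    frames = []
    mean_curves = {}
    for t in cutoffs:
        if cnt[t] == 0:
            logger.warning("stratum -log10 p2 >= %.1f below minimum size; curve omitted", t)
            continue
        mean_emp = acc[t] / cnt[t]
        # curve is only meaningful up to the stratum's own nominal range
        m_med = float(np.median(sizes[t]))
        keep = grid <= np.log10(m_med + 1)
        mean_curves[t] = (grid[keep], mean_emp[keep])
        frames.append(
            pd.DataFrame(
                {"stratum": t, "nominal_log10p": grid[keep], "empirical_log10p": mean_emp[keep]}
            )
        )
    if not frames:
        raise ValueError("all strata below the minimum size")

    enrichment = {}
    if 0.0 in mean_curves:
        # stop the summary at the rank-10 quantile of the smallest stratum:
        # the top order statistics fluctuate too much to average over
        shared = min(
            np.log10((np.median(sizes[t]) + 1) / 10.0) for t in mean_curves
        )
        g0, e0 = mean_curves[0.0]
        for t, (g, e) in mean_curves.items():
            keep = g <= max(shared, g[0])
            base = np.interp(g[keep], g0, e0)
            enrichment[t] = float(np.mean(e[keep] - base))
    return QQCurves(
        curves=pd.concat(frames, ignore_index=True),
        enrichment=enrichment,
        stratum_sizes={t: float(np.median(s)) if s else 0.0 for t, s in sizes.items()},
    )
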