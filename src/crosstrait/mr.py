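"""Two-sample Mendelian-randomization estimators from summary statistics.

Each instrument j contributes a ratio (Wald) estimate
theta_j = beta_outcome_j / beta_exposure_j with first-order standard
error se_outcome_j / |beta_exposure_j| (exposure uncertainty ignored —
the usual strong-instrument approximation).  Estimators:

* ``wald_ratio`` — single instrument.
* ``ivw`` — fixed-effect inverse-variance-weighted mean of the ratio
  estimates; with one instrument it reproduces the Wald ratio exactly.
* ``weighted_median`` — weight-interpolated median of the ordered ratio
  estimates, consistent when up to half the instrument weight is
  invalid; its standard error comes from a seeded parametric bootstrap.

Estimates are reported on the log-odds (or outcome-unit) scale plus the
odds-ratio scale: OR = exp(beta) with 95% CI exp(beta +/- 1.959964 se).
``summarize_or_ci`` inverts published OR/CI triples back to (beta, se, p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrInstrument",
    "MrEstimate",
    "MrError",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "summarize_or_ci",
    "read_instruments",
]

Z975 = 1.959964


class MrError(ValueError):
    """Invalid instrument input or degenerate estimate."""


@dataclass
class MrInstrument:
    """Per-variant exposure and outcome effects (aligned to one allele)."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    z: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    n_iv: int


def _finish(method, beta, se, n_iv):
    if se <= 0 or not np.isfinite(se):
        raise MrError(f"{method}: nonpositive standard error")
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        z=float(z),
        p=p,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        n_iv=int(n_iv),
    )


def _arrays(instruments):
    if isinstance(instruments, pd.DataFrame):
        bx = instruments["beta_exposure"].to_numpy(float)
        sx = instruments["se_exposure"].to_numpy(float)
        by = instruments["beta_outcome"].to_numpy(float)
        sy = instruments["se_outcome"].to_numpy(float)
    else:
        ivs = list(instruments)
        bx = np.array([i.beta_exposure for i in ivs], float)
        sx = np.array([i.se_exposure for i in ivs], float)
        by = np.array([i.beta_outcome for i in ivs], float)
        sy = np.array([i.se_outcome for i in ivs], float)
    if np.any(sy <= 0):
        raise MrError("outcome standard errors must be positive")
    if np.any(bx == 0):
        raise MrError("zero exposure effect: ratio estimate undefined")
    return bx, sx, by, sy


def wald_ratio(iv) -> MrEstimate:
    """Single-instrument ratio estimate beta_out/beta_exp, first-order se."""
    bx, _, by, sy = _arrays([iv] if isinstance(iv, MrInstrument) else iv)
    if len(bx) != 1:
        raise MrError("wald_ratio takes exactly one instrument")
    return _finish("wald", by[0] / bx[0], sy[0] / abs(bx[0]), 1)


def ivw(instruments) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    theta_j = by_j / bx_j weighted by w_j = bx_j^2 / se_yj^2 (the
    inverse of the first-order ratio variance); beta = sum(w theta) /
    sum(w), se = (sum w)^(-1/2).
    """
    bx, _, by, sy = _arrays(instruments)
    if len(bx) == 0:
        raise MrError("ivw requires at least one instrument")
    if len(bx) == 1:  # reduces exactly to the Wald ratio
        return _finish("ivw", by[0] / bx[0], sy[0] / abs(bx[0]), 1)
    theta = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return _finish("ivw", beta, se, len(bx))


def _weighted_median(theta, w):
    """Weight-interpolated median of theta (Bowden-style)."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    k = np.searchsorted(s, 0.5, side="right") - 1
    return float(th[k] + (th[k + 1] - th[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def weighted_median(instruments, n_boot=1000, seed=0) -> MrEstimate:
    """Weighted-median MR estimate with parametric-bootstrap standard error.

    Ratio estimates are weighted by inverse ratio variance, ordered, and
    the estimate interpolates theta at cumulative weight 1/2.  The se is
    the standard deviation of the estimate over ``n_boot`` draws with
    bx_j ~ N(bx_j, se_xj^2), by_j ~ N(by_j, se_yj^2) (seeded).
    """
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) < 2:
        raise MrError("weighted_median requires at least 2 instruments")
    if n_boot < 2:
        raise MrError("n_boot must be at least 2")
    theta = by / bx
    w = bx**2 / sy**2
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(int(seed))
    bxb = rng.normal(bx, np.maximum(sx, 0.0), size=(n_boot, len(bx)))
    byb = rng.normal(by, sy, size=(n_boot, len(bx)))
    bxb = np.where(bxb == 0, np.finfo(float).eps, bxb)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = byb[b] / bxb[b]
        boots[b] = _weighted_median(tb, bxb[b] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", est, se, len(bx))


def summarize_or_ci(or_, ci_low, ci_high):
    """Invert a published OR with 95% CI to (beta, se, z, p).

    beta = ln OR; se = (ln ci_high - ln ci_low) / (2 * 1.959964);
    p is the two-sided normal tail of beta/se.
    """
    if not (0 < ci_low <= or_ <= ci_high):
        raise MrError("need 0 < ci_low <= OR <= ci_high")
    beta = float(np.log(or_))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2 * Z975))
    if se <= 0:
        raise MrError("degenerate CI: zero width")
    z = beta / se
    return {"beta": beta, "se": se, "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def read_instruments(path):
    """Read an instrument TSV: SNP, [EA, OA,] BETA_EXP, SE_EXP, BETA_OUT, SE_OUT."""
    df = pd.read_csv(path, sep=r"\s+")
    need = {"SNP", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT"}
    if not need <= set(df.columns):
        raise MrError(f"instrument table lacks columns: {sorted(need - set(df.columns))}")
    return df.rename(
        columns={
            "SNP": "snp",
            "BETA_EXP": "beta_exposure",
            "SE_EXP": "se_exposure",
            "BETA_OUT": "beta_outcome",
            "SE_OUT": "se_outcome",
        }
    )
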